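"""File formats, result serialisation and the end-to-end pipeline driver.

All matrices are CSV with a header row and first-column labels, UTF-8,
"." decimal separator; readers are gzip-transparent (pandas handles the
extension).  Every output file embeds the package version, the master seed
and the stage parameters, either as ``#`` header comments (CSV) or as JSON
fields.  The pipeline driver orders the stages — synthesis, growth calling,
distances, Mantel tests, concordance/deltas, simulation — validates their
dependencies up front and emits a manifest of per-stage checksums so that
reruns with the same configuration are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoupling import DecouplingModel, DecouplingParams
from .distances import (
    DistanceMatrix,
    euclidean_matrix,
    mantel,
    parse_newick,
    patristic_matrix,
)
from .exceptions import DependencyError, TableParseError
from .growth import (
    GrowthYieldMixture,
    METADATA_FACTORS,
    anova_per_substrate,
    call_growth,
    correct_date_effect,
    subtract_blank,
)
from .pathways import (
    Pathway,
    completion_matrix,
    concordance,
    estimate_deltas,
    metabolic_distance,
    substrate_functionality,
)
from .synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_pipeline",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_plate",
    "write_plate",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_pathways",
    "read_substrate_map",
    "write_json_result",
]


def _header_comment(seed=None, **params) -> str:
    fields = [f"phenodecouple {__version__}"]
    if seed is not None:
        fields.append(f"seed={seed}")
    fields += [f"{k}={v}" for k, v in params.items()]
    return "# " + " ".join(fields) + "\n"


def write_labeled_matrix(df: pd.DataFrame, path, seed=None, **params) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed=seed, **params))
        df.to_csv(fh)


def read_labeled_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise TableParseError(f"duplicate row labels {dups} in {path}")
    return df


def write_distance_matrix(dm: DistanceMatrix, path, seed=None) -> None:
    write_labeled_matrix(dm.to_dataframe(), path, seed=seed, role=dm.role)


def read_distance_matrix(path, role: str = "generic") -> DistanceMatrix:
    head = Path(path).open().readline()
    if head.startswith("#") and "role=" in head:
        role = head.split("role=")[1].split()[0]
    df = read_labeled_matrix(path)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(), role=role)


def write_plate(plate: pd.DataFrame, path, seed=None, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed=seed, **params))
        plate.to_csv(fh, index=False)


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    expected = {"strain", "substrate", "date", "replicate", "od", "is_blank"}
    missing = expected - set(df.columns)
    if missing:
        raise TableParseError(f"plate table {path} lacks columns {sorted(missing)}")
    return df


def read_pathways(path) -> list[Pathway]:
    """Pathway definitions: TSV with columns pathway, genes (comma-separated)."""
    out = []
    seen = set()
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            pid, genes = parts
            if pid in seen:
                raise TableParseError(f"{path}:{lineno}: duplicate pathway id {pid}")
            seen.add(pid)
            out.append(Pathway(id=pid, genes=tuple(genes.split(","))))
    return out


def read_substrate_map(path) -> dict[str, list[str]]:
    """Substrate map: TSV with columns substrate, pathways (comma-separated)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sub, pws = parts
            if sub in out:
                raise TableParseError(f"{path}:{lineno}: duplicate substrate {sub}")
            out[sub] = [p for p in pws.split(",") if p]
    return out


def write_json_result(obj: dict, path, seed=None, **params) -> None:
    payload = {
        "package": "phenodecouple",
        "version": __version__,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
        **{k: _jsonable(v) for k, v in obj.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, pd.Series):
        return v.to_dict()
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return {k: _jsonable(x) for k, x in dataclasses.asdict(v).items()}
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

STAGES = ("synth", "growth", "distances", "mantel", "concordance", "simulate")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Input paths may be omitted when the ``synth`` stage generates them;
    later stages consume either the synthetic artefacts or the given files.
    """

    outdir: str
    seed: int = 0
    stages: tuple = STAGES
    synthetic: SyntheticConfig | None = None
    plates_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    genes_path: str | None = None
    pathways_path: str | None = None
    map_path: str | None = None
    fpr: float = 0.05
    k_candidates: tuple = (1, 2, 3, 4, 5)
    n_perm: int = 999
    decoupling: DecouplingParams = field(default_factory=DecouplingParams)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise DependencyError(f"unknown stages {sorted(unknown)}")
        synth = "synth" in self.stages
        if synth and self.synthetic is None:
            raise DependencyError("stage 'synth' requested without a SyntheticConfig")
        if "growth" in self.stages and not synth and self.plates_path is None:
            raise DependencyError("stage 'growth' needs plates_path or the synth stage")
        if "growth" in self.stages and not synth and self.metadata_path is None:
            raise DependencyError("stage 'growth' needs metadata_path or the synth stage")
        if "distances" in self.stages and not synth and self.tree_path is None:
            raise DependencyError("stage 'distances' needs tree_path or the synth stage")
        if "mantel" in self.stages and "distances" not in self.stages:
            raise DependencyError("stage 'mantel' needs the distances stage")
        if "concordance" in self.stages:
            if "growth" not in self.stages:
                raise DependencyError("stage 'concordance' needs the growth stage")
            if not synth and None in (self.genes_path, self.pathways_path, self.map_path):
                raise DependencyError(
                    "stage 'concordance' needs genes/pathways/map paths or the synth stage"
                )
        for name in ("plates_path", "metadata_path", "tree_path", "genes_path",
                     "pathways_path", "map_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise DependencyError(f"{name} does not exist: {p}")


@dataclass
class RunManifest:
    """Per-stage provenance: parameters, seeds and file checksums."""

    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)

    def add(self, name: str, params: dict, inputs: dict, outputs: dict) -> None:
        self.stages.append(
            {
                "name": name,
                "params": {k: _jsonable(v) for k, v in params.items()},
                "inputs": inputs,
                "outputs": outputs,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def checksums(self) -> dict:
        out = {}
        for stage in self.stages:
            out.update(stage["inputs"])
            out.update(stage["outputs"])
        return out

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "version": self.version, "stages": self.stages},
                indent=1,
            )
            + "\n"
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the requested stages in order and emit a manifest.

    Raises
    ------
    DependencyError
        Before any computation, if a requested stage lacks its inputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(s) for name, s in zip(STAGES, rng.integers(0, 2**31 - 1, len(STAGES)))}

    paths: dict[str, Path] = {}
    truth = None

    if "synth" in config.stages:
        truth, plate = generate_dataset(config.synthetic)
        written = truth.write(outdir)
        paths.update(written)
        paths["plates"] = outdir / "plates.csv"
        write_plate(plate, paths["plates"], seed=config.synthetic.seed)
        manifest.add(
            "synth",
            params=dataclasses.asdict(config.synthetic),
            inputs={},
            outputs={str(p): _sha256(p) for p in paths.values()},
        )
    else:
        for key, attr in (
            ("plates", "plates_path"), ("metadata", "metadata_path"),
            ("tree", "tree_path"), ("genes", "genes_path"),
            ("pathways", "pathways_path"), ("map", "map_path"),
        ):
            if getattr(config, attr) is not None:
                paths[key] = Path(getattr(config, attr))

    calls = None
    yields = None
    if "growth" in config.stages:
        plate = read_plate(paths["plates"])
        metadata = read_labeled_matrix(paths["metadata"])
        yields = correct_date_effect(subtract_blank(plate), metadata)
        results = GrowthYieldMixture(
            yields.long["yield_od"].to_numpy()
        ).fit(k_candidates=config.k_candidates, seed=stage_seeds["growth"], fpr=config.fpr)
        threshold = results.threshold()
        calls = results.call(yields)
        paths["yields"] = outdir / "yields.csv"
        write_labeled_matrix(yields.data, paths["yields"], seed=config.seed)
        paths["calls"] = outdir / "calls.csv"
        write_labeled_matrix(calls.data, paths["calls"], seed=config.seed,
                             threshold=f"{threshold:.6f}", fpr=config.fpr)
        paths["mixture"] = outdir / "mixture.json"
        f = results.fit
        write_json_result(
            {
                "k": f.k, "weights": f.weights, "means": f.means,
                "variances": f.variances, "bic": f.bic,
                "log_likelihood": f.log_likelihood,
                "threshold": threshold,
                "substrate_summary": calls.substrate_summary(),
            },
            paths["mixture"], seed=stage_seeds["growth"], fpr=config.fpr,
        )
        metadata_ok = all(c in metadata.columns for c in METADATA_FACTORS)
        if metadata_ok:
            table = anova_per_substrate(yields, metadata, calls=calls)
            paths["anova"] = outdir / "anova.tsv"
            table.effects.to_csv(paths["anova"], sep="\t", index=False)
        manifest.add(
            "growth",
            params={"fpr": config.fpr, "k_candidates": config.k_candidates,
                    "threshold": threshold, "seed": stage_seeds["growth"]},
            inputs={str(paths["plates"]): _sha256(paths["plates"])},
            outputs={str(paths[k]): _sha256(paths[k])
                     for k in ("yields", "calls", "mixture") if k in paths},
        )

    dist: dict[str, DistanceMatrix] = {}
    if "distances" in config.stages:
        tree = parse_newick(Path(paths["tree"]).read_text())
        dist["genetic"] = patristic_matrix(tree)
        outputs = {}
        if yields is not None:
            strains = dist["genetic"].labels
            dist["phenotypic"] = euclidean_matrix(
                yields.data.loc[strains], role="phenotypic"
            )
        if "genes" in paths and "pathways" in paths:
            genes = read_labeled_matrix(paths["genes"])
            pathways = read_pathways(paths["pathways"])
            completions = completion_matrix(genes, pathways)
            dist["metabolic"] = metabolic_distance(completions)
        for role, dm in dist.items():
            p = outdir / f"dist_{role}.csv"
            paths[f"dist_{role}"] = p
            write_distance_matrix(dm, p, seed=config.seed)
            outputs[str(p)] = _sha256(p)
        manifest.add(
            "distances", params={},
            inputs={str(paths["tree"]): _sha256(paths["tree"])}, outputs=outputs,
        )

    if "mantel" in config.stages:
        results = {}
        roles = list(dist)
        for i in range(len(roles)):
            for j in range(i + 1, len(roles)):
                a, b = roles[i], roles[j]
                da = dist[a]
                db = dist[b].reorder(da.labels)
                res = mantel(da, db, n_perm=config.n_perm, seed=stage_seeds["mantel"])
                results[f"{a}_vs_{b}"] = {
                    "r": res.r, "r2": res.r2, "p_value": res.p_value,
                    "n_perm": res.n_perm,
                }
        paths["mantel"] = outdir / "mantel.json"
        write_json_result(results, paths["mantel"], seed=stage_seeds["mantel"],
                          n_perm=config.n_perm)
        manifest.add(
            "mantel", params={"n_perm": config.n_perm, "seed": stage_seeds["mantel"]},
            inputs={}, outputs={str(paths["mantel"]): _sha256(paths["mantel"])},
        )

    if "concordance" in config.stages:
        genes = read_labeled_matrix(paths["genes"])
        pathway_defs = read_pathways(paths["pathways"])
        substrate_map = read_substrate_map(paths["map"])
        completions = completion_matrix(genes, pathway_defs)
        functionality = substrate_functionality(completions, substrate_map)
        mapped = [s for s in functionality.columns if s in calls.data.columns]
        counts = concordance(calls.data[mapped], functionality[mapped])
        deltas = estimate_deltas(calls.data[mapped], functionality[mapped])
        paths["concordance"] = outdir / "concordance.json"
        write_json_result(
            {
                "counts": counts.as_dict(),
                "delta_m": deltas.delta_m,
                "delta_p": deltas.delta_p,
                "n_pairs_m": deltas.n_pairs_m,
                "n_pairs_p": deltas.n_pairs_p,
            },
            paths["concordance"], seed=config.seed,
        )
        manifest.add(
            "concordance", params={},
            inputs={str(paths[k]): _sha256(paths[k]) for k in ("genes", "pathways", "map")},
            outputs={str(paths["concordance"]): _sha256(paths["concordance"])},
        )

    if "simulate" in config.stages:
        model = DecouplingModel(config.decoupling)
        res = model.simulate(seed=stage_seeds["simulate"])
        paths["pairs"] = outdir / "simulated_pairs.csv"
        with open(paths["pairs"], "w") as fh:
            fh.write(_header_comment(seed=stage_seeds["simulate"]))
            res.pairs.to_csv(fh, index=False)
        paths["simulation"] = outdir / "simulation.json"
        write_json_result(
            {"r2_dm_dg": res.r2_dm_dg, "r2_dp_dm": res.r2_dp_dm,
             "n_pairs": res.params.n_pairs, "n_pathways": len(res.params.pathway_sizes)},
            paths["simulation"], seed=stage_seeds["simulate"],
            decoupling=config.decoupling,
        )
        manifest.add(
            "simulate",
            params={"seed": stage_seeds["simulate"]},
            inputs={},
            outputs={str(paths[k]): _sha256(paths[k]) for k in ("pairs", "simulation")},
        )

    manifest.write(outdir / "manifest.json")
    return manifest
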