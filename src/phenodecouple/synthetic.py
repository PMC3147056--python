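"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a carbon-source utilisation study of a structured
bacterial species: a clade-structured phylogeny whose pairwise distances
span the observed range (0 to 0.25), per-pathway gene counts, strain x gene
functional states whose pairwise difference fraction tracks the gene-level
probability p_M(d_G; mu, Lambda), growth phenotypes decoupled from pathway
functionality through the (delta_M, delta_P) mechanism, and long-form plate
OD tables with a three-component mixture signature plus per-date block
effects and one control (blank) well per plate.

Everything flows from a single seed; ground truth (tree, gene states,
parameters, group labels) is returned alongside the data so that recovery
tests can close the loop.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .decoupling import (
    DecouplingParams,
    default_pathway_sizes,
    prob_functional_difference,
)
from .distances import DistanceMatrix, parse_newick, patristic_matrix, tree_to_newick
from .exceptions import InvalidConfigError, InvalidParameterError
from .pathways import CompletionMatrix, Pathway, completion_matrix

__all__ = [
    "SyntheticConfig",
    "TruthBundle",
    "gen_tree",
    "gen_pathway_sizes",
    "gen_gene_states",
    "gen_plate",
    "generate_dataset",
    "solve_flip_rates",
    "apply_phenotype_noise",
]

#: Default three-component mixture: (weight, mean OD, sd OD) per component —
#: two components near zero and one near one.
DEFAULT_MIXTURE = ((0.4, 0.02, 0.02), (0.2, 0.15, 0.08), (0.4, 1.00, 0.20))

PATHOGENIC_GROUPS = ("commensal", "ExPEC", "InPEC")
ANTHROPOGENIC_GROUPS = ("human", "pet", "farm", "wild")
DIETS = ("bird", "carnivore", "herbivore", "omnivore")


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the assay layout: 95 substrates per plate, 8 assay
    dates, a 395-pathway network, a three-component OD mixture and a
    maximum pairwise genetic distance of 0.25.
    """

    n_strains: int = 20
    n_substrates: int = 95
    n_pathways: int = 395
    n_dates: int = 8
    n_clades: int = 4
    n_replicates: int = 1
    mixture_spec: tuple = DEFAULT_MIXTURE
    date_effect_sd: float = 0.1
    pathway_size_law: tuple = ("poisson", 4.0, 20)
    max_genetic_distance: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "n_substrates", "n_pathways", "n_dates",
                     "n_clades", "n_replicates"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.n_clades > self.n_strains:
            raise InvalidConfigError("n_clades cannot exceed n_strains")
        if self.n_substrates > self.n_pathways:
            raise InvalidConfigError("need at least one pathway per substrate")
        weights = [w for w, _, _ in self.mixture_spec]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise InvalidConfigError("mixture weights must sum to 1")
        if any(sd <= 0 for _, _, sd in self.mixture_spec):
            raise InvalidConfigError("mixture sds must be positive")
        if self.date_effect_sd < 0:
            raise InvalidConfigError("date_effect_sd must be >= 0")


@dataclass
class TruthBundle:
    """Ground truth behind a synthetic cohort."""

    tree: dendropy.Tree
    gene_states: pd.DataFrame  # strain x gene, 1 = functional
    pathway_sizes: np.ndarray
    pathways: list[Pathway]
    substrate_map: dict[str, list[str]]
    true_params: DecouplingParams
    group_labels: pd.DataFrame  # strain -> the four grouping factors
    growth_states: pd.DataFrame | None = None  # strain x substrate, after delta noise
    date_of_strain: pd.Series | None = None
    date_offsets: dict | None = None

    @property
    def genetic_distance(self) -> DistanceMatrix:
        return patristic_matrix(self.tree)

    def completions(self) -> CompletionMatrix:
        return completion_matrix(self.gene_states, self.pathways)

    def functionality(self) -> pd.DataFrame:
        """True substrate usability (all mapped-pathway genes functional)."""
        from .pathways import substrate_functionality

        return substrate_functionality(self.completions(), self.substrate_map)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialise tree, gene matrix, pathway map and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["tree"] = outdir / "tree.nwk"
        paths["tree"].write_text(tree_to_newick(self.tree) + "\n")
        paths["genes"] = outdir / "gene_presence.csv"
        self.gene_states.rename_axis("strain").to_csv(paths["genes"])
        paths["pathways"] = outdir / "pathways.tsv"
        with open(paths["pathways"], "w") as fh:
            fh.write("pathway\tgenes\n")
            for pw in self.pathways:
                fh.write(f"{pw.id}\t{','.join(pw.genes)}\n")
        paths["map"] = outdir / "substrate_map.tsv"
        with open(paths["map"], "w") as fh:
            fh.write("substrate\tpathways\n")
            for sub, pws in self.substrate_map.items():
                fh.write(f"{sub}\t{','.join(pws)}\n")
        paths["metadata"] = outdir / "metadata.csv"
        self.group_labels.rename_axis("strain").to_csv(paths["metadata"])
        paths["truth"] = outdir / "truth.json"
        truth = {
            "mu": self.true_params.mu,
            "lambda": self.true_params.lam,
            "delta_m": self.true_params.delta_m,
            "delta_p": self.true_params.delta_p,
            "pathway_sizes": self.pathway_sizes.tolist(),
            "date_offsets": self.date_offsets,
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def gen_tree(
    n_strains: int,
    n_clades: int = 1,
    seed: int | None = None,
    max_distance: float = 0.25,
) -> dendropy.Tree:
    """Random clade-structured ultrametric tree, Newick-serialisable.

    Strains are split round-robin into clades; random coalescent-style
    merges build each clade with short heights and join clade roots with
    much larger heights, producing the bimodal intra-/inter-clade distance
    pattern of a structured species.  Branch lengths are scaled so the
    maximum patristic distance equals ``max_distance`` (single-leaf trees
    have no distances and are returned as-is).
    """
    if n_strains < 1:
        raise InvalidConfigError("n_strains must be >= 1")
    if n_clades < 1 or n_clades > n_strains:
        raise InvalidConfigError("need 1 <= n_clades <= n_strains")
    rng = np.random.default_rng(seed)
    labels = [f"S{i:03d}" for i in range(n_strains)]
    if n_strains == 1:
        return parse_newick(f"{labels[0]}:0.0;")

    clades: list[list[str]] = [[] for _ in range(n_clades)]
    for i, label in enumerate(labels):
        clades[i % n_clades].append(label)

    def _coalesce(items: list[tuple[str, float]], base: float, scale: float):
        """Random pairwise merges; returns (newick, height)."""
        items = list(items)
        height = base
        while len(items) > 1:
            height += rng.exponential(scale)
            i, j = rng.choice(len(items), size=2, replace=False)
            (na, ha), (nb, hb) = items[i], items[j]
            merged = (f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})", height)
            items = [it for idx, it in enumerate(items) if idx not in (i, j)]
            items.append(merged)
        return items[0]

    # intra-clade heights stay below 1; clade roots join between 5 and ~5+n.
    roots = []
    for members in clades:
        leaves = [(lbl, 0.0) for lbl in members]
        if len(leaves) == 1:
            roots.append(leaves[0])
        else:
            roots.append(_coalesce(leaves, 0.0, scale=1.0 / len(leaves) ** 2))
    root_height = max(h for _, h in roots)
    if len(roots) > 1:
        newick, _ = _coalesce(roots, base=max(5.0, root_height + 5.0), scale=0.5)
    else:
        newick, _ = roots[0]
    tree = parse_newick(newick + ";")

    dg = patristic_matrix(tree)
    dmax = dg.values.max()
    if dmax > 0:
        factor = max_distance / dmax
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return tree


def gen_pathway_sizes(
    n_pathways: int, law: tuple | str = ("poisson", 4.0, 20), seed: int | None = None
) -> np.ndarray:
    """Per-pathway gene counts drawn from a configurable size law.

    Laws: ``("poisson", mean, trunc)`` gives ``1 + Poisson(mean)`` truncated
    at ``trunc`` (default mean 4, truncation 20 — right-skewed, mean 5);
    ``("constant", c)`` gives every pathway c genes.
    """
    if n_pathways < 1:
        raise InvalidParameterError("n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    if law == "default":
        law = ("poisson", 4.0, 20)
    kind = law[0]
    if kind == "constant":
        return np.full(n_pathways, int(law[1]), dtype=int)
    if kind == "poisson":
        mean, trunc = float(law[1]), int(law[2])
        if mean == 4.0 and trunc == 20:
            return default_pathway_sizes(n_pathways, rng=rng)
        sizes = 1 + rng.poisson(mean, size=n_pathways)
        return np.minimum(sizes, trunc).astype(int)
    raise InvalidParameterError(f"unknown pathway size law {law!r}")


# ---------------------------------------------------------------------------
# gene states
# ---------------------------------------------------------------------------


def gen_gene_states(
    tree: dendropy.Tree,
    pathway_sizes: np.ndarray,
    mu: float = 0.83,
    lam: float = 0.13,
    seed: int | None = None,
    baseline_functional: float = 0.95,
) -> tuple[pd.DataFrame, list[Pathway]]:
    """Binary functional gene states per strain, pairwise-faithful to p_M.

    Strains are visited in leaf order; the first draws each gene functional
    with the stationary probability ``baseline_functional`` (the
    core-genome-like share of intact genes) and each subsequent strain
    copies the gene states of its nearest already-visited neighbour (by
    patristic distance) and flips genes with state-dependent rates
    ``alpha = q / (2 pi1)`` (functional -> broken) and
    ``beta = q / (2 pi0)`` (broken -> restored), where
    ``q = p_M(d; mu, Lambda)`` for the attachment distance d.  Detailed
    balance makes the marginal functional fraction stationary (no drift
    down the strain chain) while the pairwise difference probability for
    each attachment pair is exactly q; other pairs track q approximately
    but monotonically.  The construction is deliberately not
    tree-consistent.

    Returns the strain x gene matrix and the pathway definitions (genes
    are assigned to pathways in contiguous blocks).
    """
    if not (0.0 <= mu <= 1.0) or not (0.0 <= lam <= 1.0):
        raise InvalidParameterError("mu and lambda must lie in [0, 1]")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise InvalidParameterError("need a tree with >= 2 leaves")
    rng = np.random.default_rng(seed)
    dg = patristic_matrix(tree)
    strains = dg.labels
    sizes = np.asarray(pathway_sizes, dtype=int)
    n_genes = int(sizes.sum())
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    pathways = []
    start = 0
    for j, size in enumerate(sizes):
        pathways.append(Pathway(id=f"p{j:04d}", genes=tuple(gene_ids[start : start + size])))
        start += size

    pi1 = float(baseline_functional)
    pi0 = 1.0 - pi1
    q_max = prob_functional_difference(float(dg.values.max()), mu, lam)
    if pi0 > 0 and q_max > 2.0 * pi0:
        raise InvalidParameterError(
            f"pairwise difference probability {q_max:.3f} exceeds 2*(1-baseline) "
            f"= {2 * pi0:.3f}; raise 1 - baseline_functional"
        )
    states = np.empty((len(strains), n_genes), dtype=np.int8)
    states[0] = (rng.random(n_genes) < pi1).astype(np.int8)
    visited = [0]
    for i in range(1, len(strains)):
        d_row = dg.values[i, visited]
        nearest = visited[int(np.argmin(d_row))]
        q = prob_functional_difference(float(dg.values[i, nearest]), mu, lam)
        if q == 0.0 or pi0 == 0.0:
            flip_prob = np.full(n_genes, q)
        else:
            flip_prob = np.where(states[nearest] == 1, q / (2 * pi1), q / (2 * pi0))
        flips = rng.random(n_genes) < flip_prob
        states[i] = states[nearest] ^ flips
        visited.append(i)
    frame = pd.DataFrame(states, index=strains, columns=gene_ids)
    return frame, pathways


# ---------------------------------------------------------------------------
# phenotype decoupling noise
# ---------------------------------------------------------------------------


def solve_flip_rates(
    functionality: pd.DataFrame, delta_m: float, delta_p: float
) -> tuple[float, float]:
    """Per-cell flip rates realising the target pairwise (delta_M, delta_P).

    The phenotype of each (strain, substrate) cell is the functionality
    boolean flipped independently with probability ``a`` when the pathway
    is absent (ghost growth) and ``b`` when it is complete (silent
    pathway).  For a strain pair the conditionals are then

        delta_M = a + b - 2ab
        delta_P = f * 2b(1-b) + (1-f) * 2a(1-a)

    where f is the fraction of concordant-functionality (pair, substrate)
    cells in which the pathway is complete on both sides.  Solved for
    (a, b) by bisection on b; raises when the functionality structure makes
    the targets unreachable.
    """
    m = functionality.to_numpy().astype(bool)
    s = m.shape[0]
    if s < 2:
        raise InvalidParameterError("need >= 2 strains to calibrate flip rates")
    n11 = n00 = 0
    for i in range(s):
        for j in range(i + 1, s):
            same = m[i] == m[j]
            n11 += int((same & m[i] & m[j]).sum())
            n00 += int((same & ~m[i] & ~m[j]).sum())
    if n11 + n00 == 0:
        raise InvalidParameterError("no concordant-functionality cells; cannot calibrate")
    f = n11 / (n11 + n00)

    def a_of(b: float) -> float:
        return (delta_m - b) / (1.0 - 2.0 * b)

    def g(b: float) -> float:
        a = a_of(b)
        return f * 2 * b * (1 - b) + (1 - f) * 2 * a * (1 - a) - delta_p

    b_max = min(0.499, delta_m)
    # restrict to b where a(b) stays in [0, 1]
    while b_max > 1e-9 and not (0.0 <= a_of(b_max) <= 1.0):
        b_max *= 0.95
    if g(0.0) * g(b_max) > 0:
        raise InvalidParameterError(
            f"targets delta_M={delta_m}, delta_P={delta_p} unreachable for this "
            f"functionality structure (complete-pathway cell fraction f={f:.3f})"
        )
    b = brentq(g, 0.0, b_max, xtol=1e-12)
    return a_of(b), b


def apply_phenotype_noise(
    functionality: pd.DataFrame,
    delta_m: float,
    delta_p: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Growth states decoupled from functionality at the target rates."""
    a, b = solve_flip_rates(functionality, delta_m, delta_p)
    rng = np.random.default_rng(seed)
    m = functionality.to_numpy().astype(bool)
    flip_prob = np.where(m, b, a)
    flips = rng.random(m.shape) < flip_prob
    return pd.DataFrame(m ^ flips, index=functionality.index, columns=functionality.columns)


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------


def gen_plate(truth: TruthBundle, config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Long-form plate OD table for a synthetic cohort.

    Wells of substrates the strain can use draw OD from the high-mean
    mixture component; other wells draw from the weight-renormalised pair
    of low components.  Per-date offsets (the batch effect) are added to
    growth wells only — the control well reads the baseline component, so
    blank subtraction does not silently absorb the date effect.  Each plate
    carries exactly one blank record.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    growth = truth.growth_states if truth.growth_states is not None else truth.functionality()
    strains = list(growth.index)
    substrates = list(growth.columns)
    if len(strains) != config.n_strains:
        raise InvalidConfigError("truth and config disagree on strain count")

    weights = np.array([w for w, _, _ in config.mixture_spec])
    means = np.array([m for _, m, _ in config.mixture_spec])
    sds = np.array([s for _, _, s in config.mixture_spec])
    order = np.argsort(means)
    low = order[:-1]
    high = order[-1]
    w_low = weights[low] / weights[low].sum()

    dates = [f"d{k + 1}" for k in range(config.n_dates)]
    date_of_strain = truth.date_of_strain
    if date_of_strain is None:
        # randomised block design: strains shuffled before being split into
        # date blocks, so assay date is not confounded with clade structure
        shuffled = rng.permutation(len(strains))
        assignment = np.empty(len(strains), dtype=int)
        assignment[shuffled] = np.arange(len(strains)) * config.n_dates // len(strains)
        date_of_strain = pd.Series([dates[a] for a in assignment], index=strains)
    offsets = truth.date_offsets
    if offsets is None:
        offsets = dict(zip(dates, rng.normal(0.0, config.date_effect_sd, len(dates))))
    truth.date_of_strain = date_of_strain
    truth.date_offsets = {k: float(v) for k, v in offsets.items()}

    records = []
    for strain in strains:
        date = date_of_strain[strain]
        offset = offsets[date]
        for rep in range(1, config.n_replicates + 1):
            comp = np.where(
                growth.loc[strain].to_numpy(),
                high,
                low[rng.choice(len(low), size=len(substrates), p=w_low)],
            )
            od = rng.normal(means[comp], sds[comp]) + offset
            for sub, val in zip(substrates, od):
                records.append((strain, sub, date, rep, float(val), False))
            blank = rng.normal(means[order[0]], sds[order[0]])
            records.append((strain, "control", date, rep, float(blank), True))
    return pd.DataFrame(
        records, columns=["strain", "substrate", "date", "replicate", "od", "is_blank"]
    )


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------


def generate_dataset(config: SyntheticConfig) -> tuple[TruthBundle, pd.DataFrame]:
    """Generate a full synthetic cohort: truth bundle plus plate table.

    Child seeds for tree, sizes, gene states, phenotype noise, grouping
    labels and plate noise are all derived from ``config.seed``.
    """
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=6)
    params = DecouplingParams(n_pathways=config.n_pathways)

    tree = gen_tree(
        config.n_strains, config.n_clades, seed=int(seeds[0]),
        max_distance=config.max_genetic_distance,
    )
    sizes = gen_pathway_sizes(config.n_pathways, config.pathway_size_law, seed=int(seeds[1]))
    gene_states, pathways = gen_gene_states(
        tree, sizes, mu=params.mu, lam=params.lam, seed=int(seeds[2])
    )
    substrate_map = {
        f"c{j:03d}": [pathways[j].id] for j in range(config.n_substrates)
    }
    params = DecouplingParams(pathway_sizes=sizes)
    truth = TruthBundle(
        tree=tree,
        gene_states=gene_states,
        pathway_sizes=sizes,
        pathways=pathways,
        substrate_map=substrate_map,
        true_params=params,
        group_labels=_group_labels(tree, seed=int(seeds[3])),
    )
    functionality = truth.functionality()
    try:
        truth.growth_states = apply_phenotype_noise(
            functionality, params.delta_m, params.delta_p, seed=int(seeds[4])
        )
    except InvalidParameterError as exc:
        # targets unreachable for this functionality draw: fall back to the
        # noiseless map so the cohort is still usable end to end
        logging.getLogger(__name__).warning(
            "phenotype-noise targets unreachable (%s); growth follows functionality", exc
        )
        truth.growth_states = functionality
    plate = gen_plate(truth, config, seed=int(seeds[5]))
    return truth, plate


def _group_labels(tree: dendropy.Tree, seed: int | None = None) -> pd.DataFrame:
    """Grouping factors per strain: clade-derived genetic group + lifestyles."""
    rng = np.random.default_rng(seed)
    dg = patristic_matrix(tree)
    strains = dg.labels
    # clades recovered from the distance structure: strains closer than the
    # midpoint of the overall range share a genetic group
    n = len(strains)
    threshold = dg.values.max() / 2 if n > 1 else 0.0
    group = [-1] * n
    current = 0
    for i in range(n):
        if group[i] >= 0:
            continue
        group[i] = current
        for j in range(i + 1, n):
            if group[j] < 0 and dg.values[i, j] < threshold:
                group[j] = current
        current += 1
    letters = ["A/B1", "B2", "D", "E"]
    genetic = [letters[g % len(letters)] if current > 1 else "A/B1" for g in group]
    return pd.DataFrame(
        {
            "genetic_group": genetic,
            "pathogenic_group": rng.choice(PATHOGENIC_GROUPS, size=n, p=(0.6, 0.2, 0.2)),
            "anthropogenic_group": rng.choice(ANTHROPOGENIC_GROUPS, size=n),
            "diet": rng.choice(DIETS, size=n),
        },
        index=strains,
    )
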