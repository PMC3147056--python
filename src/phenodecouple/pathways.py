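"""Pathway completion, growth-vs-pathway concordance and the delta estimates.

A metabolic pathway is summarised per strain by its *completion fraction*:
the share of its enzyme-coding genes present in the genome.  A pathway is
*functional* only when complete (all genes present), and a strain can use a
substrate when at least one of the substrate's mapped degradation pathways
is functional.

Comparing binary growth calls with predicted functionality per
(strain, substrate) cell yields four categories — the two coherent ones
(no growth with an incomplete pathway, growth with a complete one) and the
two discrepancies (growth without the pathway, no growth despite it).  The
pairwise discrepancy probabilities

    delta_M = P(Delta_P = 0 | Delta_M != 0)
    delta_P = P(Delta_P != 0 | Delta_M = 0)

are estimated per unordered strain pair and averaged over the pairs that
contribute to each conditioning event.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, euclidean_matrix
from .exceptions import InvalidParameterError

__all__ = [
    "Pathway",
    "CompletionMatrix",
    "ConcordanceCounts",
    "DeltaEstimates",
    "completion_fraction",
    "completion_matrix",
    "substrate_functionality",
    "concordance",
    "estimate_deltas",
    "metabolic_distance",
]


@dataclass(frozen=True)
class Pathway:
    """A pathway and its enzyme-coding genes."""

    id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise InvalidParameterError(f"pathway {self.id} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidParameterError(f"pathway {self.id} has duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class CompletionMatrix:
    """Strain x pathway completion fractions plus per-pathway gene counts."""

    data: pd.DataFrame  # strains x pathways, values in [0, 1]
    gene_counts: pd.Series  # pathway -> n genes

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1) or np.isnan(vals).any():
            raise InvalidParameterError("completion fractions must lie in [0, 1]")
        missing = set(self.data.columns) - set(self.gene_counts.index)
        if missing:
            raise InvalidParameterError(f"pathways without gene counts: {sorted(missing)}")


def completion_fraction(genes_present: set, pathway: Pathway) -> float:
    """Fraction of the pathway's genes present: |present ∩ pathway| / n."""
    return len(genes_present.intersection(pathway.genes)) / pathway.n_genes


def completion_matrix(
    gene_presence: pd.DataFrame, pathways: list[Pathway]
) -> CompletionMatrix:
    """Completion fractions for every strain x pathway.

    Parameters
    ----------
    gene_presence : DataFrame
        Strain x gene 0/1 indicators of functional gene presence.
    """
    data = {}
    for pw in pathways:
        missing = [g for g in pw.genes if g not in gene_presence.columns]
        if missing:
            raise InvalidParameterError(
                f"pathway {pw.id} references unknown genes {missing[:5]}"
            )
        data[pw.id] = gene_presence[list(pw.genes)].mean(axis=1)
    counts = pd.Series({pw.id: pw.n_genes for pw in pathways}, name="n_genes")
    return CompletionMatrix(data=pd.DataFrame(data, index=gene_presence.index), gene_counts=counts)


def substrate_functionality(
    completions: CompletionMatrix, substrate_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Predicted ability to use each substrate, per strain.

    A substrate is usable when *any* of its mapped degradation pathways has
    completion exactly 1 (all enzyme-coding genes present).

    Raises
    ------
    InvalidParameterError
        For substrates mapped to no pathway, or to unknown pathways.
    """
    out = {}
    for substrate, pathway_ids in substrate_map.items():
        if len(pathway_ids) == 0:
            raise InvalidParameterError(f"substrate {substrate} maps to no pathway")
        unknown = [p for p in pathway_ids if p not in completions.data.columns]
        if unknown:
            raise InvalidParameterError(
                f"substrate {substrate} maps to unknown pathways {unknown}"
            )
        complete = completions.data[list(pathway_ids)].to_numpy() >= 1.0
        out[substrate] = complete.any(axis=1)
    return pd.DataFrame(out, index=completions.data.index)


@dataclass
class ConcordanceCounts:
    """The four growth-vs-pathway categories over all scored cells."""

    coherent_no_growth_incomplete: int
    coherent_growth_complete: int
    growth_without_pathway: int
    no_growth_with_pathway: int

    @property
    def total(self) -> int:
        return (
            self.coherent_no_growth_incomplete
            + self.coherent_growth_complete
            + self.growth_without_pathway
            + self.no_growth_with_pathway
        )

    @property
    def percent_coherent(self) -> float:
        """Share of coherent cells, in percent."""
        if self.total == 0:
            raise InvalidParameterError("no scored cells")
        return (
            100.0
            * (self.coherent_no_growth_incomplete + self.coherent_growth_complete)
            / self.total
        )

    def as_dict(self) -> dict:
        return {
            "coherent_no_growth_incomplete": self.coherent_no_growth_incomplete,
            "coherent_growth_complete": self.coherent_growth_complete,
            "growth_without_pathway": self.growth_without_pathway,
            "no_growth_with_pathway": self.no_growth_with_pathway,
            "total": self.total,
            "percent_coherent": self.percent_coherent,
        }


def concordance(calls, functionality: pd.DataFrame) -> ConcordanceCounts:
    """Classify every (strain, substrate) cell into the four categories.

    Only substrates present in the functionality table (i.e. mapped to a
    degradation pathway) are scored.

    Parameters
    ----------
    calls : GrowthCalls or DataFrame
        Binary growth matrix.
    """
    calls_df = calls.data if hasattr(calls, "data") else calls
    if not set(functionality.index) == set(calls_df.index):
        raise InvalidParameterError("strain registries differ between calls and functionality")
    substrates = [s for s in functionality.columns if s in calls_df.columns]
    if len(substrates) < len(functionality.columns):
        missing = sorted(set(functionality.columns) - set(calls_df.columns))
        raise InvalidParameterError(f"substrates missing from growth calls: {missing}")
    g = calls_df.loc[functionality.index, substrates].to_numpy().astype(bool)
    f = functionality[substrates].to_numpy().astype(bool)
    return ConcordanceCounts(
        coherent_no_growth_incomplete=int((~g & ~f).sum()),
        coherent_growth_complete=int((g & f).sum()),
        growth_without_pathway=int((g & ~f).sum()),
        no_growth_with_pathway=int((~g & f).sum()),
    )


@dataclass
class DeltaEstimates:
    """Pairwise discrepancy probabilities between functionality and growth.

    ``delta_m`` / ``delta_p`` are unweighted means over the strain pairs
    that contribute to each conditioning set; a value is None when no pair
    contributes (flagged, never silently zero).
    """

    delta_m: float | None
    delta_p: float | None
    per_pair_m: pd.Series
    per_pair_p: pd.Series

    @property
    def n_pairs_m(self) -> int:
        return int(self.per_pair_m.notna().sum())

    @property
    def n_pairs_p(self) -> int:
        return int(self.per_pair_p.notna().sum())

    def standard_errors(self) -> tuple[float | None, float | None]:
        """Monte-Carlo s.e. of the two pair averages."""
        def _se(s: pd.Series):
            v = s.dropna()
            return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else None

        return _se(self.per_pair_m), _se(self.per_pair_p)


def estimate_deltas(
    calls, functionality: pd.DataFrame, mode: str = "pair_average"
) -> DeltaEstimates:
    """Estimate delta_M and delta_P from calls and predicted functionality.

    For each unordered strain pair and each mapped substrate,
    ``Delta_M != 0`` iff the functionality booleans differ and
    ``Delta_P != 0`` iff the growth calls differ.  Pair-level
    ``delta_M`` is the fraction of Delta_M != 0 substrates with
    Delta_P = 0, and ``delta_P`` the fraction of Delta_M = 0 substrates
    with Delta_P != 0.  Pairs whose conditioning set is empty are skipped
    for that quantity.

    Parameters
    ----------
    mode : {"pair_average", "pooled"}
        ``pair_average`` (default) averages the pair-level fractions;
        ``pooled`` pools cells over all pairs before dividing.
    """
    calls_df = calls.data if hasattr(calls, "data") else calls
    if set(functionality.index) != set(calls_df.index):
        raise InvalidParameterError("strain registries differ between calls and functionality")
    strains = list(functionality.index)
    if len(strains) < 2:
        raise InvalidParameterError("need at least 2 strains")
    substrates = list(functionality.columns)
    if len(substrates) < 1:
        raise InvalidParameterError("need at least 1 mapped substrate")
    g = calls_df.loc[strains, substrates].to_numpy().astype(bool)
    f = functionality[substrates].to_numpy().astype(bool)

    pairs = list(itertools.combinations(range(len(strains)), 2))
    idx = [f"{strains[i]}|{strains[j]}" for i, j in pairs]
    dm_vals = np.full(len(pairs), np.nan)
    dp_vals = np.full(len(pairs), np.nan)
    pooled = np.zeros(4)  # dM!=0 & dP=0, dM!=0 total, dM=0 & dP!=0, dM=0 total
    for k, (i, j) in enumerate(pairs):
        dmask = f[i] != f[j]
        pmask = g[i] != g[j]
        n_diff = dmask.sum()
        n_same = (~dmask).sum()
        if n_diff > 0:
            dm_vals[k] = (dmask & ~pmask).sum() / n_diff
        if n_same > 0:
            dp_vals[k] = (~dmask & pmask).sum() / n_same
        pooled += [(dmask & ~pmask).sum(), n_diff, (~dmask & pmask).sum(), n_same]

    per_pair_m = pd.Series(dm_vals, index=idx, name="delta_m")
    per_pair_p = pd.Series(dp_vals, index=idx, name="delta_p")
    if mode == "pair_average":
        delta_m = float(per_pair_m.mean()) if per_pair_m.notna().any() else None
        delta_p = float(per_pair_p.mean()) if per_pair_p.notna().any() else None
    elif mode == "pooled":
        delta_m = float(pooled[0] / pooled[1]) if pooled[1] > 0 else None
        delta_p = float(pooled[2] / pooled[3]) if pooled[3] > 0 else None
    else:
        raise InvalidParameterError(f"unknown delta-estimation mode {mode!r}")
    return DeltaEstimates(
        delta_m=delta_m, delta_p=delta_p, per_pair_m=per_pair_m, per_pair_p=per_pair_p
    )


def metabolic_distance(completions: CompletionMatrix) -> DistanceMatrix:
    """d_M: Euclidean distance between strains' pathway-completion vectors."""
    return euclidean_matrix(completions.data, role="metabolic")
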