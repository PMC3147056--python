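"""Probabilistic genotype-phenotype decoupling model and its Monte Carlo.

The model describes how the genetic distance d_G between two bacterial
strains propagates — or fails to propagate — into a metabolic phenotypic
distance d_P, through the completion of metabolic pathways.

Three stacked probabilities:

1. *Gene level.*  Two strains at genetic distance d_G (the proportion of
   genes not identical by descent) differ functionally at a given gene with
   probability

       p_M = (1 - mu) * [1 - (1 - d_G) * (1 - Lambda)]

   where ``Lambda`` is the probability of a difference acquired by
   horizontal transfer independently of phylogeny, and ``mu`` the
   probability that a genetic difference leaves gene function unchanged.

2. *Pathway level.*  A pathway of n genes is functional only if all n genes
   are functional, so the two strains differ in pathway functionality
   (Delta_M != 0) with probability

       P(Delta_M != 0) = 1 - (1 - p_M)^n .

3. *Phenotype level.*  Regulatory effects and unknown enzymes decouple
   growth from gene content.  ``delta_M = P(Delta_P = 0 | Delta_M != 0)``
   is the probability of sharing a growth phenotype despite differing
   pathway functionality; ``delta_P = P(Delta_P != 0 | Delta_M = 0)`` the
   probability of differing phenotypes despite identical functionality.
   Hence

       P(Delta_P != 0) = (1 - delta_M) * P(Delta_M != 0)
                         + delta_P * (1 - P(Delta_M != 0)) .

The Monte Carlo draws strain pairs with d_G ~ Uniform(dG_range), binomial
per-pathway counts of functionally differing genes, and Bernoulli phenotype
differences, then reports the squared Pearson correlations R²(d_M, d_G) and
R²(d_P, d_M) — the signature of a strong gene-content signal coexisting
with a weak phenotypic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DegenerateMatrixError, InvalidParameterError

__all__ = [
    "DecouplingParams",
    "DecouplingModel",
    "DecouplingResults",
    "prob_functional_difference",
    "prob_pathway_difference",
    "prob_phenotype_difference",
    "r_squared",
    "default_pathway_sizes",
]

#: Default per-pathway gene-count law: 1 + Poisson(mean 4), truncated at 20.
SIZE_LAW_POISSON_MEAN = 4.0
SIZE_LAW_TRUNCATION = 20


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0) or not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")


def default_pathway_sizes(
    n_pathways: int = 395, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw per-pathway gene counts from the default right-skewed law.

    ``1 + Poisson(4)`` truncated at 20: mean 5 genes, all sizes in [1, 20].
    A stand-in for the unpublished gene counts of the 395-pathway network.
    """
    if n_pathways < 1:
        raise InvalidParameterError("n_pathways must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes = 1 + rng.poisson(SIZE_LAW_POISSON_MEAN, size=n_pathways)
    return np.minimum(sizes, SIZE_LAW_TRUNCATION).astype(int)


def prob_functional_difference(d_g, mu: float = 0.83, lam: float = 0.13):
    """Probability p_M that a gene differs functionally between two strains.

    Increasing in d_G and Lambda, decreasing in mu; 0 when mu = 1.
    Accepts scalars or arrays of d_G.
    """
    _check_prob("d_G", d_g)
    _check_prob("mu", mu)
    _check_prob("lambda", lam)
    d = np.asarray(d_g, dtype=float)
    p = (1.0 - mu) * (1.0 - (1.0 - d) * (1.0 - lam))
    return float(p) if np.isscalar(d_g) else p


def prob_pathway_difference(p_m, n):
    """Probability that a pathway of n genes differs in functionality.

    All n genes must be functional for the pathway to work, so any
    functional gene difference flips the pathway: 1 - (1 - p_M)^n.
    """
    _check_prob("p_M", p_m)
    n_arr = np.asarray(n)
    if np.any(n_arr < 0) or not np.issubdtype(n_arr.dtype, np.integer):
        raise InvalidParameterError("pathway gene count n must be a nonnegative integer")
    out = 1.0 - (1.0 - np.asarray(p_m, dtype=float)) ** n_arr
    return float(out) if out.ndim == 0 else out


def prob_phenotype_difference(p_dm, delta_m: float = 0.63, delta_p: float = 0.21):
    """Probability of a growth-phenotype difference on a substrate.

    Mixture of the two discrepancy channels: with differing pathway
    functionality the phenotypes differ with probability 1 - delta_M, with
    identical functionality they differ with probability delta_P.
    """
    _check_prob("P(Delta_M != 0)", p_dm)
    _check_prob("delta_M", delta_m)
    _check_prob("delta_P", delta_p)
    p = np.asarray(p_dm, dtype=float)
    out = (1.0 - delta_m) * p + delta_p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def r_squared(x, y) -> float:
    """Squared Pearson correlation (= R² of the least-squares line)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidParameterError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateMatrixError("constant input to r_squared")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


@dataclass
class DecouplingParams:
    """Parameters of the decoupling model.

    Defaults are the values used for the 10 000-pair simulation over the
    395-pathway network: mu = 0.83 and Lambda = 0.13 from the literature,
    delta_M = 0.63 and delta_P = 0.21 estimated from the 14 sequenced
    strains, d_G uniform on [0, 0.25] matching the observed range.
    """

    mu: float = 0.83
    lam: float = 0.13
    delta_m: float = 0.63
    delta_p: float = 0.21
    dg_range: tuple[float, float] = (0.0, 0.25)
    pathway_sizes: np.ndarray | None = None
    n_pathways: int = 395
    n_pairs: int = 10_000

    def __post_init__(self) -> None:
        for name in ("mu", "lam", "delta_m", "delta_p"):
            _check_prob(name, getattr(self, name))
        lo, hi = self.dg_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidParameterError(f"dg_range {self.dg_range} must be within [0, 1]")
        if self.n_pairs < 1:
            raise InvalidParameterError("n_pairs must be >= 1")
        if self.pathway_sizes is not None:
            self.pathway_sizes = np.asarray(self.pathway_sizes, dtype=int)
            if np.any(self.pathway_sizes < 1):
                raise InvalidParameterError("pathway sizes must be >= 1")
            self.n_pathways = int(len(self.pathway_sizes))
        elif self.n_pathways < 1:
            raise InvalidParameterError("n_pathways must be >= 1")

    def with_sizes(self, rng: np.random.Generator) -> "DecouplingParams":
        """Return a copy with pathway sizes materialised (drawn if absent)."""
        if self.pathway_sizes is not None:
            return self
        sizes = default_pathway_sizes(self.n_pathways, rng=rng)
        return replace(self, pathway_sizes=sizes)


class DecouplingModel:
    """Monte Carlo model of strain-pair divergence.

    Parameters
    ----------
    params : DecouplingParams
        Model parameters; ``params.pathway_sizes`` may be left unset, in
        which case sizes are drawn from the default law at simulation time.

    Examples
    --------
    >>> model = DecouplingModel(DecouplingParams(n_pairs=1000))
    >>> res = model.simulate(seed=0)
    >>> 0 < res.r2_dm_dg < 1
    True
    """

    def __init__(self, params: DecouplingParams | None = None) -> None:
        self.params = params if params is not None else DecouplingParams()

    def simulate(
        self, seed: int | None = None, completion_split: bool = True
    ) -> "DecouplingResults":
        """Simulate strain pairs and their three distances.

        For each pair: d_G ~ Uniform(dg_range); p_M from the gene-level
        probability; per pathway j the count k_j of functionally differing
        genes ~ Binomial(n_j, p_M).  The pathway-functionality difference
        indicator is Delta_M_j = [k_j > 0], and the phenotype difference
        Delta_P_j ~ Bernoulli(1 - delta_M) where Delta_M_j else
        Bernoulli(delta_P); d_P = sqrt(sum_j Delta_P_j) with one substrate
        per pathway.

        ``completion_split`` controls how the k_j differing genes map into
        the two strains' completion fractions: when True (default) they are
        split Binomial(k_j, 1/2) between the strains and the per-pathway
        completion difference is |k_A - k_B| / n_j; when False all k_j
        differences are charged to one strain (contribution k_j / n_j, an
        upper bound).  d_M = sqrt(sum_j contribution_j**2).
        """
        p = self.params
        rng = np.random.default_rng(seed)
        p = p.with_sizes(rng)
        sizes = p.pathway_sizes
        n_pairs, n_pw = p.n_pairs, len(sizes)

        d_g = rng.uniform(p.dg_range[0], p.dg_range[1], size=n_pairs)
        p_m = prob_functional_difference(d_g, p.mu, p.lam)
        k = rng.binomial(sizes[None, :], p_m[:, None])
        if completion_split:
            k_a = rng.binomial(k, 0.5)
            contrib = np.abs(2 * k_a - k) / sizes[None, :]
        else:
            contrib = k / sizes[None, :]
        d_m = np.sqrt((contrib**2).sum(axis=1))
        delta_m_ind = k > 0
        p_flip = np.where(delta_m_ind, 1.0 - p.delta_m, p.delta_p)
        delta_p_ind = rng.random((n_pairs, n_pw)) < p_flip
        d_p = np.sqrt(delta_p_ind.sum(axis=1).astype(float))

        pairs = pd.DataFrame({"d_G": d_g, "d_M": d_m, "d_P": d_p})
        return DecouplingResults(
            params=p,
            seed=seed,
            completion_split=completion_split,
            pairs=pairs,
            gene_diff_counts=k.astype(np.int16),
            delta_m_indicators=delta_m_ind,
            delta_p_indicators=delta_p_ind,
        )


@dataclass
class DecouplingResults:
    """Simulated strain pairs and the derived distance correlations."""

    params: DecouplingParams
    seed: int | None
    completion_split: bool
    pairs: pd.DataFrame
    gene_diff_counts: np.ndarray
    delta_m_indicators: np.ndarray
    delta_p_indicators: np.ndarray

    @property
    def r2_dm_dg(self) -> float:
        """R² between metabolic pathway distance d_M and genetic distance d_G."""
        return r_squared(self.pairs["d_M"], self.pairs["d_G"])

    @property
    def r2_dp_dm(self) -> float:
        """R² between phenotypic distance d_P and pathway distance d_M."""
        return r_squared(self.pairs["d_P"], self.pairs["d_M"])

    def analytic_pathway_difference_rates(self) -> np.ndarray:
        """Per-pathway P(Delta_M != 0) averaged over the simulated d_G draws."""
        p = self.params
        p_m = prob_functional_difference(self.pairs["d_G"].to_numpy(), p.mu, p.lam)
        return prob_pathway_difference(p_m[:, None], p.pathway_sizes[None, :]).mean(axis=0)

    def analytic_phenotype_difference_rates(self) -> np.ndarray:
        """Per-pathway P(Delta_P != 0) averaged over the simulated d_G draws."""
        p = self.params
        return prob_phenotype_difference(
            self.analytic_pathway_difference_rates(), p.delta_m, p.delta_p
        )

    def binned_means(self, by: str = "d_G", value: str = "d_M", bins: int = 10) -> pd.Series:
        """Mean of one distance within quantile bins of another."""
        q = pd.qcut(self.pairs[by], bins, duplicates="drop")
        return self.pairs.groupby(q, observed=True)[value].mean()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Genotype-phenotype decoupling simulation",
            "========================================",
            f"pairs simulated      {p.n_pairs}",
            f"pathways             {len(p.pathway_sizes)} "
            f"(gene counts: mean {p.pathway_sizes.mean():.2f}, "
            f"range {p.pathway_sizes.min()}-{p.pathway_sizes.max()})",
            f"mu (neutral prob)    {p.mu}",
            f"Lambda (HGT prob)    {p.lam}",
            f"delta_M              {p.delta_m}",
            f"delta_P              {p.delta_p}",
            f"d_G range            [{p.dg_range[0]}, {p.dg_range[1]}]",
            f"seed                 {self.seed}",
            "",
            f"R²(d_M, d_G)         {self.r2_dm_dg:.4f}",
            f"R²(d_P, d_M)         {self.r2_dp_dm:.4f}",
            f"mean d_M             {self.pairs['d_M'].mean():.4f}",
            f"mean d_P             {self.pairs['d_P'].mean():.4f}",
        ]
        return "\n".join(lines)

    def plot(self, path=None):
        """Scatter plots of d_M vs d_G and d_P vs d_M with regression lines."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
        for ax, (xc, yc) in zip(axes, (("d_G", "d_M"), ("d_M", "d_P"))):
            x = self.pairs[xc]
            y = self.pairs[yc]
            ax.plot(x, y, ".", ms=2, alpha=0.2)
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 10)
            ax.plot(xs, a + b * xs, "k--")
            ax.set_xlabel(xc)
            ax.set_ylabel(yc)
            ax.set_title(f"R² = {r_squared(x, y):.3f}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
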