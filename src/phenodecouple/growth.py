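"""From raw phenotype-microarray OD readings to growth calls and group tests.

The observable is the *growth yield*: optical density at 750 nm after 18 h
on a single carbon source, minus the control-well (blank) OD of the same
plate, optionally corrected for the assay-date block effect.  Yields pooled
over strains and substrates follow a three-component Gaussian mixture (two
components near 0 OD — no growth and weak background signal — and one near
1 OD — growth); a strain is called positive on a substrate when its yield
strictly exceeds the threshold at which the non-growing part of the mixture
leaves only a chosen false-positive mass above it.

Per-substrate group structure (genetic group, pathogenic group, host
anthropogenic group, host diet) is tested with Type-III ANOVA under
sum-to-zero contrasts, pooled p-values are screened by Benjamini-Hochberg,
and least-square group means are reported for the retained effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    AmbiguousComponentsError,
    DegenerateFitError,
    DegenerateMatrixError,
    InvalidParameterError,
    MissingBlankError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PLATE_COLUMNS",
    "METADATA_FACTORS",
    "GrowthYieldMatrix",
    "GaussianMixtureFit",
    "GrowthCalls",
    "GrowthYieldMixture",
    "GrowthMixtureResults",
    "subtract_blank",
    "correct_date_effect",
    "fit_mixture",
    "growth_threshold",
    "call_growth",
    "anova_per_substrate",
    "bh_fdr",
    "pca_scores",
    "spline_growth_yield",
]

PLATE_COLUMNS = ("strain", "substrate", "date", "replicate", "od", "is_blank")

#: Metadata grouping factors used by the four-effect linear model.
METADATA_FACTORS = ("genetic_group", "pathogenic_group", "anthropogenic_group", "diet")


# ---------------------------------------------------------------------------
# yields
# ---------------------------------------------------------------------------


@dataclass
class GrowthYieldMatrix:
    """Corrected growth yields with provenance flags.

    Attributes
    ----------
    long : DataFrame
        One row per (strain, substrate, date, replicate) with column
        ``yield_od`` (blank-subtracted OD; negative values preserved).
    blank_subtracted, date_corrected : bool
        Provenance flags.
    """

    long: pd.DataFrame
    blank_subtracted: bool = True
    date_corrected: bool = False

    @property
    def data(self) -> pd.DataFrame:
        """Strain x substrate matrix, replicates and dates averaged."""
        return self.long.pivot_table(
            index="strain", columns="substrate", values="yield_od", aggfunc="mean"
        )

    @property
    def strains(self) -> list[str]:
        return sorted(self.long["strain"].unique())

    @property
    def substrates(self) -> list[str]:
        return sorted(self.long["substrate"].unique())


def subtract_blank(plate: pd.DataFrame) -> GrowthYieldMatrix:
    """Blank-subtract a long-form plate table.

    A plate is one (strain, date, replicate) combination and must carry
    exactly one control-well (blank) record; the growth yield of every
    substrate well on that plate is its OD minus the blank OD.

    Raises
    ------
    MissingBlankError
        Naming the offending plate if a blank is absent or duplicated.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise InvalidParameterError(f"plate table lacks columns {missing}")
    if not np.all(np.isfinite(plate["od"].to_numpy(dtype=float))):
        raise InvalidParameterError("plate OD readings must be finite")

    keys = ["strain", "date", "replicate"]
    blanks = plate[plate["is_blank"].astype(bool)]
    counts = blanks.groupby(keys, sort=False).size()
    for key, grp in plate.groupby(keys, sort=False):
        n_blank = counts.get(key, 0)
        if n_blank != 1:
            raise MissingBlankError(
                f"plate (strain={key[0]}, date={key[1]}, replicate={key[2]}) "
                f"has {n_blank} blank records, expected exactly 1"
            )
    blank_od = blanks.set_index(keys)["od"]
    wells = plate[~plate["is_blank"].astype(bool)].copy()
    wells["yield_od"] = (
        wells["od"].to_numpy()
        - blank_od.loc[pd.MultiIndex.from_frame(wells[keys])].to_numpy()
    )
    long = wells[["strain", "substrate", "date", "replicate", "yield_od"]].reset_index(
        drop=True
    )
    return GrowthYieldMatrix(long=long, blank_subtracted=True, date_corrected=False)


def correct_date_effect(
    yields: GrowthYieldMatrix, metadata: pd.DataFrame
) -> GrowthYieldMatrix:
    """Remove the assay-date block effect from the growth yields.

    Per substrate, a five-factor linear model (date + the four grouping
    factors) is fitted under sum-to-zero contrasts; the fitted date effects
    (which average zero across dates, preserving the grand mean) are
    subtracted.  Substrates observed on a single date are left unchanged.
    Applying the correction twice equals applying it once, because refitting
    on corrected data yields zero date effects.

    Parameters
    ----------
    metadata : DataFrame
        Indexed by strain, with the columns in :data:`METADATA_FACTORS`.
    """
    df = yields.long.merge(
        metadata[list(METADATA_FACTORS)], left_on="strain", right_index=True, how="left"
    )
    if df[list(METADATA_FACTORS)].isna().any().any():
        missing = sorted(set(yields.long["strain"]) - set(metadata.index))
        raise InvalidParameterError(f"strains missing from metadata: {missing}")

    corrected_parts = []
    for substrate, grp in df.groupby("substrate", sort=False):
        grp = grp.copy()
        dates = grp["date"].unique()
        if len(dates) < 2:
            corrected_parts.append(grp)
            continue
        terms = ["C(date, Sum)"]
        for factor in METADATA_FACTORS:
            if grp[factor].nunique() >= 2:
                terms.append(f"C({factor}, Sum)")
            else:
                logger.warning(
                    "substrate %s: factor %s has a single level, dropped from "
                    "the date-correction model",
                    substrate,
                    factor,
                )
        formula = "yield_od ~ " + " + ".join(terms)
        res = smf.ols(formula, data=grp).fit()
        effects = _sum_coded_effects(res, "date", dates)
        grp["yield_od"] = grp["yield_od"] - grp["date"].map(effects).to_numpy()
        corrected_parts.append(grp)

    long = (
        pd.concat(corrected_parts, ignore_index=True)[
            ["strain", "substrate", "date", "replicate", "yield_od"]
        ]
        .sort_index()
        .reset_index(drop=True)
    )
    return GrowthYieldMatrix(
        long=long, blank_subtracted=yields.blank_subtracted, date_corrected=True
    )


def _sum_coded_effects(res, factor: str, levels) -> dict:
    """Extract per-level effects of a Sum-coded factor from an OLS fit.

    With sum-to-zero contrasts the omitted (last) level's effect is minus
    the sum of the named ones, so the effects average zero over levels.
    """
    prefix = f"C({factor}, Sum)[S."
    named = {}
    for name, value in res.params.items():
        if name.startswith(prefix):
            level = name[len(prefix) : -1]
            named[level] = value
    effects = {}
    total = 0.0
    levels = [str(l) for l in levels]
    for level in levels:
        if level in named:
            effects[level] = named[level]
            total += named[level]
    omitted = [l for l in levels if l not in named]
    for level in omitted:
        effects[level] = -total / max(len(omitted), 1)
    return effects


# ---------------------------------------------------------------------------
# Gaussian mixture and growth threshold
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixtureFit:
    """A fitted univariate Gaussian mixture.

    ``order`` sorts components by ascending mean, so ``order[-1]`` indexes
    the "positive growth" component.  ``bic = -2 loglik + p ln(N)`` with
    ``p`` the number of free parameters.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    n: int
    equal_variance: bool = False
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def order(self) -> np.ndarray:
        return np.argsort(self.means)

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.sum(
            self.weights
            * norm.pdf(x[:, None], self.means[None, :], np.sqrt(self.variances)[None, :]),
            axis=1,
        )

    def component_posteriors(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        logp = np.log(self.weights) + norm.logpdf(
            x[:, None], self.means[None, :], np.sqrt(self.variances)[None, :]
        )
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def _em_once(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    equal_variance: bool,
    max_iter: int,
    tol: float,
    var_floor: float,
    jitter: float,
) -> GaussianMixtureFit:
    n = x.size
    q = (np.arange(k) + 0.5) / k
    means = np.quantile(x, q)
    if jitter > 0:
        means = means + rng.normal(0.0, jitter * (x.std() + 1e-12), size=k)
    variances = np.full(k, x.var() + 1e-12)
    weights = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    trace = []
    for it in range(1, max_iter + 1):
        log_resp = np.log(weights)[None, :] + norm.logpdf(
            x[:, None], means[None, :], np.sqrt(variances)[None, :]
        )
        log_norm = logsumexp(log_resp, axis=1)
        ll = float(log_norm.sum())
        # EM guarantee: the observed-data log-likelihood never decreases.
        if ll < prev_ll - 1e-8 * (1.0 + abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        trace.append(ll)
        if it > 1 and ll - prev_ll < tol * (1.0 + abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll

        resp = np.exp(log_resp - log_norm[:, None])
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        sq = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        if equal_variance:
            variances = np.full(k, sq.sum() / n)
        else:
            variances = sq / nk
        if np.any(variances < var_floor) or np.any(nk < 1e-10):
            raise DegenerateFitError(
                f"EM collapsed (K={k}): component variance below {var_floor}"
            )

    n_var = 1 if equal_variance else k
    n_params = (k - 1) + k + n_var
    bic = -2.0 * prev_ll + n_params * np.log(n)
    return GaussianMixtureFit(
        k=k,
        weights=weights,
        means=means,
        variances=variances,
        log_likelihood=prev_ll,
        bic=float(bic),
        n=n,
        equal_variance=equal_variance,
        n_iter=len(trace),
        loglik_trace=np.array(trace),
    )


def fit_mixture(
    values,
    k_candidates=(1, 2, 3, 4, 5),
    seed: int | None = 0,
    equal_variance: bool = False,
    max_iter: int = 500,
    tol: float = 1e-10,
    var_floor: float = 1e-8,
    max_restarts: int = 5,
) -> GaussianMixtureFit:
    """Fit Gaussian mixtures by EM and select the component count by BIC.

    Each candidate K is fitted from a quantile-based initialisation (means
    at evenly spaced quantiles, global variance, equal weights).  On
    degenerate collapse the fit restarts with jittered means up to
    ``max_restarts`` times before raising.  The fit with the lowest BIC
    wins; exact ties go to the smaller K.

    Raises
    ------
    DegenerateFitError
        If every restart for some candidate K collapses onto a variance
        below ``var_floor``.
    """
    x = np.asarray(values, dtype=float).ravel()
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if min(k_candidates) < 1:
        raise InvalidParameterError("component counts must be >= 1")
    if x.size < 10 * max(k_candidates):
        raise InvalidParameterError(
            f"need >= {10 * max(k_candidates)} values to consider K={max(k_candidates)}"
        )
    rng = np.random.default_rng(seed)

    best: GaussianMixtureFit | None = None
    for k in k_candidates:
        fit = None
        for attempt in range(max_restarts + 1):
            try:
                fit = _em_once(
                    x, k, rng, equal_variance, max_iter, tol, var_floor,
                    jitter=0.0 if attempt == 0 else 0.05 * attempt,
                )
                break
            except DegenerateFitError:
                if attempt == max_restarts:
                    raise
        assert fit is not None
        if best is None or fit.bic < best.bic:  # strict: ties keep smaller K
            best = fit
    return best


def growth_threshold(
    fit: GaussianMixtureFit, fpr: float = 0.05, method: str = "renormalized"
) -> float:
    """OD threshold above which growth is called positive.

    The positive component is the one with the strictly largest mean.  With
    the default ``"renormalized"`` method the threshold t solves
    ``P(X > t) = fpr`` where X follows the weight-renormalised mixture of
    the non-positive components — i.e. a non-grower exceeds t with
    probability ``fpr``.  The ``"posterior"`` alternative instead solves
    ``P(component = positive | x = t) = 1 - fpr`` under the full mixture.

    Raises
    ------
    AmbiguousComponentsError
        If the largest component mean is not unique.
    """
    if not (0.0 < fpr < 0.5):
        raise InvalidParameterError("fpr must lie in (0, 0.5)")
    if fit.k < 2:
        raise InvalidParameterError("need at least 2 components to set a threshold")
    order = fit.order
    pos = order[-1]
    if np.isclose(fit.means[pos], fit.means[order[-2]]):
        raise AmbiguousComponentsError(
            "positive component is ambiguous: largest mean is tied"
        )
    neg = np.array([i for i in range(fit.k) if i != pos])
    w = fit.weights[neg] / fit.weights[neg].sum()
    mu = fit.means[neg]
    sd = np.sqrt(fit.variances[neg])

    lo = float(np.min(fit.means) - 20 * np.max(np.sqrt(fit.variances)))
    hi = float(np.max(fit.means) + 20 * np.max(np.sqrt(fit.variances)))

    if method == "renormalized":

        def objective(t: float) -> float:
            return float(np.sum(w * norm.sf(t, mu, sd)) - fpr)

    elif method == "posterior":

        def objective(t: float) -> float:
            post = fit.component_posteriors(t)[0, pos]
            return float(post - (1.0 - fpr))

        # the posterior of the widest component also tends to 1 far in the
        # tails, so bracket the rightmost upward crossing explicitly
        grid = np.linspace(lo, hi, 1024)
        vals = np.array([objective(t) for t in grid])
        crossings = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
        if crossings.size == 0:
            raise InvalidParameterError(
                "no posterior crossing found; components may be inseparable"
            )
        i = crossings[-1]
        return float(brentq(objective, grid[i], grid[i + 1], xtol=1e-12))

    else:
        raise InvalidParameterError(f"unknown threshold method {method!r}")

    return float(brentq(objective, lo, hi, xtol=1e-12))


@dataclass
class GrowthCalls:
    """Binary growth matrix plus the threshold that produced it."""

    data: pd.DataFrame  # strain x substrate, int 0/1
    threshold: float
    fpr: float | None = None

    def substrate_summary(self) -> dict:
        """Counts of never-growing / always-growing / variably used substrates."""
        frac = self.data.mean(axis=0)
        return {
            "nongrowing": int((frac == 0.0).sum()),
            "common": int((frac == 1.0).sum()),
            "selective": int(((frac > 0.0) & (frac < 1.0)).sum()),
        }


def call_growth(yields, threshold: float, fpr: float | None = None) -> GrowthCalls:
    """Binary growth calls: positive iff yield strictly exceeds the threshold."""
    if not np.isfinite(threshold):
        raise InvalidParameterError("threshold must be finite")
    data = yields.data if isinstance(yields, GrowthYieldMatrix) else yields
    calls = (data > threshold).astype(int)
    return GrowthCalls(data=calls, threshold=float(threshold), fpr=fpr)


class GrowthYieldMixture:
    """Model object for the growth-yield mixture analysis.

    Pools corrected growth yields, fits Gaussian mixtures across candidate
    component counts and exposes the BIC-selected fit with its positivity
    threshold through a Results object.

    Examples
    --------
    >>> rng = np.random.default_rng(0)
    >>> x = np.concatenate([rng.normal(0, 0.05, 500), rng.normal(1, 0.2, 500)])
    >>> res = GrowthYieldMixture(x).fit(k_candidates=(1, 2), seed=0)
    >>> res.fit.k
    2
    """

    def __init__(self, values) -> None:
        self.values = np.asarray(values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("growth yields must be finite")

    def fit(
        self,
        k_candidates=(1, 2, 3, 4, 5),
        seed: int | None = 0,
        equal_variance: bool = False,
        fpr: float = 0.05,
    ) -> "GrowthMixtureResults":
        fit = fit_mixture(
            self.values, k_candidates=k_candidates, seed=seed, equal_variance=equal_variance
        )
        return GrowthMixtureResults(model=self, fit=fit, fpr=fpr)


@dataclass
class GrowthMixtureResults:
    """BIC-selected mixture fit plus threshold and diagnostics."""

    model: GrowthYieldMixture
    fit: GaussianMixtureFit
    fpr: float = 0.05

    def threshold(self, fpr: float | None = None, method: str = "renormalized") -> float:
        return growth_threshold(self.fit, fpr=self.fpr if fpr is None else fpr, method=method)

    def call(self, yields, fpr: float | None = None) -> GrowthCalls:
        fpr = self.fpr if fpr is None else fpr
        return call_growth(yields, self.threshold(fpr=fpr), fpr=fpr)

    def summary(self) -> str:
        f = self.fit
        order = f.order
        lines = [
            "Growth-yield Gaussian mixture",
            "=============================",
            f"observations         {f.n}",
            f"selected components  {f.k} (BIC {f.bic:.1f}, loglik {f.log_likelihood:.1f})",
            f"EM iterations        {f.n_iter}",
        ]
        for rank, i in enumerate(order, 1):
            lines.append(
                f"  component {rank}: weight {f.weights[i]:.3f}, "
                f"mean {f.means[i]:.4f} OD, sd {np.sqrt(f.variances[i]):.4f} OD"
            )
        try:
            t = self.threshold()
            lines.append(f"threshold ({self.fpr:.0%} FPR)  > {t:.4f} OD")
        except (InvalidParameterError, AmbiguousComponentsError):
            lines.append("threshold            undefined (single component)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-substrate group analysis
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Per-substrate Type-III ANOVA results.

    ``effects``: one row per (substrate, effect) with F, dfs, p-value and an
    ``estimable`` flag; ``r2``: model R² per substrate; ``lsmeans``: one row
    per (substrate, effect, level) with the least-square mean and its
    standard error.
    """

    effects: pd.DataFrame
    r2: pd.Series
    lsmeans: pd.DataFrame

    def significant(self, q: float = 0.001) -> pd.DataFrame:
        """Effects retained by BH-FDR at level q over all pooled p-values."""
        mask = bh_fdr(self.effects["p_value"].to_numpy(), q)
        return self.effects[mask]


def anova_per_substrate(
    yields: GrowthYieldMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    factors=METADATA_FACTORS,
    calls: GrowthCalls | None = None,
) -> AnovaTable:
    """Type-III ANOVA of growth yield on the grouping factors, per substrate.

    Substrates are analysed when at least one strain grows on them — either
    judged from ``calls`` when given, or from having any positive yield.
    Contrasts are sum-to-zero; F tests use the residual denominator.
    Rank-deficient designs mark the affected effects as non-estimable
    rather than dropping them silently.
    """
    data = yields.data if isinstance(yields, GrowthYieldMatrix) else yields
    merged = data.join(metadata[list(factors)], how="left")
    if merged[list(factors)].isna().any().any():
        missing = sorted(set(data.index) - set(metadata.index))
        raise InvalidParameterError(f"strains missing from metadata: {missing}")

    effect_rows = []
    r2 = {}
    lsmean_rows = []
    for substrate in data.columns:
        if calls is not None:
            if calls.data[substrate].sum() == 0:
                continue
        elif (data[substrate] <= 0).all():
            continue
        sub = merged[[substrate] + list(factors)].rename(columns={substrate: "y"}).dropna()
        usable = [f for f in factors if sub[f].nunique() >= 2]
        if not usable:
            continue
        formula = "y ~ " + " + ".join(f"C({f}, Sum)" for f in usable)
        res = smf.ols(formula, data=sub).fit()
        rank_ok = np.linalg.matrix_rank(res.model.exog) == res.model.exog.shape[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(res, typ=3)
        r2[substrate] = float(res.rsquared)
        for f in factors:
            term = f"C({f}, Sum)"
            if f not in usable or term not in table.index:
                effect_rows.append(
                    dict(substrate=substrate, effect=f, F=np.nan, df_num=np.nan,
                         df_den=np.nan, p_value=np.nan, estimable=False)
                )
                continue
            row = table.loc[term]
            estimable = rank_ok and np.isfinite(row["F"])
            effect_rows.append(
                dict(
                    substrate=substrate,
                    effect=f,
                    F=float(row["F"]),
                    df_num=float(row["df"]),
                    df_den=float(res.df_resid),
                    p_value=float(row["PR(>F)"]),
                    estimable=bool(estimable),
                )
            )
            if estimable:
                for level, (mean, se) in _lsmeans(res, f, sub[f].unique()).items():
                    lsmean_rows.append(
                        dict(substrate=substrate, effect=f, level=level,
                             lsmean=mean, se=se)
                    )

    return AnovaTable(
        effects=pd.DataFrame(effect_rows),
        r2=pd.Series(r2, name="r2"),
        lsmeans=pd.DataFrame(lsmean_rows),
    )


def _lsmeans(res, factor: str, levels) -> dict:
    """Least-square means and standard errors for each level of a factor.

    Under sum-to-zero coding the ls-mean of a level is the intercept plus
    the level's effect (other factors contribute zero at their average);
    the omitted level's effect is minus the sum of the named ones.
    """
    params = res.params
    cov = res.cov_params()
    names = list(params.index)
    prefix = f"C({factor}, Sum)[S."
    named_levels = [n[len(prefix) : -1] for n in names if n.startswith(prefix)]
    out = {}
    for level in [str(l) for l in levels]:
        L = np.zeros(len(names))
        L[names.index("Intercept")] = 1.0
        if level in named_levels:
            L[names.index(f"{prefix}{level}]")] = 1.0
        else:  # omitted level: effect = -sum of named effects
            for other in named_levels:
                L[names.index(f"{prefix}{other}]")] = -1.0
        mean = float(L @ params.to_numpy())
        se = float(np.sqrt(L @ cov.to_numpy() @ L))
        out[level] = (mean, se)
    return out


def bh_fdr(pvalues, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at FDR level q.

    Returns a boolean mask over the input p-values.  NaNs are never
    selected.  Empty input yields an empty selection.
    """
    if not (0.0 < q < 1.0):
        raise InvalidParameterError("q must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        mask[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return mask


# ---------------------------------------------------------------------------
# PCA and growth-curve amplitude
# ---------------------------------------------------------------------------


def pca_scores(yields: pd.DataFrame, scale: bool = False):
    """Principal-component scores of the strain x substrate yield matrix.

    Columns are centred; by default they are *not* variance-scaled, since
    all variables share OD units (set ``scale=True`` to standardise).
    Returns ``(scores, explained_variance_ratio)`` where scores is a
    DataFrame (strains x components) and the ratios sum to 1.
    """
    x = yields.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise InvalidParameterError("PCA needs at least 2 strains")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd > 0, sd, 1.0)
    if not np.any(x != 0):
        raise DegenerateMatrixError("yield matrix is constant; PCA undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    evr = s**2 / np.sum(s**2)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=yields.index, columns=cols), evr


def spline_growth_yield(times_min, ods, t_end_min: float = 18 * 60.0) -> float:
    """Growth-curve amplitude from a monitored OD time series.

    A natural cubic spline is interpolated through the (time, OD) points
    and the amplitude is spline(18 h) - spline(0), the OD gained over the
    assay.  Replicate amplitudes should be averaged before thresholding.

    Raises
    ------
    InvalidParameterError
        On duplicate time points or fewer than 4 observations.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(ods, dtype=float)
    if t.size != y.size or t.size < 4:
        raise InvalidParameterError("need >= 4 (time, OD) points")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if np.any(np.diff(t) == 0):
        raise InvalidParameterError("duplicate time points in growth curve")
    spline = CubicSpline(t, y, bc_type="natural")
    return float(spline(t_end_min) - spline(0.0))
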