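# Methods

## The question the package addresses

A bacterial species can be sharply structured genetically — distinct
phylogroups, distinct lifestyles — and still show continuous, unstructured
variation in what its strains can eat.  `phenodecouple` implements the
analysis chain used to dissect that decoupling in *Escherichia coli* carbon
source utilisation: (i) turn phenotype-microarray optical densities into
binary growth calls; (ii) compare three strain-to-strain distances
(genetic d_G, phenotypic d_P, metabolic-pathway d_M) with Mantel tests;
(iii) quantify how often growth disagrees with genome-predicted pathway
functionality; and (iv) reproduce the observed distance correlations with a
three-level probabilistic model simulated by Monte Carlo.

## Growth phenotyping

**Growth yield.** OD at 750 nm after 18 h on one carbon source, minus the
control-well OD of the same plate (one plate = one strain × date ×
replicate).  Negative yields are preserved.  For monitored growth curves the
yield is instead the amplitude of a natural cubic spline through the
(time, OD) points: spline(18 h) − spline(0); replicate amplitudes are
averaged before thresholding.

**Date correction.** Assays run in date blocks carry additive batch
offsets.  Per substrate, a linear model with five factors (assay date +
genetic group, pathogenic group, host anthropogenic group, host diet) is
fitted under sum-to-zero contrasts and the fitted date effects — which
average zero over dates, preserving the grand mean — are subtracted.
Because the same design matrix is used on the corrected data, the
correction is exactly idempotent.  Factor levels absent from the data are
dropped with a logged warning.

**Mixture and threshold.** Pooled corrected yields are fitted with
univariate Gaussian mixtures by EM for K = 1…5 (quantile-based mean
initialisation, global variance, equal weights; unequal variances by
default, equal-variance fitting available).  The observed-data
log-likelihood is asserted non-decreasing at every iteration; a component
variance falling below 1e-8 triggers a jittered restart (up to 5) before
raising.  K is selected by BIC = −2·loglik + p·ln N, ties going to the
smaller K.  The positive-growth component is the one with the strictly
largest mean.  The threshold t solves P(X > t) = FPR (default 0.05) where X
follows the weight-renormalised mixture of the non-positive components —
i.e. a non-grower is called positive with probability FPR.  An alternative
"posterior" rule (posterior probability of the positive component = 1 −
FPR) is provided; because the widest component also dominates far tails,
that rule uses the rightmost upward crossing.  Growth calls use a strict
inequality (yield > t).

**Group analysis.** Per substrate with any positive call, a four-factor
Type-III ANOVA (sum-to-zero contrasts, residual denominator df) yields F
tests whose pooled p-values are screened by Benjamini–Hochberg (default
q = 0.001); least-square group means and standard errors are reported for
estimable effects.  Rank-deficient designs flag the affected effects as
non-estimable instead of dropping them.  PCA of the yield matrix is
centred but not variance-scaled, since all variables share OD units
(scaling is a flag).

## Distances and the Mantel test

d_G is the patristic distance (branch-length path sum) on the strain
phylogeny; d_P the Euclidean distance between growth-yield vectors
(quantitative mode) or binary call vectors (qualitative mode, where d_P²
counts discordant substrates); d_M the Euclidean distance between
pathway-completion vectors.  The Mantel statistic is the Pearson
correlation over the n(n−1)/2 off-diagonal pairs, reported alongside
R² = r²; the null jointly permutes rows and columns of the second matrix;
the one-sided p-value uses the add-one rule with 9 999 permutations by
default, or exact enumeration of all n! relabellings for small n.

## Pathway concordance and the discrepancy probabilities

Pathway completion is the fraction of a pathway's enzyme-coding genes
present.  A pathway is functional only when completion is exactly 1, and a
substrate is predicted usable when **any** of its mapped degradation
pathways is functional (the combination rule for multi-pathway substrates
is a package decision; the strict all-genes rule follows the model's
assumption).  Each (strain, mapped substrate) cell falls into one of four
categories — coherent no-growth/incomplete, coherent growth/complete,
growth without the pathway, no growth despite it — and the percent coherent
is their coherent share.  Substrates with no mapped degradation pathway are
excluded.

For each unordered strain pair, δ_M is the fraction of
functionality-discordant substrates on which the phenotypes nevertheless
agree, and δ_P the fraction of functionality-concordant substrates on which
they differ.  Estimates are unweighted means over the pairs whose
conditioning set is non-empty (pairs with an empty set are skipped, never
zero-filled; a pooled-cells mode is available).  A quantity with no
contributing pair is reported as undefined, not 0.

## The decoupling model

Three stacked probabilities for a strain pair at genetic distance d_G:

- gene level: p_M = (1 − μ)·[1 − (1 − d_G)(1 − Λ)], the probability of a
  functional gene difference, combining divergence by descent (d_G),
  horizontal transfer (Λ) and the probability μ that a genetic difference
  is functionally neutral;
- pathway level: P(ΔM ≠ 0) = 1 − (1 − p_M)^n for a pathway of n genes (all
  genes must work);
- phenotype level: P(ΔP ≠ 0) = (1 − δ_M)·P(ΔM ≠ 0) + δ_P·(1 − P(ΔM ≠ 0)).

Defaults: μ = 0.83, Λ = 0.13 (literature values), δ_M = 0.63, δ_P = 0.21
(estimated from sequenced-strain data), d_G ~ Uniform(0, 0.25), 10 000
pairs, 395 pathways.

**Monte Carlo.** Per pair: d_G is drawn, k_j ~ Binomial(n_j, p_M) counts
functionally differing genes per pathway; ΔM_j = [k_j > 0];
ΔP_j ~ Bernoulli(1 − δ_M) where ΔM_j else Bernoulli(δ_P); one substrate per
pathway; d_P = √(Σ ΔP_j).  For d_M, the k_j differing genes are split
Binomial(k_j, ½) between the two strains and the per-pathway completion
difference is |k_A − k_B| / n_j, so d_M = √(Σ (|k_A − k_B|/n_j)²).  The
split is the default because d_M is defined on the two strains' own
completion vectors; charging all k_j differences to one strain (the
`completion_split=False` option) upper-bounds every completion difference
and inflates R²(d_M, d_G) by roughly 0.05–0.08.  Note the deliberate
asymmetry: ΔM uses k_j > 0 (forced by the pathway-level closed form) even
when the symmetric split happens to leave both completions equal.

**Pathway sizes.** The real network's per-pathway gene counts are not
published; the default stand-in law is 1 + Poisson(4) truncated at 20
(mean 5, right-skewed, all sizes in [1, 20]), drawn per run and fully
configurable (`pathway_sizes` accepts any vector).  The simulated
R²(d_M, d_G) is sensitive to this choice: across seeds the default law
gives ≈ 0.655 ± 0.031, all-size-1 networks ≈ 0.54, 1 + Poisson(2) ≈ 0.58,
1 + Poisson(8) ≈ 0.86.  R²(d_P, d_M) stays near 0.09 throughout.  Both R²
values are plain squared Pearson correlations over the simulated pairs —
a Mantel permutation would be meaningless for independently drawn pairs.

## Synthetic data generator

The generator emulates the study conditions end to end and returns the
ground truth for recovery tests.

- **Tree**: strains split round-robin into clades; random coalescent-style
  merges with short intra-clade and long inter-clade heights give the
  bimodal intra/inter distance pattern of a structured species; branch
  lengths are rescaled so the maximum patristic distance is 0.25.
- **Gene states**: strains visited in leaf order; the first draws each gene
  functional with probability π₁ = 0.95 (a core-genome-like share of
  intact genes) and each later strain copies its nearest already-visited
  neighbour with state-dependent flip rates α = q/(2π₁) (1→0) and
  β = q/(2π₀) (0→1), q = p_M(d) for the attachment distance.  Detailed
  balance keeps the marginal functional fraction stationary — a plain
  symmetric flip would drift every strain towards 50% functionality and
  collapse pathway completions — while the pairwise difference probability
  is exactly q for each attachment pair and approximately (monotonically)
  q(d) otherwise.  The construction is deliberately pairwise-faithful
  rather than tree-consistent.
- **Phenotype decoupling**: growth states are the functionality booleans
  flipped per cell with rate a where the pathway is absent (ghost growth)
  and b where complete (silent pathway); (a, b) are solved numerically so
  the pair-level conditionals equal the target (δ_M, δ_P) in expectation
  given the realised functionality matrix.  Unreachable targets raise (the
  cohort then falls back to noiseless growth with a logged warning).
- **Plates**: growth wells draw OD from the high-mean mixture component,
  non-growth wells from the weight-renormalised pair of low components
  (defaults (0.4, 0.02, 0.02), (0.2, 0.15, 0.08), (0.4, 1.00, 0.20));
  strains are shuffled into date blocks (so date is not confounded with
  clade) and per-date Normal(0, 0.1 OD) offsets are added to growth wells
  only — if the control well carried the offset too, blank subtraction
  would silently absorb the date effect and the correction stage would be
  untestable.  Each plate carries exactly one control-well record.

What the generator does **not** emulate: sequence-level evolution (no MLST
loci), pathway overlap (each gene belongs to one pathway; each substrate
maps to one pathway), growth-curve kinetics (only endpoint OD), plate
spatial effects, and any lifestyle-phenotype association (lifestyle labels
are drawn independently of the tree).  Passing recovery tests therefore
show the estimators are correct under the model's own assumptions, not that
real data meet those assumptions.

## Numerical choices and problem sizes

- EM convergence: relative log-likelihood change < 1e-10, max 500
  iterations; variance floor 1e-8.
- Threshold root-finding: Brent's method to 1e-12 on a bracket spanning
  ±20 component standard deviations.
- Stochastic tests run at fixed seeds with 3-standard-error tolerances;
  unbiasedness checks (δ recovery) average 6–8 independent noise draws and
  test the mean at 3 s.e.
- Test-suite problem sizes: cohorts of 12–60 strains, gene-state checks at
  10⁵ genes, threshold false-positive rate at 10⁶ draws, simulations at the
  full 10 000 pairs × 395 pathways (sub-second each).
- All randomness flows from explicit seeds; `generate_dataset` derives
  child streams for tree, sizes, gene states, noise, labels and plate from
  one master seed.

## Known limitations

- The δ-noise mechanism is cell-level with two rates; it matches the
  pairwise (δ_M, δ_P) in expectation but cannot represent, e.g.,
  substrate-specific regulatory classes.
- Gene-state generation is only approximately pairwise-faithful for
  non-adjacent strain pairs.
- The estimated date effects are per-substrate; with very few strains per
  date the correction trades date bias for estimation noise.
- The simulated R²(d_M, d_G) inherits the uncertainty of the stand-in
  pathway-size law (see above); conclusions should quote the sensitivity
  range, not a single value.
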