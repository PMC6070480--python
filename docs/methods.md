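# Methods

`sccanet` links two views of the same subjects — a high-dimensional
functional-connectivity view and an item-level clinical symptom view — by
sparse canonical correlation analysis, and wraps that core in the inference
and summarization machinery the analysis needs end to end. This note
records the model, the defaults and why they are what they are, the
numerical choices, and what the synthetic benchmark does and does not show.

## The model

Given column-standardized matrices `X` (n subjects × p connectivity
features) and `Y` (n × q clinical items), each canonical variate is a pair
of loading vectors `(u, v)` solving

    maximize u' X'Y v   s.t.  ||u||2^2 <= 1, ||v||2^2 <= 1,
                              ||u||1 <= c1,  ||v||1 <= c2.

This is the penalized matrix decomposition form of sparse CCA with
elastic-net-style constraints: the L2 bounds are fixed at 1 and the L1
bounds control sparsity. The solver alternates

    u <- argmax_u u'(Zv)  and  v <- argmax_v (Z'u)'v      (Z = X'Y)

where each argmax under the joint L2/L1 constraint is a soft-threshold
followed by L2 normalization, with the threshold chosen as the smallest
value that brings the L1 norm under the bound. Components beyond the first
come from rank-1 deflation `Z <- Z - d u v'` with `d = u'Zv`.

Sparsity is parameterized per view on a 0–1 scale: `c = max(1, frac *
sqrt(dim))`. `frac = 1` makes the L1 constraint inactive (Cauchy–Schwarz),
recovering the plain SVD of `Z`; `frac = 0` maps to the minimal feasible
bound 1, a single active feature.

### Numerical choices in the solver

* **Threshold solve.** `||w(delta)||1` is continuous and non-increasing in
  the threshold `delta`, and between consecutive sorted `|a|` values the
  constraint `||w||1 = c` is a quadratic in `delta`; the solver computes the
  exact root from cumulative sums of the sorted magnitudes
  (O(d log d), verified in the tests against a brute-force threshold scan).
  Tied maxima can make the smallest attainable L1 norm `sqrt(#ties) > c`; in
  that degenerate case the first (lowest-index) maximum is kept.
* **Initialization.** `v0` is the leading right singular vector of `Z`,
  oriented so its largest-magnitude entry is positive — deterministic, and
  in the unconstrained limit already the fixed point.
* **Convergence.** Stop when the max absolute change in `u` and `v` drops
  below `tol` (default 1e-6, `max_iter` 100). Near the L1 boundary the
  active set can oscillate between supports with identical objective; a
  stagnant objective (change < tol over two iterations) therefore also
  counts as converged. Genuine non-convergence is warned about and logged.
* **Orientation.** `d` is forced non-negative by flipping `u`; then each
  variate is flipped jointly so the largest-|v| clinical loading is
  positive. Joint flips change nothing observable (r, d, covariance
  shares), they only make output canonical.
* **Covariance explained.** Defined as `d_k / sum_j d_j` (the default used
  for selection); the squared variant `d_k^2 / sum d_j^2` is also
  implemented. Both sum to 1 over extracted components.

## Feature engineering

Connectivity matrices are vectorized over the upper triangle *including*
the diagonal, row-major, so an m-node matrix yields `m(m+1)/2` features
(264 nodes → 34,980). The diagonal of a correlation matrix is constant and
has zero median absolute deviation, so the MAD filter always discards it;
the convention only fixes the enumeration and the printed feature count.

The MAD filter keeps the `floor(fraction * p)` features with the largest
`median(|x - median(x)|)` across subjects, ranking zero-MAD features last
and breaking ties by column order. The fraction is a parameter (default
0.1) and the realized count is reported, not hard-coded.

Confounds (age, sex, race, in-scanner motion for connectivity; age, sex,
race for clinical) are removed by per-column least squares against an
intercept plus reference-level indicator encoding; the residuals are
exactly orthogonal to the design and residualization is idempotent.
Columns are then standardized to mean 0, population SD 1. Edge weights are
used as raw correlations (no Fisher z); standardization before the fit
defaults on and is switchable. Order of operations: vectorize → MAD filter
→ residualize → standardize.

## Tuning and variate selection

The two sparsity fractions are tuned by grid search (default 0.1 steps over
(0,1]²; 0 is excluded as degenerate but can be included): every cell is
scored by the mean first-variate correlation over 10 subsamples of
two-thirds of the subjects drawn without replacement, the same subsamples
for every cell. Ties prefer the sparser cell. Tuning belongs to the
discovery role only; a replication run must be given frozen fractions and
the driver refuses to re-tune.

The number of variates carried to inference is read off the
covariance-explained scree: components whose share lies strictly above the
mean share (1/K) are selected; if all shares are equal the first component
is kept.

## Permutation inference

Rows of `Y` are shuffled B times (default 1000); the model is refitted with
identical penalties and `K = max(selected)+1` components. Because
permutation can reorder variates and flip signs, each refitted variate is
matched to its reference variate greedily by the absolute Pearson
correlation of clinical loading vectors (an optimal-assignment mode exists
for larger K). The empirical p is the plain count `#{r_null >= r_obs}/B`
(an add-one variant is available and recommended for small B), compared by
default against each variate's own observed correlation; an aggregate mode
compares against the mean observed correlation over the selected variates.
Benjamini–Hochberg FDR is applied across the selected variates.

## Stability selection

Each of R resamples (default 1000) draws two-thirds of the subjects without
replacement and restores sample size n by redrawing the remaining third
with replacement from those two-thirds. Refits are matched and sign-aligned
to the reference; per-feature percentile intervals use 99% for connectivity
loadings and 95% for clinical loadings, and a feature is stable when its
interval excludes zero.

## Network-module summaries

Stability-surviving edge loadings are placed back on the node grid
(symmetric, zero diagonal). Community summaries are size-normalized means:
within community m, `sum_{i,j in m} 2 W_ij / (|M|(|M|-1))` over unordered
pairs; between m and n, `sum_{i in m, j in n} W_ij / (|M||N|)`. Cell
significance comes from relabeling nodes uniformly at random while
preserving community sizes (two-sided on |mean loading|, since loadings
carry sign), with BH-FDR across unique cells. All communities enter the
computation, including small ones.

Cross-dimension overlap intersects the per-dimension significant-edge
masks (threshold = the number of dimensions supplied). The null model
redraws, B times, uniformly random edge sets with the same per-dimension
edge counts and intersects them; any edge ever seen in a null intersection
is eliminated. Edge-count preservation (rather than degree-sequence
preservation) is the implemented reading of density matching; a
degree-preserving null would be a straightforward extension. Surviving
edges get the mean absolute loading across dimensions and per-node strength
`sum_j |W_ij|`.

## Age and sex effects

Dimension scores for the developmental analysis come from a refit on data
residualized for race and motion only (age and sex must stay in), matched
back to the fully residualized reference; direct projection of the
reference loadings is available as an alternative mode. Each score is
modeled as `score ~ Sex + s(Age)` with a cubic B-spline basis (default
basis dimension 10) and a difference penalty.

Two deliberate choices here:

* **Smoothness selection** minimizes GCV over a fixed log-spaced penalty
  grid with the usual effective-df inflation gamma = 1.4, which guards
  against GCV's tendency to undersmooth on flat criterion surfaces; a
  linear age trend collapses to EDF ≈ 1.
* **Significance of the age smooth** is the exact nested F-test of the
  full-rank (unpenalized) spline block against the sex-only model. Wald
  tests on penalized coefficients, and F-tests conditioned on a data-driven
  penalty, were both badly anticalibrated in null simulations (rejection
  rates far above nominal); the unpenalized nested F-test is exactly
  calibrated under Gaussian errors (simulation: 0.051 at alpha = 0.05 over
  2000 null replicates) at a modest cost in power. EDF, the fitted smooth
  and the sex shift are reported from the penalized fit; the p-value from
  the exact test.

The age × sex interaction is tested separately as a linear (centered)
product term added to the unpenalized model. FDR is applied across
dimensions separately per effect family (age, sex, interaction).

## The synthetic cohort

The generator plants known structure so every stage is testable without
restricted clinical data. Per subject, latent scores `t_k ~ N(0,1)`; edge
pre-values are `mu_ij + sum_k sigma_k t_k u*_k,(ij) + confounds + noise`
squashed into (−1,1) by tanh (any monotone squashing preserves the planted
covariance ranks), symmetrized with unit diagonal; `mu` is elevated within
communities (0.45 vs 0.10 pre-squash) so block structure is visible.
Clinical latents are the analogous `v*` combination, discretized to ordinal
levels at equal-mass quantile cuts. Covariates emulate a developmental
community sample qualitatively: age ~ U(8,22) years, sex ~ Bernoulli(0.5),
race 3-level categorical (0.50/0.35/0.15), motion log-normal (median
≈ 0.1 mm); each acts on both views through per-feature Gaussian
coefficients scaled by configurable effect sizes, so residualization has
real structure to remove. One seeded generator drives all draws; the seed
is recorded in the truth sidecar.

What this emulates: planted sparse cross-view structure at realistic
sample sizes (hundreds of subjects), community-structured connectivity,
ordinal items, and confounding. What it does not: BOLD autocorrelation,
scanner/site effects, heavy-tailed motion artifacts, realistic item
marginals, or spatially smooth edge dependence. Passing the recovery and
calibration benchmarks therefore demonstrates the estimator and inference
machinery are correct and well calibrated under the generative model — not
that any particular effect size is attainable in real cohorts.

## Problem sizes

Defaults follow the analysis as specified (B = 1000 permutations, R = 1000
resamples, 10×10 tuning grid). The test suite and the acceptance script
use desk-scale sizes chosen once: cohorts of 150–500 subjects, 18–25 nodes
(so 25 nodes gives exactly 300 off-diagonal features), B = R = 200, 10
replicate seeds for medians and rates, 200 replicates for the permutation
calibration rate. Calibration claims always use an acceptance band matched
to the replicate count actually run.

## Known limitations

* The deflation scheme does not re-orthogonalize scores; like the
  underlying decomposition, later variates can share variance with earlier
  ones.
* Greedy variate matching can mis-assign when two reference variates have
  nearly collinear clinical loadings; the optimal-assignment mode is
  preferable for K > 3.
* The common-edge null preserves edge counts, not degree sequences; hubs
  make the null slightly liberal at the node level.
* The GAM's exact F-test spends the full spline rank; with very small n and
  large basis dimension it loses power relative to adaptive-rank tests.
* Ordinal items are analyzed as numeric after residualization, mirroring
  the screening-item treatment; no ordinal link is modeled.
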