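# Methods

## The Impact effect size

Impact quantifies the difference between two groups X1, X2 of univariate
measurements as the sum of a location effect and a distribution-shape
effect:

```
Impact(X1, X2) = w · DirCT · CTdiff + (1 − w) · DirMorph · MorphDiff
```

with the following ingredients.

**Central-tendency component.**
`CTdiff = |median(X2) − median(X1)| / GMD(X1, X2)` — the absolute median
difference in units of pooled variability. Variability is measured by
Gini's mean difference,

```
GMD(ξ) = (1/n²) Σᵢ Σⱼ |ξᵢ − ξⱼ|,
```

a robust dispersion measure that requires no distributional assumptions
(the n² denominator including zero self-pairs is used, not the unbiased
n(n−1) variant). Pooling follows a case ladder:

1. both group variances positive → the quadratic mean
   `sqrt((GMD(X1)² + GMD(X2)²)/2)`, which is independent of the group
   sizes;
2. one group constant but the pooled sample not → GMD of the pooled
   sample;
3. pooled sample constant → a small ε (default 1e−7).

The ladder guarantees a strictly positive denominator, so `CTdiff` is
defined even when Cohen's d is not (constant groups). In practice case 3
is unreachable through the main entry point because the Kolmogorov–
Smirnov gate fires first on identical constant groups.

**Shape ("morphic") component.**
`MorphDiff = ∫ |pdf(X2) − pdf(X1)|` — the integrated absolute difference
of the two estimated densities, a total-variation-style distance with
range [0, 2] (2 for disjoint supports). Its sign is taken from the
ordering of the groups' *momentum*, the mean of the log-modulus
transform `L(x) = sign(x)·log(|x| + 1)`; L is monotone and odd, so any
monotone location summary of L(ξ) would induce the same sign, and the
mean is used. Ties in either direction operator resolve to +1.

**Weight.** `w = min(CTdiff, 2)/2`. Once the median shift reaches two
pooled-GMD units the weight saturates at 1 and Impact reduces to the
unbounded `CTdiff` alone; for small median shifts the shape component
dominates. The clamp at 2 matches MorphDiff's maximum, so neither
component can be drowned out by construction artifacts.

**Zero gate.** Before anything else, a two-sample two-sided
Kolmogorov–Smirnov test is run; if it cannot reject identical
distributions at level `alpha_gate` (default 0.05), Impact is defined as
exactly 0. All components are still reported for inspection. The gate
level is conventional; it only matters near zero effect, where it
suppresses density-estimation noise.

**Reference Cohen's d.** `cohens_d` implements
`(mean2 − mean1)/SD_pooled` with two poolings: the rms variant
`sqrt((SD1² + SD2²)/2)` (default — the pooling that the GMD ladder
mirrors, independent of group sizes) and the classical n-weighted
variant with n1 + n2 − 2 degrees of freedom. A zero pooled SD raises
`UndefinedEffectSizeError`; the statistic is never silently coerced to a
number.

## Density estimation

Both group densities are evaluated on one shared, equally spaced grid
(default 512 points) spanning the pooled data padded by one smoothing
radius, and each is renormalized to unit trapezoidal integral — the
MorphDiff integral is therefore comparing like with like.

*Pareto Density Estimation* (default): the density at a grid point is
proportional to the number of observations within a fixed "Pareto
radius" of it. The radius is the 18th percentile (configurable) of the
pairwise absolute-difference distribution of the *pooled* sample — one
radius for both groups, so shape comparison happens at equal smoothing.
Above a configurable cap (default 5000 points) the quantile is taken on
a seeded subsample, keeping the only O(n²) step bounded. Heavily tied
data can drive the quantile to zero; the radius then falls back to 5% of
the data range, so it is always strictly positive. PDE is deliberately
under-smoothed relative to rule-of-thumb kernels, which makes it
sensitive to fine shape features such as bimodality.

*Gaussian KDE* (fallback, `density_method="kde"`): per-group
`scipy.stats.gaussian_kde` with Silverman bandwidth, evaluated on the
same shared grid.

Zero-variance groups support neither estimator and are represented as a
discrete unit point mass in the grid cell containing the value; two such
masses in different cells yield MorphDiff = 2, in the same cell 0. This
keeps all degenerate scenarios computable.

Exact numerical agreement with other implementations of PDE is not a
goal — grid construction and boundary padding are implementation
choices — only statistical agreement of MorphDiff.

## Synthetic benchmark scenarios

The generators are pure functions of (parameters, seed) and reproduce
bit-for-bit under a fixed seed. Defaults:

* **Shape benchmark** (`make_dataset1`, n = 1000/group): mixtures with
  unit-SD modes at ±4 (balanced and 80/20) against *moment-matched*
  unimodal normals, equal-mean normals with SD 1 vs 4, chi-square(df=2)
  vs its moment-matched normal, plus exact mirror images. Matching the
  unimodal group's mean *and* SD to the mixture isolates modality as the
  only group difference.
* **Extreme scenarios** (`make_dataset2`, n = 100/group): constant
  groups, a constant shift without variance, identical discrete groups,
  independent resampling from 1..100, its exact ×10 copy, and constant
  vs N(2, 2).
* **Component scans** (`make_dataset3_*`, n = 100/group): 100 subsets
  with equal means and group-2 SD sweeping 1..100 (shape-only), and 100
  subsets with equal SD 5 and group-2 mean sweeping 1..100
  (location-only).
* **Feature matrix** (`make_dataset4`, n = 1000/group, 20 variables):
  10 pure-noise standard normals, 5 mean shifts of 3..7 SD, and 5
  mean-preserving symmetric bimodal variables with modes at ±3..±7,
  their mean forced to exactly zero by mirroring half the draws.

What the generators emulate is clean, independent, univariate sampling
from known distributions. They do not emulate measurement noise floors,
heavy-tailed contamination, correlated features, unequal group sizes, or
instrument-specific artifacts of real biomedical data (e.g. flow
cytometry). Passing tests therefore demonstrate the measure's designed
behavior under controlled conditions, not its performance on any
particular empirical data set.

## Experiments

* `effect_size_table` computes Impact (with all components) and both
  Cohen's d variants per sample; degenerate d is reported as NaN with a
  flag, never as a number. A Pearson-correlation helper supports regime
  analyses.
* `robustness_subsampling` draws class-proportional subsamples without
  replacement at decreasing fractions and reports mean, SD and
  coefficient of variation of both measures across repeated runs.
  Fractions leaving fewer than 2 points per group are flagged, not
  silently dropped.
* `classification_experiment` contrasts effect-size detection with
  machine-learning separability: a Gini decision tree and a 500-tree
  random forest (sqrt(d) features per split, other hyperparameters at
  library defaults) under Monte-Carlo cross-validation with stratified
  non-overlapping 2/3–1/3 splits; metrics (sensitivity, specificity,
  PPV, NPV, F1, accuracy, AUC) are summarized as median and range in
  percent. The negative control permutes every feature column
  independently *within the training split only*, destroying the
  feature–label association while leaving test data intact.

The shipped test and acceptance configuration uses 25 cross-validation
runs and 10 subsampling/seed repetitions — sizes chosen to give stable
medians and coefficients of variation at interactive runtimes; all run
counts are parameters.

## Numerical choices

* GMD is computed exactly in O(n log n) via the sorted-order identity
  `Σ_{i<j}(x_(j) − x_(i)) = Σ_k (2k − n − 1)·x_(k)`; a brute-force
  double loop serves as the test oracle (agreement to 1e−12 relative at
  n ≤ 200).
* Medians are standard midpoint medians of the sorted values.
* All density integrals use the trapezoidal rule on the uniform grid;
  unit mass is enforced to 1e−6.
* Direction ties (equal medians or equal momenta) resolve to +1.
* Scale invariance holds up to grid discretization; ×10 rescaling moves
  Impact by far less than 0.05 in the shipped tests.
* Seeds: every stochastic step (generators, subsampling, CV splits,
  forests) is driven by an explicit integer seed; child seeds are
  derived via `numpy.random.SeedSequence` and kept below 2³¹.

## Known limitations

* Univariate, two-group only; no confidence intervals for Impact.
* The sign of Impact is arbitrary for symmetric, mean-preserving shape
  changes (it hinges on tiny median/momentum differences); use
  `absolute_value=True` when ranking such effects.
* MorphDiff magnitudes depend on the density estimator and its
  smoothing; PDE and KDE agree qualitatively but not to high precision.
* The KS gate makes Impact exactly 0 below detectability — intended,
  but it creates a discontinuity as a function of the data.
* The momentum normalization is a convention (mean of L(ξ)); any
  monotone summary would give the same signs, but momentum magnitudes
  are not comparable across implementations.
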