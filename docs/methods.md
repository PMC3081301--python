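# Methods

## Generative model

One in-silico experiment is a two-condition expression study of M genes on
n₁ + n₂ arrays. Gene g on array a has expression

    x_ga = μ_g,cond(a) + ε_ga,    ε ~ N(0, Σ_block),

with equal within-condition variance σ² for both conditions. M₀ =
round(π₀·M) genes are null (μ control = μ treatment = 0); each remaining
gene receives a treatment mean shift δ_g drawn once from N(d, effect_sd²).
Genes are partitioned into blocks of k; noise within a block is multivariate
normal with the equicorrelated covariance Σ_ij = σ²·(ρ + (1−ρ)·1{i=j}),
sampled through the block's lower Cholesky factor independently per array.
Blocks are mutually independent, and a block never mixes null and
differentially expressed genes (the rationale: genes co-regulated with a
responsive gene would themselves respond). Null genes fill blocks first;
remainders form one smaller block per truth class. Per-gene two-sided
pooled-variance t-tests (df = n₁ + n₂ − 2) convert a study to p-values.

Because each null gene's test is marginally an exact t-test, null p-values
are Uniform(0,1) for every ρ, and E(FP) = π₀αM holds regardless of the
correlation structure; correlation only inflates the *variance* of
error counts and of the π₀ estimators.

### Default parameters

| parameter | default | why |
|-----------|---------|-----|
| M | 10,000 | typical microarray scale; scaled to 2,000 in tests |
| σ | 1 | effects are expressed in units of σ |
| d (effect_mean) | 2 | typical effect; at n = 8 gives power 0.826 at α = 0.01 |
| effect_sd | 0.5 | effects vary by gene but stay clearly positive (P(δ<0) ≈ 3e−5) |
| k (block size) | 5 | small co-regulated groups (pathway-sized) |
| n₁ = n₂ | 8 | smallest balanced design with power > 0.8 and PFP < 0.05 at π₀ = 0.8 (see the design table) |

The power used in that design choice is the exact noncentral-t power: with
t* the upper α/2 quantile of the central t(df) and noncentrality
δ = d/(σ√(1/n₁+1/n₂)), power = P(T′ > t*) + P(T′ < −t*),
T′ ~ nct(df, δ). The two-sided form is the one consistent with the design
table (one-sided power at n = 8 would be ≈ 0.90, not 0.826). The PFP column
obeys the marginal-FDR identity PFP = π₀α/(π₀α + (1−π₀)·power), verified
cell-by-cell in the tests.

## Estimators: numerical choices

**ZG04.** p-values sorted ascending; slopes s_i = (1 − i/M)/(1 − p₍ᵢ₎) for
t₁ ≤ p₍ᵢ₎ ≤ t₂ (defaults 0.5, 1); π̂₀ = median slope. The index i = M is
excluded (its slope is identically 0 and carries no information), as is any
p₍ᵢ₎ = 1 (undefined slope). An empty selection raises with instructions to
widen the range. The median — rather than mean or minimum — makes the
estimator robust to the few extreme slopes near p = 1.

**ST03.** π̂₀(λ) = #{p > λ}/(M(1−λ)) on the grid λ = 0, 0.01, …, 0.95; a
natural cubic smoothing spline with 3 *effective* degrees of freedom is
fitted and read at λ = 0.95. The spline is the Reinsch form: fitted values
(I + αK)⁻¹y with K the natural-spline roughness matrix; the penalty α is
found by bisection on log α so that tr(I + αK)⁻¹ = 3 (the trace is monotone
in α, between 2 at the linear limit and the grid size at interpolation).
This matches R's `smooth.spline(..., df = 3)` to five decimals on a frozen
test sample.

**PM03.** The BUM log-likelihood Σ log[w + (1−w)·a·p^(a−1)] is maximised
over the box 0 < a ≤ 1, 0 ≤ w ≤ 1 by L-BFGS-B with bound constraints from a
3×3 grid of starts (the surface is flat in w as a → 1, so multi-start is
cheap insurance). p-values are clipped to [1e−10, 1] to keep p^(a−1)
finite. π̂₀ = ŵ + (1−ŵ)â, the fitted density at p = 1, which upper-bounds
π₀ under the mixture model. A test verifies the optimiser dominates a 50×50
grid search on every tested sample.

**PC04.** Sorted distinct p-values give spacings; the raw density ordinate
at each interval midpoint is 1/(M·d̄), where d̄ is the running mean of 21
neighbouring per-point spacings (tied values are merged, contributing their
multiplicity-divided spacing). The running mean is what makes the ordinate
usable: the reciprocal of a *single* exponential gap has infinite mean, and
locally weighted regression applied to such ordinates is unstable — robust
iterations track a biased multiple of the density and occasionally collapse
a local fit entirely. Averaging 21 gaps gives an inverse-gamma ordinate with
light tails and ~5% multiplicative bias while leaving the value on an
equally spaced grid exactly 1. Ordinates are anchored at 0 and 1, smoothed
by LOWESS (span 0.3, no robust iterations), and π̂₀ is the smoothed minimum
clipped to [0, 1].

**Ch04.** The CDF is a cubic B-spline on [0, 1] with 10 interior knots —
six in geometric progression from 0.005 to 0.3 (p-value CDFs bend hardest
near 0) and four uniform tail knots — constrained to F(0) = 0, F(1) = 1,
nondecreasing coefficients (monotone CDF), and, by default, nonincreasing
derivative coefficients (concave CDF, i.e. nonincreasing density). The
concavity constraint is the working interpretation of the original method's
"strategically designed" shape: under the uniform-plus-alternatives mixture
the density is nonincreasing, and without the constraint the spline's
derivative develops spurious near-zero dips just past the steep CDF rise,
destroying the estimate. Coefficient increments are fitted by SLSQP least
squares against the ECDF (thinned to 2,000 points for large M); π̂₀ is the
minimum of the fitted derivative on a 1,001-point grid.

All five estimators clip π̂₀ to [0, 1] and record the raw value and a
clipping flag in their diagnostics. All are invariant to permutation of the
input (sorting is internal).

## Benchmark design

At each (π₀, ρ[, n]) grid point, R replicate studies are simulated; all five
estimators see the *same* p-value vector per replicate, which is what makes
the paired t-test on per-replicate absolute errors valid. Accuracy is
summarised by MAE (equal weight to all errors; RMSE, which emphasises large
errors, is reported alongside and always ≥ MAE). Labels per point:

- **blue** — reference (ZG04) beats each other method with all four paired
  p-values < threshold;
- **red** — some method beats the reference at the threshold;
- **yellow** — otherwise (at least one tie).

The default threshold 1e−5 is chosen so that a full-scale sweep (~190 points
× 4 tests ≈ 760 tests) expects < 1 falsely declared significance; no further
multiplicity correction is applied. Per-point seeds are derived from the
master seed and the point coordinates, so sweep output is independent of
evaluation order. Estimator failures are recorded as missing (excluded
pairwise); a point with > 10% failures for any method is flagged rather
than labelled.

Replication sizes: the package defaults to R = 100 per point with
M = 10,000. The test suite and the acceptance script use scaled-down
conditions — M = 2,000, R = 20–50, a handful of grid points — which
preserve the estimators' relative ordering (MAE differences at π₀ = 0.8 are
several SEs wide already at R = 50) but not the full map's resolution: the
boundaries of the blue/yellow/red regions, and in particular the narrow red
strip near π₀ ≈ 0.95 where the BUM upper bound becomes the most accurate
method, are sensitive to R and are reported empirically rather than
asserted.

## What the simulator does and does not emulate

It emulates: realistic test counts, block-correlated genes with tunable
common ρ, gene-varying effect sizes, exact null calibration, and the
p-value computation pipeline of a two-group design. It does not emulate:
non-normal expression distributions, heteroscedastic or heavy-tailed noise,
normalisation artefacts, complex (non-equicorrelated, cross-block)
dependence, or raw-intensity file formats. Passing benchmarks here
therefore speak to estimator behaviour under clean marginal t-tests with
block dependence — not to robustness against distributional misspecification.

## Degenerate inputs and edge cases

- Zero pooled variance (probability zero under the model): p = 1 and a
  degeneracy flag when the group means are also equal; an error otherwise.
- All p-values identical: PC04 raises (spacing density undefined).
- ZG04 with no sorted p-value in [t₁, t₂]: an error advising a wider range.
- Paired comparison with all differences zero: p = 1, tie; zero variance
  with nonzero mean: p = 0 with the sign of the mean difference.
- Estimates at the boundary: clipping to [0, 1] is recorded in diagnostics.

## Known limitations

- PC04's spacing window (21) and LOWESS span (0.3), and Ch04's knot layout,
  are this package's documented defaults for procedures whose original
  publications leave them open; conclusions about those two methods'
  *absolute* accuracy carry that caveat.
- The equicorrelated block model is the simplest dependence structure;
  real co-expression is richer, and estimator variance under it may differ.
- MAE standard errors treat replicates as independent, which they are by
  construction here but would not be for resampled real data.
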