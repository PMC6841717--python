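# Methods

This note records the statistical procedures implemented in `migrastat`,
the numerical choices behind them, and what the validation on synthetic
data does and does not establish.

## Data model

A trajectory is an ordered sequence of absolute 2D positions in mm sampled
at a fixed frame interval `dt` (default 2 s). No recentering or smoothing
happens at read time; gaps in the frame index are warned about and spanned
by a single step, never interpolated, because continuous sampling is
assumed and gaps indicate tracking faults. The one-dimensional signal for
all correlation analyses is the move-step series u(t), the Euclidean
displacement magnitude between consecutive frames (length N−1 for N
positions). Stops (u = 0) are retained: they carry information and the
cumulative-sum constructions make no exclusion.

The pixel→mm calibration of any particular dataset is a reader parameter
(`scale`, default 1.0); exponents are scale-invariant but speeds and
distances are not, so users of digitized data must supply their
calibration.

## rmsf scaling (α) and correlation duration (M)

F(l) is the population standard deviation of net displacements
Δy(l) = y(l+l₀) − y(l₀) of the cumulative step sum, averaged over window
offsets l₀ at stride Δl₀ (default 1 = all offsets; a scale is dropped when
fewer than two offsets fit). The scale grid is every integer 1–10 then
≈25 log-spaced points per decade up to N/4: dense small scales anchor the
fit, log spacing bounds cost.

α is the OLS slope of log₁₀F vs log₁₀l. The fit range matters and the
crossover criterion is deliberately explicit rather than visual: a
two-segment continuous (hinge) regression is fitted over the log-log curve
with the knot at each grid point; if the best two-segment fit reduces the
single-line residual sum of squares by ≥ 5 %, the knot is the crossover and
M is the knot scale rounded to the nearest 100 steps (clamped into the
grid, never below 100 or the smallest scale). α is then fitted over the
pre-crossover range [1, M]. If no crossover reaches the 5 % improvement, M
is the largest scale in the grid and α is fitted over [1, N/10]. Ties in
the knot search break toward the larger scale. Both the improvement
threshold and the fit range are parameters.

Scale invariance re-estimates α at strides Δl₀ ∈ {1, 5, 10, 25} with one
common fit range; for a genuinely scale-invariant series the exponents
agree (observed spread < 0.01 on fractional Gaussian noise at n = 8192).

## Detrended fluctuation analysis (γ)

The profile z(t) is the cumulative sum of the mean-centred steps. Boxes of
size n tile the profile from the start; the trailing remainder shorter
than n is excluded and D(n) is normalized by the covered length (the
remainder policy is a convention; excluding it is the simplest contract).
Detrending is order-1 (straight line per box) by default, exposed as
`order`. The box grid is ≈20 log-spaced sizes from 4 to N/4. γ is the OLS
slope of log₁₀D vs log₁₀n over the whole grid. A constant series has a
linear profile removed exactly by detrending; it is reported as degenerate
rather than fitted.

## Dispersion-analysis Hurst exponent (H)

SD(n) is the population standard deviation of the means of non-overlapping
blocks of n values; H is one plus the OLS slope of log₁₀SD vs log₁₀n. Bins
are powers of two starting at 2. Bins are kept only while at least
`min_blocks` = 16 blocks remain: the SD of a handful of block means is
biased low (for m blocks the bias in log₁₀SD is ≈ 0.5·log₁₀((m−1)/m) plus
a chi-distribution term, reaching −0.2 at m = 3), and including bins up to
N/2 drags the white-noise calibration down to Ĥ ≈ 0.46. With the cutoff
the estimator is calibrated: mean Ĥ = 0.494 ± 0.025 on iid Gaussian series
of length 6700. The cutoff is a parameter; for series too short to leave
three bins it relaxes automatically to 2 blocks.

Known bias: at strong persistence the estimator compresses toward 0.5
(Ĥ ≈ 0.76 at H = 0.8, ≈ 0.83 at H = 0.9 for n in the thousands). Recovery
stays within ±0.05 for H ≤ 0.8 at n = 8192; above that, DFA is the more
faithful exponent and the two should not be expected to agree more tightly
than ≈ 0.1.

## Shuffle null

Each input series is permuted uniformly `n_perm` (default 200) times —
permutation preserves the value multiset while destroying temporal order —
and H is re-estimated on every replicate. One child seed per (series,
permutation) pair is derived from the master seed via `SeedSequence`
spawn keys, so any subset of the ensemble is reproducible in isolation.
Degenerate replicates are counted, not fatal. The experimental-vs-shuffled
contrast is a two-sided rank-sum test; p-values below representable
precision would be reported as an upper bound rather than 0 (with 20-vs-
4000 exponent samples the normal approximation stays representable).

## MSD exponents (β)

The default MSD follows the scalar-radial definition: positions are
recentred so the first recorded point is the origin (absolute dish
coordinates would make the modulus depend on arbitrary placement), and the
time-averaged squared increments of r(t) = |P(t) − P(t₀)| are fitted as
MSD(τ) ~ τ^β over τ = 1 … N/4. The field-standard vector definition
|P(t+τ) − P(t)|² is available via `definition="vector"`. The two agree on
ballistic and isotropic random walks, but the radial definition
systematically reads lower on walks with intermediate persistence (the
radial coordinate can stall while the position keeps moving
tangentially) — worth keeping in mind when comparing against
vector-definition results.

The RGO estimator treats the radial increment sequence I as a candidate
fixed point of the block-sum-and-rescale map (R_{n,p}I)ᵢ = (Σ block i)/n^p.
For each non-overlapping window of 1000 increments it scans
p ∈ [0.25, 1.25] in steps of 0.01, measures the two-sample
Kolmogorov–Smirnov distance between renormalized and original increments
for block sizes n ∈ {2, 3, 4, 5, 6, 8}, and takes p̂ minimizing the mean
distance over n (argmin ties break toward smaller p, biasing away from
over-claiming super-diffusion); βᵢ = 2p̂ and the reported β is the window
mean. A window of constant increments is an exact fixed point at p = 1 and
is assigned β = 2 with a flag. The per-p match frequencies across
(window, n) pairs are retained as a diagnostic histogram of the match
probability. Validation: β̂ = 1.00 on Brownian radial increments and
β̂ within 0.06 of 2H on fractional Brownian trajectories at
H ∈ {0.5, 0.7, 0.9} (20 seeds, n = 6000).

## Kinematics

DR = d/δ with d the Euclidean start-to-endpoint distance and δ the summed
step magnitudes; it is invariant under rigid motions and lies in [0, 1] by
the triangle inequality. The profile evaluates DR at endpoints every 200
frames (400 s at dt = 2) from 200 to 3800, omitting endpoints beyond the
track, so full-length tracks yield 19 values. Average speed is mean(u)/dt.
Total distance sums the first ⌊130 min/dt⌋ steps (3900 at dt = 2) so cells
recorded for different durations are compared over a common horizon; a
shorter track is summed over its available length with a warning rather
than rejected.

## Group comparison

One row per cell (α, M, γ, β direct, β RGO, DR, AS, TD); group summaries
report mean ± sample SD (n−1 divisor) and a two-sided Wilcoxon rank-sum
p-value per metric, including TD. For pooled sizes ≤ 12 the p-value is an
exact enumeration over all rank assignments (mid-ranks make this valid
under ties); otherwise the normal approximation with tie-corrected
variance and 0.5 continuity correction is used (type-I error calibrated to
0.03–0.07 at nominal 0.05 in 20-vs-20 null simulations). No
multiple-testing adjustment is applied; p-values are reported raw,
metric by metric.

## Synthetic generator

All generators draw from a single seeded PCG64 stream; identical
spec + seed gives bitwise-identical output, and the algorithm name is
recorded in output metadata so seeds are portable.

* **fgn** — exact-covariance circulant embedding (Davies–Harte). If the
  embedding's eigenvalues are negative (possible only at extreme H with
  small n), the O(n²) Hosking recursion is used and logged. Optional
  rectification to nonnegative step magnitudes shifts by 3 sample SDs,
  clips at 0 and rescales to a target mean; the affine transform and the
  clipped fraction (~0.1 %) are recorded. Clipping necessarily leaves a few
  exact zeros and perturbs the correlation structure only to first order.
* **brownian2d / ballistic** — the β = 1 and β = 2 reference regimes.
* **persistent_walk** — constant step length, headings from a wrapped
  AR(1) with lag-1 circular correlation `persistence`
  (σ² = −2 ln ρ); ρ = 0 is the uniform-heading walk, ρ → 1 ballistic.
* **levy_walk** — straight flights at constant speed with Pareto
  durations, P(d > x) ~ x^{−(μ−1)}, fresh uniform heading per flight.
* **amoeba_like** — rectified fGn step magnitudes (mean 0.008 mm per 2 s
  frame ⇒ average speed ≈ 0.004 mm/s), persistent headings, optional stop
  states. Defaults n = 6690 (the average recording length), H = 0.8,
  persistence = 0.997, stop rate 0.01, calibrated so that the generated
  walks land in the empirically observed regime (α ≈ 0.76, β ≈ 1.7,
  DR ≈ 0.3) under this package's own estimators, radial MSD included.

What the generator does **not** emulate: the marginal distribution of real
step magnitudes is unknown (the rectified Gaussian is a stand-in), heading
dynamics of real cells are not a wrapped AR(1), there is no coupling
between speed and turning, and no measurement noise or tracking error is
modelled. Passing parameter-recovery tests therefore demonstrates that the
estimators recover known exponents from signals with the assumed
correlation structure — not that real trajectories satisfy these models.

## Numerical choices and degenerate inputs

* Log-log fits exclude zero statistic values; fewer than four usable
  points is an error, not a silent fit.
* Step series whose variation is below 10⁻¹² of their magnitude are
  treated as constant: exactly regular trajectories produce step series
  constant only up to floating-point rounding, and without the guard the
  scaling estimators would fit numerical noise.
* Exponent estimates are deterministic given the input and parameters;
  only the generator and the shuffle null consume randomness.
* Pipeline runs degrade gracefully: a stage whose input is degenerate
  (stationary track, constant series) records a failure message and leaves
  its metric unset while the other stages proceed.

## Problem sizes used in validation

Calibration and recovery checks run at the scale of the motivating
experiments: series of 6700–8192 points for the 1D estimators (50 seeds
for white-noise calibrations, 20 for recovery), 20 series × 200
permutations (4000 replicates) for the shuffle null, trajectories of 6000
points (20 seeds) for the MSD estimators, and 1000 replicates for the
rank-sum type-I calibration. Oracle-equivalence checks (vectorized vs
brute-force evaluation) use series of length ≤ 512 where exact agreement
to rounding error is asserted.

## Known limitations

* The crossover criterion behind M (5 % RSS improvement, rounding to 100)
  is a convention; "where the curve starts to bend" has no unique
  definition, and reported M values should be read at ±1 grid step.
* The dispersion estimator's compressive bias at H > 0.8 (above) makes the
  shuffle-null contrast conservative but biases absolute H readings low.
* The radial MSD definition depresses β on persistent-but-winding walks
  relative to the vector definition.
* The RGO diagnostic histogram (per-p match frequency) is one reasonable
  realization of a "match probability" plot; other constructions exist.
* The rank-sum exact path enumerates C(N, n_a) assignments and is
  restricted to pooled sizes ≤ 12 (≤ 924 combinations).
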