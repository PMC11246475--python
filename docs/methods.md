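# Methods

## Model and guarantee

conformap implements split (inductive) conformal prediction. A reference
dataset is partitioned into train / calibration / test splits (default
ratios 65:20:15, configurable; a group-aware variant assigns whole groups
such as countries or source images to a single role). A predictive model
fitted on the train split scores the calibration split; each calibration
instance receives a nonconformity score measuring disagreement with its
true value. The conformal threshold is the order statistic of the
calibration scores at the finite-sample adjusted quantile level

    qLevel = ceil((1 + nCal) * (1 - alpha)) / nCal,

realized as the k-th smallest score, k = ceil((nCal + 1)(1 - alpha)),
with no interpolation — interpolating between order statistics would void
the finite-sample guarantee. Under exchangeability of calibration and
inference data, the resulting prediction region contains the truth with
probability at least 1 - alpha; for continuous scores the coverage is
also bounded above by 1 - alpha + 1/(nCal + 1), which is what the
Monte-Carlo tests check on both sides.

Scoring rules:

- **Classification (LAC, least-ambiguous set-valued classifier).** Hinge
  score 1 - f(x)[y_true] on probability-like classifier outputs. The
  threshold is reported on the probability scale t = 1 - qhat, and the
  prediction set is every class with f(x)[y] >= t (boundary inclusive).
  Inputs may be uncalibrated pseudo-probabilities: entries must lie in
  [0, 1] but need not sum to one; they are validated, never renormalized
  or clipped. Empty sets are retained as meaningful output (an input
  unlike the calibration data), never coerced to the argmax class.
- **Mondrian (class-conditional) classification.** The LAC procedure is
  repeated within each true-class stratum, giving one threshold per
  class. This targets per-class coverage at the cost of efficiency.
  A class with zero calibration instances is an error; a class whose
  stratum is too small for the requested alpha is *flagged* and assigned
  the always-include threshold t = 0 — conditionally valid but
  uninformative, the explicit degenerate-policy choice (see below).
- **Regression, absolute residual.** Score |y - yhat|; interval
  yhat ± qhat. All intervals share width 2*qhat — the rule's known lack
  of adaptability, asserted as a property in the tests.
- **Regression, CQR.** Score max(q_lo - y, y - q_hi) against a fitted
  quantile pair; interval [q_lo - qhat, q_hi + qhat]. qhat may be
  negative (the fitted band was conservative and shrinks). The nominal
  quantile pair defaults to (alpha/2, 1 - alpha/2). Crossed quantile
  predictions are repaired by sorting the pair before scoring and before
  interval construction; this keeps every instance usable. The quantile
  learner is pluggable; the shipped reference is a LightGBM pinball-loss
  pair (`QuantileGBM`), which the conformal layer treats as a black box.

## Parameters that matter

- `alpha` — tolerance level in (0, 1); confidence = 1 - alpha. Typical
  mapping choices: 0.10 for classification, 0.05 for regression.
  Classification calibration accepts an alpha grid and stores one
  threshold per level (thresholds are non-decreasing in alpha), so
  thresholds can be published once and reused.
- `nCal` — calibration size. The adjusted level is attainable only when
  ceil((nCal + 1)(1 - alpha)) <= nCal; below that the calibration is
  *degenerate*. Default policy is a refusal naming the minimum nCal for
  the requested alpha; an opt-in (`on_degenerate="inf"`) instead returns
  an infinite margin — full sets / unbounded intervals, valid but
  uninformative.
- Seeds — every stochastic operation takes one integer seed and uses
  numpy's PCG64 (`default_rng`), so splits, generators and experiments
  reproduce across platforms. The Monte-Carlo harness derives per-replicate
  seeds from a `SeedSequence` of the master seed.

## Numerical choices

- **Tolerant ceiling.** k = ceil((nCal + 1)(1 - alpha)) is computed with
  a few-ulp epsilon (4 spacings of the product, floor 1e-12) so binary
  floating point cannot push k one order statistic too high when the
  product is exactly an integer in decimal arithmetic (e.g. nCal = 9,
  alpha = 0.1 gives exactly 9). The test oracle evaluates the same
  expression in exact decimal (Fraction) arithmetic.
- **Ties.** Ties among calibration scores need no special handling under
  the order-statistic convention: the k-th smallest value is well defined
  with duplicates. Threshold comparisons are boundary-inclusive (>=).
- **Bitmask encoding.** Raster prediction sets are packed into a 32-bit
  unsigned band, bit c = roster class c (band order, recorded in the
  calibration artifact). The set-length band is 8-bit. Nodata sentinels
  are all-ones (bitmask) and 255 (length); since a full 32-class set is
  also all-ones, the length band is the authoritative nodata indicator.
- **Nodata.** Strict propagation: a pixel with nodata (or a non-finite
  value) in any input band is nodata in every output band; no partial-set
  computation. Interval rasters use NaN as the output nodata so no finite
  sentinel can collide with legitimate bounds.
- **Tiling.** Rasters are processed in square tiles (default 256 px);
  results are tile-size invariant (asserted) and bit-exact against the
  tabular path on the flattened pixels.

## Synthetic generators: what they emulate, and what not

The generators exist so validity claims are testable without any
satellite data.

- `gen_classification_table` draws each instance's probability vector
  from a peaked Dirichlet (uniform base weight plus `difficulty` on a
  focal class sampled from the priors) and then samples the label *from
  that vector*. The emitted vector is therefore exactly the conditional
  label distribution: exchangeability holds by construction and true
  coverage is measurable. `difficulty` sweeps easy to hard; the default
  (32, with nine classes) mimics a usually-confident land-cover model and
  yields sets of ~2.5 classes on average at 90% confidence.
- `gen_regression_table` produces a canopy-height-like response: a smooth
  sinusoidal-plus-linear mean of uniform features with Gaussian noise,
  homoscedastic (sd `sigma`, default 1 in response units, metres in the
  emulated setting) or heteroscedastic (sd growing linearly along the
  first feature). The oracle object exposes the true mean, noise scale
  and conditional quantiles for adaptivity checks.
- `gen_probability_raster` smooths per-class Gaussian random fields
  (Gaussian kernel, `correlation_length` pixels) and softmaxes them onto
  the simplex, so class "objects" emerge with ambiguous boundaries; labels
  are sampled per pixel; a vertical nodata stripe is always present so
  propagation is exercised by default.

None of the generators emulate sensor physics, cloud artefacts, seamline
geometry, class-dependent label noise, or real spatial non-stationarity.
Passing tests therefore demonstrate the *statistical machinery* — the
coverage guarantee under exchangeability, adaptivity, the raster
plumbing — not performance on real imagery, where exchangeability can
fail (drift, post-processing) and recalibration is the remedy.

## Experiment sizes

The Monte-Carlo validity experiments run 100 replicates at calibration
size 2000 and test size 5000 (CQR uses 30 replicates at 1000/1000 with a
fitted LightGBM quantile pair), sizes at which the Monte-Carlo standard
error of mean coverage is ~1e-3 — small enough to resolve the guarantee
band [1 - alpha, 1 - alpha + 1/(nCal + 1)] while keeping a full run in
seconds on one CPU.

## Design choices where the design was open

- **Score sign.** The hinge score is implemented as 1 - p (nonnegative)
  rather than p - 1; the two rank identically, and reporting the
  threshold on the probability scale (t = 1 - qhat) makes the inclusion
  rule a direct probability comparison.
- **Clustering for spatial folds** is k-means on raw planar coordinates,
  one cluster = one fold — the simplest construction that yields
  spatially compact folds; fold sizes follow the data's clumping.
- **Tilted-coordinate angles** default to {0, 30, 60, 90, 120, 150}
  degrees (an even half-turn grid); angles are accepted in degrees and
  converted internally. feature(θ) = x·cosθ + y·sinθ, so θ and θ+90°
  jointly preserve the squared radius (asserted at machine precision).
- **Group-aware splitting** fills instance-count quotas greedily over
  shuffled groups, so realized ratios are approximate when group sizes
  are uneven (exact rounding applies only to the ungrouped split).
- **CLI scope.** The command line is a thin veneer (calibrate / apply /
  evaluate / simulate) over the library; the importable API is the
  primary surface.

## Known limitations

- Split conformal's guarantee is *marginal*; subpopulations can be under-
  covered. Mondrian calibration addresses classes, not arbitrary strata.
- Guarantees assume exchangeability; distribution shift between
  calibration and inference voids them, and no drift detection is built
  in.
- Rosters are limited to 32 classes by the bitmask encoding.
- Jackknife+ and transductive conformal variants are out of scope, as are
  reprojection and any raster resampling.
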