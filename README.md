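# conformap

Split-conformal uncertainty quantification for pixel-wise mapping:
calibrated **prediction sets** for classification (land cover, species
discrimination) and calibrated **prediction intervals** for regression
(canopy height and similar continuous targets), with raster application,
validity/efficiency evaluation, spatial cross-validation utilities, and
synthetic generators that make the coverage guarantee itself testable.

Maps produced by machine-learning models are point predictions; decisions
built on them need to know *how sure* each pixel is. Split conformal
prediction converts any model's scores into prediction regions with a
distribution-free, finite-sample guarantee: for a user-chosen tolerance
α, the region contains the true value with probability at least 1 − α,
for any model and any data distribution, provided calibration and
inference data are exchangeable.

## The method

Given nonconformity scores `s_1, …, s_nCal` from a held-out calibration
set, the conformal threshold is the order statistic of the scores at the
finite-sample adjusted quantile level

```
qLevel = ceil((1 + nCal) · (1 − α)) / nCal
```

realized as the k-th smallest score with `k = ceil((nCal + 1)(1 − α))`,
without interpolation.

* **Classification (LAC).** Scores are hinge losses `1 − f(x)[y_true]`.
  The threshold maps back to the probability scale, `t = 1 − q̂`, and the
  prediction set for a new instance is every class with `f(x)[y] ≥ t`.
  Set *length* is the per-pixel uncertainty: 0 = outlying input, 1 =
  confident, >1 = ambiguous. A Mondrian variant calibrates one threshold
  per class for approximate class-conditional coverage.
* **Regression.** Absolute-residual scores `|y − ŷ|` give constant-width
  intervals `ŷ ± q̂`; conformalized quantile regression (CQR) scores
  `max(q_lo − y, y − q_hi)` against a fitted quantile pair give adaptive
  intervals `[q_lo − q̂, q_hi + q̂]`.
* **Evaluation.** Empirical marginal coverage (fraction of regions
  containing the truth) for validity; average set size / interval width
  for efficiency.

Raster application reproduces the tabular rules pixel-by-pixel on
multi-band GeoTIFFs, emitting a 32-bit set-bitmask band, an 8-bit
set-length band, or lower/upper/width interval bands, with strict nodata
propagation and verbatim pass-through of georeferencing tags.

## Worked example

```python
import conformap as cm

spec = cm.ClassificationGeneratorSpec(n=10_000, n_classes=9, seed=42)
probs, labels = cm.gen_classification_table(spec)
split = cm.split_three_way(spec.n, ratios=(0.65, 0.20, 0.15), seed=42)
cal, test = split.indices("calibration"), split.indices("test")

calibration = cm.calibrate_lac(probs[cal], labels[cal], alpha=[0.10])
sets = cm.predict_set(probs[test], calibration, alpha=0.10)
report = cm.classification_report(sets, labels[test])
print(report.empirical_marginal_coverage, report.average_set_size)
```

Running the fuller version of this (`python examples/classification_sets.py`)
prints:

```
at 90% confidence on 1500 test instances:
  empirical marginal coverage = 0.8993
  average set size            = 2.45 classes
  singleton fraction          = 0.19
  empty-set fraction          = 0.000
```

Coverage sits at the nominal 90%: about nine in ten label sets contain
the true class. The average set carries 2.45 of the 9 candidate classes —
the efficiency cost of the guarantee on this problem; singletons are the
confident pixels.

The other scripts under `examples/` each demonstrate one capability:
adaptive CQR vs constant-width intervals (`regression_intervals.py`),
raster products and class-inclusion masks (`raster_uncertainty.py`),
per-class coverage under imbalance (`mondrian_per_class.py`), tilted
location features and clustered spatial CV (`spatial_workflow.py`), and
the Monte-Carlo validity check (`coverage_experiment.py`).

A thin CLI wraps the same library for shell use:
`conformap calibrate | apply | evaluate | simulate` (see `--help`).

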