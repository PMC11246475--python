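"""Validity and efficiency assessment of conformal predictors.

Validity is empirical marginal coverage — the fraction of held-out
prediction sets (or intervals) containing the true value; for a sound
split-conformal predictor it should match or exceed the nominal ``1 -
alpha``.  Efficiency is informativeness given validity: average set size
for classification, average interval width for regression.
:func:`coverage_experiment` wraps the generate → calibrate → evaluate loop
into a seeded Monte-Carlo harness so the guarantee itself can be tested.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import classification as cls
from . import regression as reg
from . import synthetic
from .calibration import DegenerateCalibrationError

__all__ = [
    "ClassificationReport",
    "RegressionReport",
    "ExperimentSummary",
    "classification_report",
    "regression_report",
    "coverage_experiment",
]


@dataclass(frozen=True)
class ClassificationReport:
    """Step-6 style summary for set-valued classification on a test split.

    ``per_class_coverage`` maps each roster class to the coverage over its
    true instances; classes absent from the test truths map to NaN (an
    undefined marker, not zero).
    """

    empirical_marginal_coverage: float
    average_set_size: float
    empty_fraction: float
    singleton_fraction: float
    per_class_coverage: dict
    n_test: int

    def to_json(self) -> str:
        doc = asdict(self)
        doc["per_class_coverage"] = {
            str(k): (None if np.isnan(v) else v)
            for k, v in self.per_class_coverage.items()
        }
        return json.dumps(doc, indent=2)

    def to_row(self) -> dict:
        """Flat scalar row for batch experiment tables."""
        row = asdict(self)
        per_class = row.pop("per_class_coverage")
        for k, v in per_class.items():
            row[f"coverage[{k}]"] = v
        return row


@dataclass(frozen=True)
class RegressionReport:
    """Coverage, mean interval width and point-prediction RMSE on a test split."""

    empirical_marginal_coverage: float
    average_interval_width: float
    rmse: float
    n_test: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self) -> dict:
        return asdict(self)


def classification_report(
    sets: cls.PredictionSets, truths
) -> ClassificationReport:
    """Coverage (fraction of sets containing the truth) and set-size stats."""
    truths = np.asarray(truths).ravel()
    n = len(truths)
    if n == 0:
        raise ValueError("empty test set")
    if sets.membership.shape[0] != n:
        raise ValueError("sets and truths must have equal length")
    covered = sets.contains(truths)
    sizes = sets.cardinality
    per_class = {}
    for c in sets.classes:
        mask = truths == c
        per_class[c] = float(covered[mask].mean()) if mask.any() else float("nan")
    return ClassificationReport(
        empirical_marginal_coverage=float(covered.mean()),
        average_set_size=float(sizes.mean()),
        empty_fraction=float((sizes == 0).mean()),
        singleton_fraction=float((sizes == 1).mean()),
        per_class_coverage=per_class,
        n_test=n,
    )


def regression_report(
    intervals: reg.PredictionIntervals, truths, yhat=None
) -> RegressionReport:
    """Boundary-inclusive interval coverage, mean width, and RMSE of yhat."""
    truths = np.asarray(truths, dtype=float).ravel()
    if truths.size == 0:
        raise ValueError("empty test set")
    if intervals.lower.size != truths.size:
        raise ValueError("intervals and truths must have equal length")
    covered = intervals.contains(truths)
    if yhat is None:
        rmse = float("nan")
    else:
        yhat = np.asarray(yhat, dtype=float).ravel()
        rmse = float(np.sqrt(np.mean((truths - yhat) ** 2)))
    return RegressionReport(
        empirical_marginal_coverage=float(covered.mean()),
        average_interval_width=float(intervals.width.mean()),
        rmse=rmse,
        n_test=truths.size,
    )


@dataclass(frozen=True)
class ExperimentSummary:
    """Across-replicate summary of a Monte-Carlo coverage experiment.

    ``mc_se`` is the standard error of the mean coverage across replicates;
    a sound predictor keeps ``mean_coverage`` within a few ``mc_se`` at or
    above ``1 - alpha``.
    """

    method: str
    alpha: float
    replicates: int
    dropped: int
    mean_coverage: float
    sd_coverage: float
    mc_se: float
    mean_efficiency: float
    sd_efficiency: float
    efficiency_metric: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _fit_point_model(model: str, X, y, seed):
    if model == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression().fit(X, y)
    if model == "gbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(n_estimators=100, random_state=seed, verbose=-1).fit(X, y)
    raise ValueError(f"unknown point model {model!r}")


def _one_classification_rep(spec, method, alpha, n_cal, n_test, seed):
    rep_spec = synthetic.ClassificationGeneratorSpec(
        n=n_cal + n_test,
        n_classes=spec.n_classes,
        difficulty=spec.difficulty,
        priors=spec.priors,
        seed=seed,
    )
    probs, labels = synthetic.gen_classification_table(rep_spec)
    cal_p, cal_y = probs[:n_cal], labels[:n_cal]
    test_p, test_y = probs[n_cal:], labels[n_cal:]
    if method == "lac":
        calib = cls.calibrate_lac(cal_p, cal_y, alpha)
        sets = cls.predict_set(test_p, calib, alpha)
    else:
        calib = cls.calibrate_mondrian(cal_p, cal_y, alpha)
        sets = cls.predict_set_mondrian(test_p, calib)
    report = classification_report(sets, test_y)
    return report.empirical_marginal_coverage, report.average_set_size


def _one_regression_rep(spec, method, alpha, n_cal, n_test, n_train, model, seed):
    rep_spec = synthetic.RegressionGeneratorSpec(
        n=n_train + n_cal + n_test,
        n_features=spec.n_features,
        noise=spec.noise,
        sigma=spec.sigma,
        seed=seed,
    )
    X, y, _ = synthetic.gen_regression_table(rep_spec)
    tr = slice(0, n_train)
    ca = slice(n_train, n_train + n_cal)
    te = slice(n_train + n_cal, None)
    if method == "absolute":
        fitted = _fit_point_model(model, X[tr], y[tr], seed)
        calib = reg.calibrate_absolute(y[ca], fitted.predict(X[ca]), alpha)
        intervals = reg.predict_interval_absolute(fitted.predict(X[te]), calib)
    else:
        learner = reg.QuantileGBM.for_alpha(alpha, random_state=seed)
        learner.fit(X[tr], y[tr])
        qlo, qhi = learner.predict_pair(X[ca])
        calib = reg.calibrate_cqr(y[ca], qlo, qhi, alpha)
        qlo, qhi = learner.predict_pair(X[te])
        intervals = reg.predict_interval_cqr(qlo, qhi, calib)
    report = regression_report(intervals, y[te])
    return report.empirical_marginal_coverage, report.average_interval_width


def coverage_experiment(
    generator,
    method: str,
    alpha: float,
    replicates: int,
    seed: int | None = None,
    *,
    n_cal: int = 2000,
    n_test: int = 5000,
    n_train: int = 1000,
    point_model: str = "linear",
) -> ExperimentSummary:
    """Monte-Carlo estimate of marginal coverage and efficiency.

    Each replicate independently regenerates data from ``generator`` (a
    :class:`~conformap.synthetic.ClassificationGeneratorSpec` or
    :class:`~conformap.synthetic.RegressionGeneratorSpec`; its ``n`` and
    ``seed`` are overridden per replicate), recalibrates with ``method``
    (``"lac"``, ``"mondrian"``, ``"absolute"`` or ``"cqr"``) at ``alpha``,
    and re-evaluates on fresh test data.  Replicates whose calibration is
    degenerate are dropped and counted.  Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    classification = isinstance(generator, synthetic.ClassificationGeneratorSpec)
    if classification and method not in ("lac", "mondrian"):
        raise ValueError(f"method {method!r} does not apply to classification data")
    if not classification and method not in ("absolute", "cqr"):
        raise ValueError(f"method {method!r} does not apply to regression data")
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    coverages, efficiencies, dropped = [], [], 0
    for rep_seed in child_seeds:
        try:
            if classification:
                cov, eff = _one_classification_rep(
                    generator, method, alpha, n_cal, n_test, int(rep_seed)
                )
            else:
                cov, eff = _one_regression_rep(
                    generator, method, alpha, n_cal, n_test, n_train,
                    point_model, int(rep_seed),
                )
        except DegenerateCalibrationError:
            dropped += 1
            continue
        coverages.append(cov)
        efficiencies.append(eff)
    if not coverages:
        raise DegenerateCalibrationError(
            "every replicate had a degenerate calibration; increase n_cal"
        )
    coverages = np.asarray(coverages)
    efficiencies = np.asarray(efficiencies)
    sd = float(coverages.std(ddof=1)) if coverages.size > 1 else 0.0
    return ExperimentSummary(
        method=method,
        alpha=float(alpha),
        replicates=int(coverages.size),
        dropped=dropped,
        mean_coverage=float(coverages.mean()),
        sd_coverage=sd,
        mc_se=sd / float(np.sqrt(coverages.size)),
        mean_efficiency=float(efficiencies.mean()),
        sd_efficiency=(
            float(efficiencies.std(ddof=1)) if efficiencies.size > 1 else 0.0
        ),
        efficiency_metric=(
            "average_set_size" if classification else "average_interval_width"
        ),
    )
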