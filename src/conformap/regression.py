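"""Split-conformal regression intervals.

Two scoring rules are provided.  The absolute-residual rule scores each
calibration instance by ``|y - yhat|`` and adds/subtracts the conformal
quantile of those residuals around the point prediction — every interval
then has the same width, the rule's known lack of adaptability.
Conformalized quantile regression (CQR) instead starts from fitted lower
and upper conditional-quantile predictions and scores the signed
exceedance ``max(qlo - y, y - qhi)``; the conformal margin (possibly
negative, shrinking the band) is added outward, so harder instances with
wider fitted bands keep wider intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    CalibrationScores,
    ToleranceLevel,
    _check_alpha,
    conformal_quantile,
)

__all__ = [
    "PredictionIntervals",
    "RegressionCalibration",
    "absolute_residual_scores",
    "calibrate_absolute",
    "predict_interval_absolute",
    "cqr_scores",
    "calibrate_cqr",
    "predict_interval_cqr",
    "repair_quantile_pairs",
    "QuantileGBM",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class PredictionIntervals:
    """Lower/upper interval bounds per instance, in response units."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float).ravel()
        upper = np.asarray(self.upper, dtype=float).ravel()
        if lower.shape != upper.shape:
            raise ValueError("lower and upper must have equal length")
        if np.any(lower > upper):
            raise ValueError("interval lower bounds must not exceed upper bounds")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        return (self.lower <= y) & (y <= self.upper)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lower": self.lower, "upper": self.upper, "width": self.width}
        )


@dataclass(frozen=True)
class RegressionCalibration:
    """Conformal margin for interval construction.

    ``method`` is ``"absolute_residual"`` (qhat >= 0) or ``"cqr"`` (qhat may
    be negative, shrinking the fitted quantile band).
    """

    method: str
    qhat: float
    alpha: float
    n_cal: int

    def __post_init__(self) -> None:
        if self.method not in ("absolute_residual", "cqr"):
            raise ValueError(f"unknown regression method {self.method!r}")
        if self.method == "absolute_residual" and self.qhat < 0:
            raise ValueError("absolute-residual margin cannot be negative")

    def to_json(self) -> dict:
        return {
            "schema": "conformap-calibration-v1",
            "task": "regression",
            "method": self.method,
            "qhat": float(self.qhat),
            "alpha": float(self.alpha),
            "n_cal": int(self.n_cal),
        }

    @classmethod
    def from_json(cls, doc: dict) -> "RegressionCalibration":
        return cls(
            method=doc["method"],
            qhat=float(doc["qhat"]),
            alpha=float(doc["alpha"]),
            n_cal=int(doc["n_cal"]),
        )


def absolute_residual_scores(y, yhat) -> CalibrationScores:
    """Nonconformity as the absolute residual ``|y - yhat|``."""
    y = _as_1d(y, "y")
    yhat = _as_1d(yhat, "yhat")
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return CalibrationScores(np.abs(y - yhat))


def calibrate_absolute(y, yhat, alpha, **kwargs) -> RegressionCalibration:
    """Conformal quantile of absolute residuals -> constant-width margin."""
    if isinstance(alpha, ToleranceLevel):
        alpha = alpha.alpha
    scores = absolute_residual_scores(y, yhat)
    thr = conformal_quantile(scores, alpha, **kwargs)
    return RegressionCalibration(
        method="absolute_residual", qhat=thr.qhat, alpha=thr.alpha, n_cal=thr.n_cal
    )


def predict_interval_absolute(yhat, calibration: RegressionCalibration) -> PredictionIntervals:
    """``[yhat - qhat, yhat + qhat]``: identical width 2*qhat everywhere."""
    if calibration.method != "absolute_residual":
        raise ValueError(
            f"calibration method is {calibration.method!r}, expected "
            "'absolute_residual'"
        )
    yhat = np.asarray(yhat, dtype=float).ravel()
    return PredictionIntervals(
        lower=yhat - calibration.qhat, upper=yhat + calibration.qhat
    )


def repair_quantile_pairs(qlo, qhi) -> tuple[np.ndarray, np.ndarray]:
    """Sort crossed quantile predictions so qlo <= qhi elementwise.

    Quantile learners occasionally cross; sorting keeps the scores defined
    without discarding instances.
    """
    qlo = np.asarray(qlo, dtype=float).ravel()
    qhi = np.asarray(qhi, dtype=float).ravel()
    if qlo.shape != qhi.shape:
        raise ValueError("qlo and qhi must have equal length")
    return np.minimum(qlo, qhi), np.maximum(qlo, qhi)


def cqr_scores(y, qlo, qhi) -> CalibrationScores:
    """CQR nonconformity ``max(qlo - y, y - qhi)``.

    Negative when y lies strictly inside the fitted quantile band.
    """
    y = _as_1d(y, "y")
    qlo, qhi = repair_quantile_pairs(_as_1d(qlo, "qlo"), _as_1d(qhi, "qhi"))
    if y.shape != qlo.shape:
        raise ValueError("y and quantile pairs must have equal length")
    return CalibrationScores(np.maximum(qlo - y, y - qhi))


def calibrate_cqr(y, qlo, qhi, alpha, **kwargs) -> RegressionCalibration:
    """Conformal margin for fitted (lo, hi) quantile predictions."""
    if isinstance(alpha, ToleranceLevel):
        alpha = alpha.alpha
    scores = cqr_scores(y, qlo, qhi)
    thr = conformal_quantile(scores, alpha, **kwargs)
    return RegressionCalibration(
        method="cqr", qhat=thr.qhat, alpha=thr.alpha, n_cal=thr.n_cal
    )


def predict_interval_cqr(qlo, qhi, calibration: RegressionCalibration) -> PredictionIntervals:
    """``[qlo - qhat, qhi + qhat]``; a negative margin shrinks the band.

    After shrinkage the bounds are re-ordered so lower <= upper always.
    """
    if calibration.method != "cqr":
        raise ValueError(
            f"calibration method is {calibration.method!r}, expected 'cqr'"
        )
    qlo, qhi = repair_quantile_pairs(qlo, qhi)
    lower = qlo - calibration.qhat
    upper = qhi + calibration.qhat
    return PredictionIntervals(
        lower=np.minimum(lower, upper), upper=np.maximum(lower, upper)
    )


class QuantileGBM:
    """Reference gradient-boosted quantile learner (LightGBM pinball loss).

    Fits one model per nominal quantile level; the conformal layer treats
    it as a black box, and any object with the same ``fit``/``predict_pair``
    surface can replace it.  The default nominal pair (alpha/2, 1 - alpha/2)
    matches the common 5th/95th-percentile choice at 90% confidence.
    """

    def __init__(
        self,
        lo: float = 0.05,
        hi: float = 0.95,
        n_estimators: int = 100,
        random_state: int | None = None,
        **params,
    ):
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("need 0 < lo < hi < 1")
        self.lo = lo
        self.hi = hi
        self._params = dict(
            n_estimators=n_estimators,
            random_state=random_state,
            verbose=-1,
            **params,
        )
        self._models = None

    @classmethod
    def for_alpha(cls, alpha: float, **params) -> "QuantileGBM":
        alpha = _check_alpha(alpha)
        return cls(lo=alpha / 2.0, hi=1.0 - alpha / 2.0, **params)

    def fit(self, X, y) -> "QuantileGBM":
        from lightgbm import LGBMRegressor

        self._models = {}
        for level in (self.lo, self.hi):
            model = LGBMRegressor(objective="quantile", alpha=level, **self._params)
            model.fit(np.asarray(X), np.asarray(y, dtype=float).ravel())
            self._models[level] = model
        return self

    def predict_pair(self, X) -> tuple[np.ndarray, np.ndarray]:
        if self._models is None:
            raise RuntimeError("fit must be called before predict_pair")
        import warnings

        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about feature names even for
            # consistent ndarray fit/predict round trips
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            qlo = self._models[self.lo].predict(np.asarray(X))
            qhi = self._models[self.hi].predict(np.asarray(X))
        return repair_quantile_pairs(qlo, qhi)
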