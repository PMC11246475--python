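"""Least-ambiguous set-valued (LAC) conformal classification.

The classifier supplies a probability-like score per class; the hinge
nonconformity score of a calibration instance is ``1 - p_true``.  The
conformal quantile of those scores, mapped back to the probability scale
as ``t = 1 - qhat``, gives a probability threshold: every class whose
score meets the threshold (inclusive) enters the prediction set.  Set
cardinality is the uncertainty measure — empty sets mark outlying inputs,
singletons confident ones, larger sets ambiguity.

Mondrian (class-conditional) calibration repeats the procedure within
each true-class stratum, trading some statistical efficiency for an
approximate per-class coverage guarantee.

Probability vectors may be uncalibrated pseudo-probabilities: entries must
lie in [0, 1] but need not sum to one, and they are never renormalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationScores,
    DegenerateCalibrationError,
    ToleranceLevel,
    _check_alpha,
    adjusted_quantile_level,
    conformal_quantile,
    minimum_calibration_size,
)

__all__ = [
    "PredictionSets",
    "LacCalibration",
    "MondrianCalibration",
    "hinge_scores",
    "calibrate_lac",
    "predict_set",
    "calibrate_mondrian",
    "predict_set_mondrian",
]


def _as_prob_matrix(probs, classes=None):
    """Validate probability-like scores; return (matrix (n, C), roster, squeeze)."""
    if isinstance(probs, pd.DataFrame):
        roster = list(probs.columns) if classes is None else list(classes)
        matrix = probs.to_numpy(dtype=float)
    else:
        matrix = np.asarray(probs, dtype=float)
        roster = None if classes is None else list(classes)
    squeeze = matrix.ndim == 1
    if squeeze:
        matrix = matrix[None, :]
    if matrix.ndim != 2:
        raise ValueError("probability input must be a vector or an (n, C) matrix")
    if roster is None:
        roster = list(range(matrix.shape[1]))
    if len(roster) != matrix.shape[1]:
        raise ValueError(
            f"class roster has {len(roster)} entries but probabilities have "
            f"{matrix.shape[1]} columns"
        )
    if not np.all(np.isfinite(matrix)):
        raise ValueError("probability scores must be finite (no missing values)")
    if matrix.min() < 0.0 or matrix.max() > 1.0:
        raise ValueError(
            "probability scores must lie in [0, 1]; inputs are rejected, not clipped"
        )
    return matrix, roster, squeeze


def _label_indices(labels, roster) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(roster)}
    labels = np.asarray(labels).ravel()
    try:
        return np.array([lookup[l] for l in labels.tolist()], dtype=int)
    except KeyError as err:
        raise ValueError(
            f"label {err.args[0]!r} is not in the class roster {list(roster)!r}"
        ) from None


def hinge_scores(cal_probs, cal_labels, *, classes=None) -> CalibrationScores:
    """Hinge nonconformity scores ``1 - f(x)[y_true]`` for each instance."""
    matrix, roster, _ = _as_prob_matrix(cal_probs, classes)
    idx = _label_indices(cal_labels, roster)
    if idx.size != matrix.shape[0]:
        raise ValueError("labels and probability rows must have equal length")
    return CalibrationScores(1.0 - matrix[np.arange(matrix.shape[0]), idx])


@dataclass(frozen=True)
class PredictionSets:
    """Set-valued predictions over a fixed class roster.

    ``membership`` is a boolean (n, C) matrix; row i's prediction set is the
    classes whose column is True.  Cardinality per row is the set length.
    """

    membership: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=bool)
        if m.ndim == 1:
            m = m[None, :]
        if m.shape[1] != len(self.classes):
            raise ValueError("membership width must equal roster size")
        object.__setattr__(self, "membership", m)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def cardinality(self) -> np.ndarray:
        return self.membership.sum(axis=1)

    def sets(self) -> list[frozenset]:
        labels = np.asarray(self.classes, dtype=object)
        return [frozenset(labels[row]) for row in self.membership]

    def contains(self, labels) -> np.ndarray:
        """Boolean per instance: is the given true label inside the set?"""
        idx = _label_indices(labels, self.classes)
        return self.membership[np.arange(len(idx)), idx]

    def to_frame(self) -> pd.DataFrame:
        """0/1 membership column per class plus a set_size column."""
        frame = pd.DataFrame(
            self.membership.astype(int), columns=[str(c) for c in self.classes]
        )
        frame["set_size"] = self.cardinality
        return frame


@dataclass(frozen=True)
class LacCalibration:
    """Probability thresholds ``t(alpha) = 1 - qhat(alpha)`` for LAC sets.

    Thresholds are non-decreasing in alpha: lower tolerance (higher
    confidence) lowers the bar for inclusion, giving larger sets.
    """

    thresholds: dict[float, float]
    classes: tuple
    n_cal: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(
            self, "thresholds", {float(a): float(t) for a, t in self.thresholds.items()}
        )

    def threshold(self, alpha: float) -> float:
        alpha = float(alpha)
        if alpha not in self.thresholds:
            raise KeyError(
                f"alpha={alpha:g} was not calibrated; available: "
                f"{sorted(self.thresholds)}"
            )
        return self.thresholds[alpha]

    def to_json(self) -> dict:
        return {
            "schema": "conformap-calibration-v1",
            "task": "classification",
            "method": "lac",
            "classes": [str(c) for c in self.classes],
            "n_cal": self.n_cal,
            "thresholds": {f"{a:g}": t for a, t in sorted(self.thresholds.items())},
        }

    @classmethod
    def from_json(cls, doc: dict) -> "LacCalibration":
        return cls(
            thresholds={float(a): float(t) for a, t in doc["thresholds"].items()},
            classes=tuple(doc["classes"]),
            n_cal=int(doc["n_cal"]),
        )


def calibrate_lac(cal_probs, cal_labels, alpha, *, classes=None) -> LacCalibration:
    """Calibrate the LAC probability threshold(s) from a calibration split.

    ``alpha`` may be a single tolerance or an iterable (a confidence grid in
    the style of publishing thresholds for 0.70..0.95 confidence).  Each
    threshold is ``t = 1 - qhat`` with qhat the conformal quantile of the
    hinge scores.
    """
    matrix, roster, _ = _as_prob_matrix(cal_probs, classes)
    scores = hinge_scores(matrix, cal_labels, classes=roster)
    if isinstance(alpha, (float, int, ToleranceLevel)):
        alphas = [alpha]
    else:
        alphas = list(alpha)
    thresholds = {}
    for a in alphas:
        if isinstance(a, ToleranceLevel):
            a = a.alpha
        qhat = conformal_quantile(scores, a).qhat
        thresholds[float(a)] = max(0.0, 1.0 - qhat)
    return LacCalibration(thresholds=thresholds, classes=roster, n_cal=scores.n_cal)


def predict_set(probs, calibration: LacCalibration, alpha: float) -> PredictionSets:
    """LAC prediction sets: every class with ``f(x)[y] >= t(alpha)``.

    The comparison is boundary-inclusive and empty sets are retained — an
    empty set flags an input unlike anything seen in calibration.
    """
    matrix, roster, _ = _as_prob_matrix(probs, calibration.classes)
    t = calibration.threshold(alpha)
    return PredictionSets(membership=matrix >= t, classes=roster)


@dataclass(frozen=True)
class MondrianCalibration:
    """Per-class probability thresholds from class-conditional calibration.

    ``flagged`` lists classes whose calibration subset was too small for the
    requested alpha; those classes fall back to an always-include threshold
    of 0, which keeps their conditional coverage (uninformatively) valid.
    """

    thresholds: dict
    n_cal_per_class: dict
    alpha: float
    classes: tuple
    flagged: tuple = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "flagged", tuple(self.flagged))
        missing = [c for c in self.classes if c not in self.thresholds]
        if missing:
            raise ValueError(f"missing thresholds for classes {missing!r}")

    def to_json(self) -> dict:
        return {
            "schema": "conformap-calibration-v1",
            "task": "classification",
            "method": "mondrian",
            "alpha": self.alpha,
            "classes": [str(c) for c in self.classes],
            "thresholds": {str(c): float(self.thresholds[c]) for c in self.classes},
            "n_cal_per_class": {
                str(c): int(self.n_cal_per_class[c]) for c in self.classes
            },
            "flagged": [str(c) for c in self.flagged],
        }

    @classmethod
    def from_json(cls, doc: dict) -> "MondrianCalibration":
        classes = tuple(doc["classes"])
        return cls(
            thresholds={c: float(doc["thresholds"][str(c)]) for c in classes},
            n_cal_per_class={c: int(doc["n_cal_per_class"][str(c)]) for c in classes},
            alpha=float(doc["alpha"]),
            classes=classes,
            flagged=tuple(doc.get("flagged", ())),
        )


def calibrate_mondrian(
    cal_probs, cal_labels, alpha: float, *, classes=None
) -> MondrianCalibration:
    """Class-conditional calibration: one LAC threshold per true-class stratum.

    A class with no calibration instances raises; a class whose stratum is
    smaller than the minimum size for alpha is flagged and assigned the
    always-include threshold 0.
    """
    matrix, roster, _ = _as_prob_matrix(cal_probs, classes)
    alpha = _check_alpha(alpha if not isinstance(alpha, ToleranceLevel) else alpha.alpha)
    idx = _label_indices(cal_labels, roster)
    empty = [roster[c] for c in range(len(roster)) if not np.any(idx == c)]
    if empty:
        raise ValueError(
            f"classes with zero calibration instances: {empty!r}; Mondrian "
            "calibration needs scores from every class"
        )
    thresholds, n_per, flagged = {}, {}, []
    for c, name in enumerate(roster):
        sub = np.flatnonzero(idx == c)
        scores = CalibrationScores(1.0 - matrix[sub, c])
        n_per[name] = scores.n_cal
        if adjusted_quantile_level(scores.n_cal, alpha).degenerate:
            flagged.append(name)
            thresholds[name] = 0.0
        else:
            thresholds[name] = max(0.0, 1.0 - conformal_quantile(scores, alpha).qhat)
    return MondrianCalibration(
        thresholds=thresholds,
        n_cal_per_class=n_per,
        alpha=alpha,
        classes=roster,
        flagged=tuple(flagged),
    )


def predict_set_mondrian(probs, calibration: MondrianCalibration) -> PredictionSets:
    """Prediction sets with a class-specific threshold: ``f(x)[y] >= t_y``."""
    matrix, roster, _ = _as_prob_matrix(probs, calibration.classes)
    t = np.array([calibration.thresholds[c] for c in roster], dtype=float)
    return PredictionSets(membership=matrix >= t[None, :], classes=roster)
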