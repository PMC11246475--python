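"""Finite-sample conformal calibration primitives.

Split conformal prediction turns the nonconformity scores of a held-out
calibration set into a threshold with a distribution-free coverage
guarantee: if calibration and test data are exchangeable, the region built
from the threshold contains the truth with probability at least
``1 - alpha``.  The finite-sample correction replaces the naive
``1 - alpha`` quantile of the score bag with the adjusted level

    q_level = ceil((n_cal + 1) * (1 - alpha)) / n_cal

realized as the k-th smallest order statistic, ``k = ceil((n_cal + 1) *
(1 - alpha))``, without interpolation (interpolation would void the
guarantee).

This module also provides the three-way train/calibration/test split that
every split-conformal workflow starts from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToleranceLevel",
    "CalibrationScores",
    "QuantileLevel",
    "ConformalThreshold",
    "SplitAssignment",
    "DegenerateCalibrationError",
    "adjusted_quantile_level",
    "conformal_quantile",
    "split_three_way",
    "minimum_calibration_size",
]

ROLES = ("train", "calibration", "test")


class DegenerateCalibrationError(ValueError):
    """Raised when the calibration set is too small for the requested alpha.

    The adjusted quantile level exceeds 1, so no order statistic of the
    score bag delivers the guarantee.  The message names the minimum
    calibration size for the given tolerance.
    """


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not (0.0 < alpha < 1.0) or not math.isfinite(alpha):
        raise ValueError(f"tolerance level alpha must lie in (0, 1), got {alpha!r}")
    return alpha


@dataclass(frozen=True)
class ToleranceLevel:
    """Acceptable error proportion ``alpha``; confidence is ``1 - alpha``."""

    alpha: float

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)

    @property
    def confidence(self) -> float:
        return 1.0 - self.alpha


@dataclass(frozen=True)
class CalibrationScores:
    """A bag of nonconformity scores from the calibration split.

    Scores must be finite; missing values are not admitted because every
    calibration instance contributes one order statistic to the quantile.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size < 1:
            raise ValueError("calibration requires at least one score")
        if not np.all(np.isfinite(values)):
            raise ValueError("nonconformity scores must all be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_cal(self) -> int:
        return int(self.values.size)

    @classmethod
    def from_csv(cls, path, column: str | None = None) -> "CalibrationScores":
        """Read scores from a single-column CSV (or a named column)."""
        frame = pd.read_csv(path)
        if column is None:
            if frame.shape[1] != 1:
                raise ValueError(
                    f"{path} has {frame.shape[1]} columns; pass column= to pick one"
                )
            column = frame.columns[0]
        return cls(frame[column].to_numpy())


@dataclass(frozen=True)
class QuantileLevel:
    """The finite-sample adjusted quantile level.

    ``degenerate`` is set when the adjusted ratio exceeds 1, i.e. the
    calibration set is too small for the requested tolerance.
    """

    q_level: float
    k: int
    n_cal: int
    alpha: float
    degenerate: bool


@dataclass(frozen=True)
class ConformalThreshold:
    """The conformal quantile of a score bag: qhat plus its provenance."""

    qhat: float
    alpha: float
    n_cal: int
    k: int

    def to_json(self) -> dict:
        return {
            "qhat": self.qhat,
            "alpha": self.alpha,
            "n_cal": self.n_cal,
            "order_statistic": self.k,
        }


def _order_statistic_index(n_cal: int, alpha: float) -> int:
    """k = ceil((n_cal + 1) * (1 - alpha)) with a few-ulp tolerant ceil.

    Binary floating point can land a hair above an exact integer product
    (e.g. 10 * 0.9); the epsilon keeps k from jumping one order statistic
    too high there while being far below the spacing of genuine non-integer
    products.
    """
    q = (n_cal + 1) * (1.0 - alpha)
    eps = max(4.0 * np.spacing(q), 1e-12)
    return int(math.ceil(q - eps))


def adjusted_quantile_level(n_cal: int, alpha: float | ToleranceLevel) -> QuantileLevel:
    """Finite-sample adjusted quantile level for a calibration set of size n_cal.

    Returns ``ceil((1 + n_cal) * (1 - alpha)) / n_cal`` with the degenerate
    flag set when that ratio exceeds 1 (no valid order statistic exists).
    """
    if isinstance(alpha, ToleranceLevel):
        alpha = alpha.alpha
    alpha = _check_alpha(alpha)
    if not isinstance(n_cal, (int, np.integer)) or isinstance(n_cal, bool):
        raise TypeError(f"n_cal must be an integer, got {type(n_cal).__name__}")
    if n_cal < 1:
        raise ValueError(f"n_cal must be >= 1, got {n_cal}")
    k = _order_statistic_index(int(n_cal), alpha)
    return QuantileLevel(
        q_level=k / n_cal,
        k=k,
        n_cal=int(n_cal),
        alpha=alpha,
        degenerate=k > n_cal,
    )


def minimum_calibration_size(alpha: float) -> int:
    """Smallest n_cal for which the adjusted quantile level is attainable."""
    alpha = _check_alpha(alpha)
    n = max(1, math.ceil((1.0 - alpha) / alpha) - 1)
    while adjusted_quantile_level(n, alpha).degenerate:
        n += 1
    return n


def conformal_quantile(
    scores: CalibrationScores | Sequence[float] | np.ndarray,
    alpha: float | ToleranceLevel,
    *,
    on_degenerate: str = "raise",
) -> ConformalThreshold:
    """Conformal quantile: the k-th smallest score, k = ceil((n+1)(1-alpha)).

    Parameters
    ----------
    scores
        Calibration nonconformity scores.
    alpha
        Tolerance level in (0, 1).
    on_degenerate
        ``"raise"`` (default) raises :class:`DegenerateCalibrationError`
        naming the minimum calibration size; ``"inf"`` returns qhat = +inf,
        which yields full prediction sets / unbounded intervals — valid but
        uninformative.
    """
    if not isinstance(scores, CalibrationScores):
        scores = CalibrationScores(np.asarray(scores))
    if isinstance(alpha, ToleranceLevel):
        alpha = alpha.alpha
    alpha = _check_alpha(alpha)
    level = adjusted_quantile_level(scores.n_cal, alpha)
    if level.degenerate:
        if on_degenerate == "inf":
            return ConformalThreshold(
                qhat=math.inf, alpha=alpha, n_cal=scores.n_cal, k=level.k
            )
        raise DegenerateCalibrationError(
            f"calibration set of size {scores.n_cal} is too small for "
            f"alpha={alpha:g}; at least {minimum_calibration_size(alpha)} "
            "calibration scores are required"
        )
    ordered = np.sort(scores.values)
    qhat = float(ordered[level.k - 1])
    return ConformalThreshold(qhat=qhat, alpha=alpha, n_cal=scores.n_cal, k=level.k)


@dataclass(frozen=True)
class SplitAssignment:
    """One role per instance from the three-way split.

    ``roles`` holds the strings ``"train"``, ``"calibration"``, ``"test"``.
    """

    roles: np.ndarray
    ratios: tuple[float, float, float]
    seed: int | None = None
    counts: dict = field(init=False)

    def __post_init__(self) -> None:
        roles = np.asarray(self.roles)
        object.__setattr__(self, "roles", roles)
        counts = {r: int(np.sum(roles == r)) for r in ROLES}
        object.__setattr__(self, "counts", counts)

    def mask(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        return self.roles == role

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.mask(role))


def _largest_remainder_counts(n: int, ratios: np.ndarray) -> np.ndarray:
    exact = n * ratios
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    # ties broken by role order: stable argsort of descending remainder
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def split_three_way(
    n: int,
    ratios: Sequence[float] = (0.65, 0.20, 0.15),
    seed: int | None = None,
    *,
    groups: Sequence | None = None,
) -> SplitAssignment:
    """Randomly partition n instances into train/calibration/test.

    Counts follow the ratios by largest-remainder rounding; permutation uses
    numpy's PCG64 generator, so the split is reproducible across platforms
    for a fixed seed.  When ``groups`` is given (e.g. a country or source
    image per instance), whole groups are assigned to a single role and
    instance counts only approximate the ratios.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (3,):
        raise ValueError("ratios must be three fractions (train, calibration, test)")
    if np.any(ratios < 0):
        raise ValueError("ratios must be nonnegative")
    if abs(ratios.sum() - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got sum={ratios.sum()!r}")
    if n < 1:
        raise ValueError("n must be positive")
    if groups is None and n < np.count_nonzero(ratios):
        raise ValueError("n too small for the number of positive ratios")
    rng = np.random.default_rng(seed)
    roles = np.empty(n, dtype="<U11")
    if groups is None:
        counts = _largest_remainder_counts(n, ratios)
        flat = np.repeat(np.array(ROLES, dtype="<U11"), counts)
        roles[:] = flat[rng.permutation(n)]
    else:
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups must have one entry per instance")
        uniq, inverse = np.unique(groups, return_inverse=True)
        order = rng.permutation(uniq.size)
        group_sizes = np.bincount(inverse, minlength=uniq.size)
        quota = n * ratios  # remaining instance quota per role
        group_role = np.empty(uniq.size, dtype=int)
        for g in order:
            r = int(np.argmax(quota))
            group_role[g] = r
            quota[r] -= group_sizes[g]
        roles[:] = np.array(ROLES, dtype="<U11")[group_role[inverse]]
    return SplitAssignment(roles=roles, ratios=tuple(ratios), seed=seed)
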