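"""Synthetic data with known ground truth for validity experiments.

Coverage guarantees can only be *verified* when the true conditional
distribution is known.  The classification generator therefore emits
probability vectors and then samples each label *from that vector*, so the
vector is exactly the conditional label distribution and calibration/test
exchangeability holds by construction.  The regression generator records
the mean function and noise law, making the true conditional quantiles
computable for oracle comparisons.  The raster generator produces smooth,
spatially correlated probability fields (plus a nodata stripe) emulating
the structure of per-class probability bands from a land-cover model,
where class boundaries carry the ambiguity.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage, stats

from .raster import Raster

__all__ = [
    "ClassificationGeneratorSpec",
    "RegressionGeneratorSpec",
    "RegressionOracle",
    "gen_classification_table",
    "gen_regression_table",
    "gen_probability_raster",
]


@dataclass(frozen=True)
class ClassificationGeneratorSpec:
    """Multi-class probability-vector generator settings.

    ``difficulty`` is a concentration knob: each instance draws its vector
    from a Dirichlet with weight ``difficulty`` added on a focal class
    sampled from ``priors``.  Large values give near-one-hot vectors (easy,
    sets shrink to singletons); values near zero give flat vectors (hard,
    sets grow).  The default of 32 with nine classes mimics a land-cover
    model that is usually confident but ambiguous near class boundaries,
    yielding prediction sets of a couple of classes on average at 90%
    confidence.
    """

    n: int
    n_classes: int = 9
    difficulty: float = 32.0
    priors: tuple | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (self.difficulty > 0):
            raise ValueError("difficulty must be positive")
        if self.priors is not None:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != (self.n_classes,) or np.any(priors < 0):
                raise ValueError("priors must be n_classes nonnegative weights")
            if abs(priors.sum() - 1.0) > 1e-9:
                raise ValueError("priors must sum to 1")
            object.__setattr__(self, "priors", tuple(priors))


def gen_classification_table(
    spec: ClassificationGeneratorSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (probability matrix (n, C), labels sampled from each row)."""
    rng = np.random.default_rng(spec.seed)
    C = spec.n_classes
    priors = (
        np.full(C, 1.0 / C) if spec.priors is None else np.asarray(spec.priors)
    )
    focal = rng.choice(C, size=spec.n, p=priors)
    conc = np.ones((spec.n, C))
    conc[np.arange(spec.n), focal] += spec.difficulty
    # row-wise Dirichlet via normalized Gammas
    probs = rng.gamma(shape=conc)
    probs /= probs.sum(axis=1, keepdims=True)
    # sample each label from its own row: inverse-CDF on the row cumsum
    u = rng.random(spec.n)
    labels = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return probs, labels


@dataclass(frozen=True)
class RegressionGeneratorSpec:
    """Heights-like regression generator settings.

    The response emulates a canopy-height field: a smooth nonlinear mean of
    the first feature plus a linear trend, with Gaussian noise that is
    either homoscedastic (sd ``sigma``, metres) or heteroscedastic with sd
    ``sigma * (0.25 + 1.5 * x0)`` growing along the first feature — taller,
    structurally complex stands are harder to measure.
    """

    n: int
    n_features: int = 3
    noise: str = "homoscedastic"
    sigma: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if self.noise not in ("homoscedastic", "heteroscedastic"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class RegressionOracle:
    """True mean, noise scale and conditional quantiles of generated data."""

    mean: Callable[[np.ndarray], np.ndarray]
    noise_scale: Callable[[np.ndarray], np.ndarray]

    def quantiles(self, X, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        mu = self.mean(X)
        sd = self.noise_scale(X)
        return mu + stats.norm.ppf(lo) * sd, mu + stats.norm.ppf(hi) * sd


def _mean_fn(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = 10.0 + 8.0 * np.sin(2.5 * X[:, 0])
    if X.shape[1] > 1:
        out = out + 4.0 * X[:, 1]
    return out


def gen_regression_table(
    spec: RegressionGeneratorSpec,
) -> tuple[np.ndarray, np.ndarray, RegressionOracle]:
    """Return (features (n, d), responses, oracle with true quantiles)."""
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(0.0, 1.0, size=(spec.n, spec.n_features))
    if spec.noise == "homoscedastic":
        scale_fn = lambda A: np.full(np.atleast_2d(A).shape[0], spec.sigma)
    else:
        scale_fn = lambda A: spec.sigma * (0.25 + 1.5 * np.atleast_2d(A)[:, 0])
    y = _mean_fn(X) + rng.normal(scale=scale_fn(X))
    return X, y, RegressionOracle(mean=_mean_fn, noise_scale=scale_fn)


def gen_probability_raster(
    height: int,
    width: int,
    n_classes: int,
    correlation_length: float = 8.0,
    seed: int | None = None,
    nodata: float = -1.0,
) -> tuple[Raster, Raster]:
    """Spatially correlated probability raster plus sampled label raster.

    Per-class Gaussian random fields are smoothed with a Gaussian kernel of
    the given correlation length (pixels; 0 gives independent pixels) and
    mapped to the simplex with a softmax, so class "objects" emerge with
    ambiguous boundaries.  A vertical nodata stripe is always included so
    nodata propagation is exercised by default.  Labels are sampled
    per-pixel from the pixel's probability vector; label nodata is -1.
    """
    if height < 1 or width < 1:
        raise ValueError("raster dimensions must be positive")
    if not (2 <= n_classes <= 32):
        raise ValueError("n_classes must lie in [2, 32]")
    if correlation_length < 0:
        raise ValueError("correlation length must be nonnegative")
    rng = np.random.default_rng(seed)
    fields = rng.standard_normal((n_classes, height, width))
    if correlation_length > 0:
        fields = np.stack(
            [ndimage.gaussian_filter(f, sigma=correlation_length) for f in fields]
        )
        # restore unit variance lost to smoothing so peakedness is stable
        sd = fields.std()
        if sd > 0:
            fields /= sd
    logits = 2.0 * fields
    logits -= logits.max(axis=0, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=0, keepdims=True)

    u = rng.random((height, width))
    labels = (probs.cumsum(axis=0) < u[None, :, :]).sum(axis=0).astype(np.int16)

    stripe = slice(width // 2, width // 2 + max(1, width // 16))
    probs = probs.astype(np.float32)
    probs[:, :, stripe] = nodata
    labels[:, stripe] = -1

    band_names = tuple(f"class_{c}" for c in range(n_classes))
    prob_raster = Raster(data=probs, nodata=nodata, band_names=band_names)
    label_raster = Raster(data=labels[None, :, :], nodata=-1, band_names=("label",))
    return prob_raster, label_raster
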