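"""Spatial machinery for point-based species-mapping workflows.

Two pieces support modelling from georeferenced localities.  *Tilted
coordinates* project each point onto axes rotated by a set of angles,
supplying smooth location covariates that let a model absorb broad spatial
trends while damping the leakage that raw x/y coordinates invite under
spatial autocorrelation.  *Clustered spatial folds* group localities into
spatially compact clusters (k-means on the planar coordinates) and use
each cluster as one cross-validation fold, so the test fold is spatially
separated from its training complement — a standard guard against
optimistic accuracy under autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoldAssignment",
    "SpatialCVResult",
    "tilted_coordinates",
    "spatial_clustered_folds",
    "spatial_cv_confusion",
    "DEFAULT_ANGLES",
]

# the angle grid is configurable; this default spans a half-turn evenly
DEFAULT_ANGLES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)


def _as_coords(coords) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of planar x, y")
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")
    return arr


def tilted_coordinates(coords, angles=DEFAULT_ANGLES) -> np.ndarray:
    """Location features: the coordinate along axes tilted by each angle.

    Angles are in degrees (converted internally); feature(theta) =
    x*cos(theta) + y*sin(theta), so 0 deg returns x and 90 deg returns y.
    Returns an (n, len(angles)) feature matrix.
    """
    arr = _as_coords(coords)
    theta = np.radians(np.asarray(angles, dtype=float).ravel())
    if not np.all(np.isfinite(theta)):
        raise ValueError("angles must be finite")
    return arr[:, 0:1] * np.cos(theta)[None, :] + arr[:, 1:2] * np.sin(theta)[None, :]


@dataclass(frozen=True)
class FoldAssignment:
    """One fold index in [0, k) per point."""

    folds: np.ndarray
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        folds = np.asarray(self.folds, dtype=int)
        if folds.min(initial=0) < 0 or (folds.size and folds.max() >= self.k):
            raise ValueError("fold indices must lie in [0, k)")
        object.__setattr__(self, "folds", folds)

    def mask(self, fold: int) -> np.ndarray:
        return self.folds == fold


def spatial_clustered_folds(coords, k: int, seed: int | None = None) -> FoldAssignment:
    """Cluster localities into k spatially compact folds (k-means).

    Each k-means cluster on the raw planar coordinates becomes one fold;
    fold sizes are therefore uneven, following the spatial clustering of
    the data.  Deterministic for a fixed seed.
    """
    arr = _as_coords(coords)
    n = arr.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} points")
    if k == 1:
        return FoldAssignment(folds=np.zeros(n, dtype=int), k=1, seed=seed)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return FoldAssignment(folds=km.fit_predict(arr), k=k, seed=seed)


@dataclass(frozen=True)
class SpatialCVResult:
    """Summed confusion matrix and accuracy statistics from spatial CV.

    ``confusion[i, j]`` counts instances of true class i predicted as class
    j, summed over all folds; its total equals the instance count.
    """

    confusion: np.ndarray
    classes: tuple
    accuracy: float
    per_class_recall: dict
    per_class_precision: dict

    def to_json(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
            "per_class_precision": {
                str(k): v for k, v in self.per_class_precision.items()
            },
        }


def spatial_cv_confusion(
    features, labels, folds: FoldAssignment, model=None
) -> SpatialCVResult:
    """Leave-one-fold-out CV with a pluggable classifier.

    For each fold the model is trained on the complement and evaluated on
    the fold; per-fold confusion matrices are summed and accuracy
    statistics derived from the sum.  ``model`` is any scikit-learn style
    classifier (cloned per fold); default is a 100-tree random forest.
    """
    from sklearn.base import clone
    from sklearn.ensemble import RandomForestClassifier

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0] or X.shape[0] != folds.folds.size:
        raise ValueError("features, labels and folds must have equal length")
    if model is None:
        model = RandomForestClassifier(n_estimators=100, random_state=0)
    classes = np.unique(y)
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    for fold in range(folds.k):
        test = folds.mask(fold)
        train = ~test
        if not test.any():
            continue
        missing = [c for c in classes if not np.any(y[train] == c)]
        if missing:
            raise ValueError(
                f"fold {fold} holds every instance of class(es) {missing!r}; "
                "its training complement cannot learn them"
            )
        fitted = clone(model).fit(X[train], y[train])
        pred = fitted.predict(X[test])
        for t, p in zip(y[test], pred):
            confusion[index[t], index[p]] += 1
    total = confusion.sum()
    row = confusion.sum(axis=1)
    col = confusion.sum(axis=0)
    diag = np.diag(confusion)
    recall = {
        c: (float(diag[i] / row[i]) if row[i] else float("nan"))
        for i, c in enumerate(classes)
    }
    precision = {
        c: (float(diag[i] / col[i]) if col[i] else float("nan"))
        for i, c in enumerate(classes)
    }
    return SpatialCVResult(
        confusion=confusion,
        classes=tuple(classes.tolist()),
        accuracy=float(diag.sum() / total) if total else float("nan"),
        per_class_recall=recall,
        per_class_precision=precision,
    )
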