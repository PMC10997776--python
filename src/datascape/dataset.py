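"""Immutable point dataset and ambient-metric contracts.

A :class:`Dataset` is the raw input to every datascape computation: an
``n x d`` coordinate matrix, one unique identifier per row, and an optional
binary label column (e.g. outcome status in a clinical cohort).  A
:class:`Metric` wraps the ambient-space distance used to pick nearest
neighbors and weight graph edges; Euclidean is the default, but any
symmetric non-negative callable can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["Dataset", "Metric", "EUCLIDEAN", "get_metric", "pairwise_distances"]


@dataclass(frozen=True)
class Dataset:
    """An immutable ``n x d`` point matrix with ids and optional 0/1 labels.

    Parameters
    ----------
    points
        Real coordinate matrix, one observation per row.  All entries must
        be finite.
    ids
        ``n`` unique identifiers (any hashables; stored as an object array).
        Defaults to ``0..n-1``.
    labels
        Optional ``n`` binary labels (0/1).
    """

    points: np.ndarray
    ids: np.ndarray = None  # type: ignore[assignment]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(-1, 1)
        # zero rows are tolerated (empty sample results); zero columns are not
        if pts.ndim != 2 or pts.shape[1] < 1:
            raise ValueError("points must be a 2-d matrix with at least one column")
        if not np.isfinite(pts).all():
            bad = np.argwhere(~np.isfinite(pts))
            raise ValueError(
                f"non-finite coordinate at row {bad[0][0]}, column {bad[0][1]}"
            )
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

        ids = self.ids
        if ids is None:
            ids = np.arange(pts.shape[0])
        ids = np.asarray(ids, dtype=object)
        if ids.shape != (pts.shape[0],):
            raise ValueError("ids must have one entry per point")
        if len(set(ids.tolist())) != len(ids):
            raise ValueError("ids must be unique")
        ids.setflags(write=False)
        object.__setattr__(self, "ids", ids)

        if self.labels is not None:
            lab = np.asarray(self.labels, dtype=float)
            if lab.shape != (pts.shape[0],):
                raise ValueError("labels must have one entry per point")
            if not np.isin(lab, (0.0, 1.0)).all():
                raise ValueError("labels must be binary 0/1")
            lab = lab.astype(np.int8)
            lab.setflags(write=False)
            object.__setattr__(self, "labels", lab)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def index_of(self, point_id) -> int:
        """Row index of ``point_id``; raises ``KeyError`` if unknown."""
        idx = self._id_index().get(point_id)
        if idx is None:
            raise KeyError(f"unknown id: {point_id!r}")
        return idx

    def _id_index(self) -> dict:
        cache = getattr(self, "_id_index_cache", None)
        if cache is None:
            cache = {pid: i for i, pid in enumerate(self.ids)}
            object.__setattr__(self, "_id_index_cache", cache)
        return cache

    def drop_duplicates(self) -> "Dataset":
        """Return a dataset keeping the first row of each duplicated coordinate."""
        _, keep = np.unique(self.points, axis=0, return_index=True)
        keep = np.sort(keep)
        labels = None if self.labels is None else self.labels[keep]
        return Dataset(self.points[keep], self.ids[keep], labels)


@dataclass(frozen=True)
class Metric:
    """Ambient-space distance contract: symmetric, non-negative, zero on the diagonal."""

    func: Callable[[np.ndarray, np.ndarray], float]
    name: str = "custom"
    #: scipy ``cdist`` metric string when a vectorized path exists
    cdist_name: str | None = None

    def __call__(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(self.func(np.asarray(x, float), np.asarray(y, float)))


EUCLIDEAN = Metric(
    lambda x, y: float(np.linalg.norm(x - y)), name="euclidean", cdist_name="euclidean"
)

_REGISTRY: dict[str, Metric] = {
    "euclidean": EUCLIDEAN,
    "manhattan": Metric(
        lambda x, y: float(np.abs(x - y).sum()), name="manhattan", cdist_name="cityblock"
    ),
    "chebyshev": Metric(
        lambda x, y: float(np.abs(x - y).max()), name="chebyshev", cdist_name="chebyshev"
    ),
}


def get_metric(name_or_metric: str | Metric) -> Metric:
    """Resolve a metric by registry name, or pass a :class:`Metric` through."""
    if isinstance(name_or_metric, Metric):
        return name_or_metric
    try:
        return _REGISTRY[name_or_metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {name_or_metric!r}; known: {sorted(_REGISTRY)}"
        ) from None


def pairwise_distances(data: Dataset, metric: Metric = EUCLIDEAN) -> np.ndarray:
    """Full ``n x n`` symmetric ambient-distance matrix.

    Uses the vectorized scipy path when the metric advertises a ``cdist``
    name, otherwise evaluates the callable on every unordered pair.
    """
    pts = data.points
    if metric.cdist_name is not None:
        mat = cdist(pts, pts, metric=metric.cdist_name)
    else:
        n = data.n
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = metric(pts[i], pts[j])
    np.fill_diagonal(mat, 0.0)
    # enforce exact symmetry against float asymmetries in user callables
    return (mat + mat.T) / 2.0
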