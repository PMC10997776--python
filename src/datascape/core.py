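"""The Datascape: dataset + neighbor graph + union of local hulls.

The datascape couples three views of the same sample: the neighbor graph
(topology and geodesic metric), one convex hull per neighborhood (shape
and volume), and the set of globally extreme points (boundary).  A point
of the ambient space belongs to the datascape iff it lies inside at least
one local hull; a dataset point is *extreme* iff it is a vertex of every
local hull that contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dataset import Dataset, Metric, EUCLIDEAN, get_metric
from .graph import NeighborGraph, build_graph
from .hulls import LocalHull, build_hull_from_points

__all__ = ["Datascape", "build_datascape", "extreme_points", "contains"]


@dataclass
class Datascape:
    """Built datascape over a dataset.

    Hulls are constructed lazily per center and cached: graph-level
    operations (geodesics, risk scores, out-of-sample prediction) never
    pay the hull cost, while shape queries trigger construction on demand.
    """

    data: Dataset
    graph: NeighborGraph
    eps: float | None = None
    _hulls: dict[int, LocalHull] = field(default_factory=dict, repr=False)
    _extreme_idx: np.ndarray | None = field(default=None, repr=False)
    _center_tree: cKDTree | None = field(default=None, repr=False)

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def d(self) -> int:
        return self.data.d

    @property
    def k(self) -> int:
        return self.graph.k

    @property
    def metric(self) -> Metric:
        return self.graph.metric

    def hull(self, i: int) -> LocalHull:
        """Local hull of point i ({x_i} ∪ N(x_i), connecting neighbors excluded)."""
        h = self._hulls.get(i)
        if h is None:
            neigh = self.graph.neighbors(i, include_connecting=False)
            members = np.unique(np.concatenate([[i], neigh])).astype(int)
            h = build_hull_from_points(
                self.data.points[members], members, center_idx=i, eps=self.eps
            )
            self._hulls[i] = h
        return h

    def hulls(self) -> list[LocalHull]:
        return [self.hull(i) for i in range(self.n)]

    # -- shape queries -------------------------------------------------------

    def contains(self, q: np.ndarray) -> tuple[bool, list]:
        """Is q inside the union of local hulls?  Returns (flag, containing ids).

        Hulls are probed in order of ambient distance from q to their
        centers and the search short-circuits on the first hit, so the
        boolean is cheap for points that are inside; the id list then
        holds only the first containing hull's center id (diagnostics for
        a full scan are available via :meth:`containing_hulls`).
        """
        q = np.asarray(q, float).ravel()
        if q.shape[0] != self.d:
            raise ValueError(f"dimension mismatch: datascape d={self.d}, query d={q.shape[0]}")
        for i in self._centers_by_distance(q):
            if self.hull(i).contains(q):
                return True, [self.data.ids[i]]
        return False, []

    def containing_hulls(self, q: np.ndarray) -> list:
        """Ids of every hull containing q (full scan, no short-circuit)."""
        q = np.asarray(q, float).ravel()
        return [
            self.data.ids[i] for i in range(self.n) if self.hull(i).contains(q)
        ]

    def _centers_by_distance(self, q: np.ndarray) -> np.ndarray:
        if self.metric.name == "euclidean":
            if self._center_tree is None:
                self._center_tree = cKDTree(self.data.points)
            return self._center_tree.query(q, k=self.n)[1].ravel().astype(int)
        dists = np.array([self.metric(q, p) for p in self.data.points])
        return np.argsort(dists, kind="stable")

    # -- boundary ------------------------------------------------------------

    @property
    def extreme_indices(self) -> np.ndarray:
        if self._extreme_idx is None:
            self._extreme_idx = _extreme_indices(self)
        return self._extreme_idx

    @property
    def extreme_ids(self) -> list:
        return [self.data.ids[i] for i in self.extreme_indices]

    def is_extreme(self, point_id) -> bool:
        return self.data.index_of(point_id) in set(self.extreme_indices.tolist())


def _extreme_indices(ds: Datascape) -> np.ndarray:
    """Dataset points that are vertices of every hull containing them.

    Scans hull by hull: any dataset point strictly inside a hull (contained
    but not among that hull's vertices) is disqualified.  Candidate points
    per hull are pre-filtered by the hull's bounding box.
    """
    pts = ds.data.points
    non_extreme = np.zeros(ds.n, dtype=bool)
    for i in range(ds.n):
        h = ds.hull(i)
        lo, hi = h.bounding_box()
        pad = max(h.eps, 1e-12)
        cand = np.where(
            ((pts >= lo - pad) & (pts <= hi + pad)).all(axis=1) & ~non_extreme
        )[0]
        if len(cand) == 0:
            continue
        inside = h.contains_many(pts[cand])
        vset = set(h.vertex_indices.tolist())
        for c in cand[inside]:
            if int(c) not in vset:
                non_extreme[c] = True
    return np.where(~non_extreme)[0]


def build_datascape(
    data: Dataset,
    k: int,
    metric: Metric | str = EUCLIDEAN,
    connect: bool = True,
    eps: float | None = None,
) -> Datascape:
    """Build the neighbor graph and wrap it as a (lazy-hull) datascape."""
    graph = build_graph(data, k, get_metric(metric), connect=connect)
    return Datascape(data, graph, eps=eps)


def extreme_points(ds: Datascape) -> list:
    """Ids of the datascape's boundary (globally extreme) points."""
    return ds.extreme_ids


def contains(ds: Datascape, q: np.ndarray) -> tuple[bool, list]:
    """Membership of an arbitrary ambient point in the datascape's shape."""
    return ds.contains(q)
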