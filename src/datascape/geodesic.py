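"""Geodesic distances on the neighbor graph and out-of-sample insertion.

The geodesic distance between two points is the minimum cumulative edge
weight over graph paths; it approximates arc length on the underlying
manifold the way Isomap's graph distances do.  New points are inserted
non-destructively by wiring them to their k nearest dataset points with
ambient-metric weights; the original graph and hulls are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .core import Datascape
from .dataset import Metric

__all__ = [
    "GeodesicResult",
    "AugmentedGraph",
    "geodesic",
    "insert_point",
    "distance_to_boundary",
    "extremeness_scores",
]

_RTOL = 1e-9


@dataclass(frozen=True)
class GeodesicResult:
    """Shortest path between two vertices: ordered ids and cumulative weight."""

    path: tuple
    length: float

    @property
    def finite(self) -> bool:
        return np.isfinite(self.length)


def _restore_zero(w: float) -> float:
    # adjacency() encodes exact-zero weights as 1e-300 to survive CSR
    return 0.0 if w <= 1e-290 else float(w)


def _lexmin_path(
    adj: sp.csr_matrix, src: int, dst: int, d_src: np.ndarray, d_dst: np.ndarray
) -> list[int]:
    """Lexicographically smallest vertex sequence among shortest src→dst paths.

    Greedy walk on the shortest-path DAG: from each vertex pick the
    smallest-index neighbor that still lies on some shortest path.
    """
    total = d_src[dst]
    scale = max(total, 1.0)
    path = [src]
    u = src
    while u != dst:
        row = adj.getrow(u)
        best = None
        for v, w in zip(row.indices, row.data):
            w = _restore_zero(w)
            on_sp = (
                abs(d_src[u] + w - d_src[int(v)]) <= _RTOL * scale
                and abs(d_src[u] + w + d_dst[int(v)] - total) <= _RTOL * scale
            )
            # forbid standing still on zero-weight cycles
            if on_sp and int(v) not in path and (best is None or int(v) < best):
                best = int(v)
        if best is None:  # numerical dead end: fall back to any predecessor chain
            break
        path.append(best)
        u = best
    return path


def geodesic(
    ds: Datascape, i, j, use_connecting: bool = True
) -> GeodesicResult:
    """Shortest path between dataset points ``i`` and ``j`` (by id).

    With ``use_connecting=False`` the component-bridging edges are
    ignored; points in different natural components then get an
    infinite-length sentinel result (never an exception).
    """
    si, sj = ds.data.index_of(i), ds.data.index_of(j)
    if si == sj:
        return GeodesicResult((i,), 0.0)
    adj = ds.graph.adjacency(use_connecting=use_connecting)
    d_src = dijkstra(adj, directed=False, indices=si)
    if not np.isfinite(d_src[sj]):
        return GeodesicResult((), float("inf"))
    d_dst = dijkstra(adj, directed=False, indices=sj)
    path_idx = _lexmin_path(adj, si, sj, d_src, d_dst)
    ids = tuple(ds.data.ids[p] for p in path_idx)
    length = float(d_src[sj])
    return GeodesicResult(ids, 0.0 if length <= 1e-290 else length)


@dataclass
class AugmentedGraph:
    """Non-destructive single-point (or two-point) graph augmentation G_{x*}.

    The query point(s) occupy the last row(s) of the adjacency matrix;
    the base datascape is never modified and hulls are not rebuilt.
    """

    ds: Datascape
    queries: np.ndarray  # q x d
    #: per query: (neighbor vertex index in augmented space, weight)
    links: list[list[tuple[int, float]]]

    @property
    def n_base(self) -> int:
        return self.ds.n

    def query_index(self, which: int = 0) -> int:
        return self.n_base + which

    def adjacency(self, use_connecting: bool = True) -> sp.csr_matrix:
        base = self.ds.graph.adjacency(use_connecting=use_connecting).tocoo()
        nq = len(self.queries)
        ntot = self.n_base + nq
        rows = list(base.row)
        cols = list(base.col)
        vals = list(base.data)
        for qi, lk in enumerate(self.links):
            u = self.n_base + qi
            for v, w in lk:
                wv = w if w > 0 else 1e-300
                rows += [u, v]
                cols += [v, u]
                vals += [wv, wv]
        return sp.csr_matrix((vals, (rows, cols)), shape=(ntot, ntot))


def _k_nearest(
    points: np.ndarray, metric: Metric, q: np.ndarray, k: int
) -> list[tuple[int, float]]:
    if metric.cdist_name is not None:
        from scipy.spatial.distance import cdist

        d = cdist(q[None, :], points, metric=metric.cdist_name).ravel()
    else:
        d = np.array([metric(q, p) for p in points])
    order = np.lexsort((np.arange(len(d)), d))[: min(k, len(d))]
    return [(int(i), float(d[i])) for i in order]


def insert_point(ds: Datascape, q: np.ndarray) -> AugmentedGraph:
    """Insert q by connecting it to its k nearest dataset points.

    Edge weights are ambient distances; the augmentation is query-time
    only — the base graph, hulls and extreme set are unchanged.
    """
    q = np.asarray(q, float).ravel()
    if q.shape[0] != ds.d:
        raise ValueError(f"dimension mismatch: datascape d={ds.d}, query d={q.shape[0]}")
    links = _k_nearest(ds.data.points, ds.metric, q, ds.k)
    return AugmentedGraph(ds, q[None, :], [links])


def insert_pair(ds: Datascape, q0: np.ndarray, q1: np.ndarray) -> AugmentedGraph:
    """Insert two query points; the second may pick the first as a neighbor.

    Sequential insertion makes geodesics between coincident states
    degenerate to length 0, as expected for a stationary trajectory.
    """
    q0 = np.asarray(q0, float).ravel()
    q1 = np.asarray(q1, float).ravel()
    if q0.shape[0] != ds.d or q1.shape[0] != ds.d:
        raise ValueError("dimension mismatch in trajectory states")
    links0 = _k_nearest(ds.data.points, ds.metric, q0, ds.k)
    ext_points = np.vstack([ds.data.points, q0[None, :]])
    links1 = _k_nearest(ext_points, ds.metric, q1, ds.k)
    return AugmentedGraph(ds, np.vstack([q0, q1]), [links0, links1])


def geodesic_between_queries(aug: AugmentedGraph, use_connecting: bool = True) -> float:
    """Geodesic length between the two inserted queries of an AugmentedGraph."""
    adj = aug.adjacency(use_connecting)
    d = dijkstra(adj, directed=False, indices=aug.query_index(0))
    length = float(d[aug.query_index(1)])
    return 0.0 if length <= 1e-290 else length


def distance_to_boundary(ds: Datascape, q: np.ndarray) -> float:
    """Geodesic distance from q to the nearest extreme point, d_G(x*, E).

    A single multi-source Dijkstra sweep from the extreme set over the
    augmented graph G_{x*}.
    """
    ext = ds.extreme_indices
    if len(ext) == 0:
        raise ValueError(
            "empty extreme set: the datascape is ill-conditioned for boundary queries"
        )
    aug = insert_point(ds, q)
    adj = aug.adjacency(use_connecting=True)
    d = dijkstra(adj, directed=False, indices=ext, min_only=True)
    val = float(d[aug.query_index(0)])
    return 0.0 if val <= 1e-290 else val


def extremeness_scores(ds: Datascape) -> np.ndarray:
    """Per-point geodesic distance to the extreme set: 0 exactly on extremes.

    High scores trace the interior backbone of the shape (the points
    deepest inside the datascape).
    """
    ext = ds.extreme_indices
    if len(ext) == 0:
        raise ValueError("empty extreme set")
    adj = ds.graph.adjacency(use_connecting=True)
    d = dijkstra(adj, directed=False, indices=ext, min_only=True)
    d = np.asarray(d, float)
    d[ext] = 0.0
    # zero-weight sentinel edges can leave ~1e-300 residues; snap them
    d[d <= 1e-290] = 0.0
    return d
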