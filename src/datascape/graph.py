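"""Symmetrized, connected k-nearest-neighbor graph construction.

The neighbor graph abstracts the topology of the manifold the points were
sampled from.  Construction has four steps:

1. *natural neighbors* — each point's k closest points under the ambient
   metric (ties broken by ascending row index, so builds are deterministic);
2. *symmetrization* — the neighbor relation is made reciprocal by adding
   *enforced* neighbors: j is enforced for i whenever i is natural for j
   but not vice versa;
3. *component detection* — the symmetric graph may still be disconnected;
4. *connecting edges* — for every component pair the minimum-ambient-
   distance cross pair is a candidate; a minimum spanning tree over the
   component meta-graph selects the subset that reconnects the graph with
   the least total added weight.

Connecting edges exist only to make geodesics finite; they carry a
``connecting`` provenance tag and are excluded from hull construction and
from neighborhood-based scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree

from .dataset import Dataset, Metric, EUCLIDEAN, pairwise_distances

__all__ = [
    "NeighborGraph",
    "natural_neighbors",
    "symmetrize",
    "connected_components",
    "connect_components",
    "build_graph",
]

Provenance = Literal["natural", "enforced", "connecting"]

#: above this n the dense distance matrix is not materialized
DENSE_LIMIT = 8192


@dataclass
class NeighborGraph:
    """Undirected weighted neighbor graph over a :class:`Dataset`.

    Edges are stored once per unordered pair with their ambient-metric
    weight and a provenance tag (``natural`` for mutual k-NN pairs,
    ``enforced`` for one-sided pairs added by symmetrization,
    ``connecting`` for component bridges).
    """

    data: Dataset
    k: int
    metric: Metric
    #: per-vertex ordered natural neighbor indices (row index space)
    natural: list[np.ndarray]
    #: per-vertex enforced neighbor indices
    enforced: list[np.ndarray]
    #: per-vertex connecting neighbor indices
    connecting: list[np.ndarray]
    #: {(i, j) with i < j: (weight, provenance)}
    edges: dict[tuple[int, int], tuple[float, str]]

    @property
    def n(self) -> int:
        return self.data.n

    def neighbors(self, i: int, include_connecting: bool = False) -> np.ndarray:
        """Indices of i's graph neighbors N(x_i) = N_k ∪ N+ (optionally ∪ N_con)."""
        parts = [self.natural[i], self.enforced[i]]
        if include_connecting:
            parts.append(self.connecting[i])
        return np.unique(np.concatenate(parts)).astype(int)

    def adjacency(self, use_connecting: bool = True) -> sp.csr_matrix:
        """Symmetric CSR weight matrix (zero-weight edges kept via eps floor)."""
        rows, cols, vals = [], [], []
        for (i, j), (w, prov) in self.edges.items():
            if not use_connecting and prov == "connecting":
                continue
            # csr drops explicit zeros on arithmetic; encode exact-duplicate
            # edges with a tiny positive weight so connectivity survives
            wv = w if w > 0 else 1e-300
            rows += [i, j]
            cols += [j, i]
            vals += [wv, wv]
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def edge_list(self, use_connecting: bool = True) -> list[tuple[int, int, float, str]]:
        out = [
            (i, j, w, prov)
            for (i, j), (w, prov) in sorted(self.edges.items())
            if use_connecting or prov != "connecting"
        ]
        return out

    def num_components(self, use_connecting: bool = False) -> int:
        return int(_cc(self.adjacency(use_connecting), directed=False)[0])

    def circuit_rank(self, use_connecting: bool = False) -> int:
        """|E| - |V| + c: the number of independent cycles."""
        m = sum(
            1
            for _, (_, prov) in self.edges.items()
            if use_connecting or prov != "connecting"
        )
        return m - self.n + self.num_components(use_connecting)

    def component_labels(self, use_connecting: bool = False) -> np.ndarray:
        return _cc(self.adjacency(use_connecting), directed=False)[1]


def natural_neighbors(dist: np.ndarray, k: int) -> list[np.ndarray]:
    """Per-row ordered k-nearest neighbor indices from a distance matrix.

    Ties in distance are broken by ascending index.  ``k >= n`` is clamped
    to ``n - 1`` with a warning so that tiny fixtures remain usable.
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        warnings.warn(f"k={k} >= n={n}; clamping to {n - 1}", stacklevel=2)
        k = n - 1
    if k == 0:
        return [np.empty(0, dtype=int) for _ in range(n)]
    idx = np.arange(n)
    out = []
    for i in range(n):
        order = np.lexsort((idx, dist[i]))  # distance asc, index asc on ties
        order = order[order != i]
        out.append(order[:k].copy())
    return out


def symmetrize(natural: list[np.ndarray]) -> list[np.ndarray]:
    """Enforced neighbor sets N+(x_i) = {j : i ∈ N_k(x_j), j ∉ N_k(x_i)}."""
    n = len(natural)
    nat_sets = [set(a.tolist()) for a in natural]
    enforced: list[list[int]] = [[] for _ in range(n)]
    for j, neigh in enumerate(natural):
        for i in neigh:
            if j not in nat_sets[i]:
                enforced[i].append(j)
    return [np.array(sorted(e), dtype=int) for e in enforced]


def connected_components(
    n: int, edges: Iterable[tuple[int, int]]
) -> np.ndarray:
    """Component label per vertex for an undirected edge set."""
    rows, cols = [], []
    for i, j in edges:
        rows += [i, j]
        cols += [j, i]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return _cc(adj, directed=False)[1]


def _cross_component_minima(
    data: Dataset,
    metric: Metric,
    labels: np.ndarray,
    dist: np.ndarray | None,
) -> dict[tuple[int, int], tuple[float, int, int]]:
    """Minimum ambient distance and argmin point pair per component pair.

    Tie-break: smallest (i, j) index pair.
    """
    comps = np.unique(labels)
    members = {c: np.where(labels == c)[0] for c in comps}
    out: dict[tuple[int, int], tuple[float, int, int]] = {}
    for a_i, ca in enumerate(comps):
        for cb in comps[a_i + 1 :]:
            ia, ib = members[ca], members[cb]
            if dist is not None:
                block = dist[np.ix_(ia, ib)]
            else:
                from scipy.spatial.distance import cdist

                if metric.cdist_name is not None:
                    block = cdist(
                        data.points[ia], data.points[ib], metric=metric.cdist_name
                    )
                else:
                    block = np.array(
                        [
                            [metric(data.points[i], data.points[j]) for j in ib]
                            for i in ia
                        ]
                    )
            flat = np.argwhere(block == block.min())
            # deterministic: smallest (row, col) among minima
            r, c = min(map(tuple, flat))
            out[(int(ca), int(cb))] = (float(block[r, c]), int(ia[r]), int(ib[c]))
    return out


def connect_components(
    data: Dataset,
    metric: Metric,
    labels: np.ndarray,
    dist: np.ndarray | None = None,
) -> list[tuple[int, int, float]]:
    """Minimum-total-weight connecting edges Con(G_0).

    For every component pair the candidate edge is the globally closest
    cross pair; Kruskal's MST over the component meta-graph then picks the
    sufficient subset with minimal total added weight.  Returns
    ``[(i, j, weight), ...]``; empty when the graph is already connected.
    """
    comps = np.unique(labels)
    if len(comps) <= 1:
        return []
    minima = _cross_component_minima(data, metric, labels, dist)
    # Kruskal over the meta-graph
    cand = sorted(
        (w, ca, cb, i, j) for (ca, cb), (w, i, j) in minima.items()
    )
    parent = {int(c): int(c) for c in comps}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[int, int, float]] = []
    for w, ca, cb, i, j in cand:
        ra, rb = find(ca), find(cb)
        if ra != rb:
            parent[ra] = rb
            chosen.append((min(i, j), max(i, j), w))
        if len(chosen) == len(comps) - 1:
            break
    return chosen


def _knn_from_tree(data: Dataset, k: int) -> list[np.ndarray]:
    # Euclidean large-n path: spatial index instead of the dense matrix
    tree = cKDTree(data.points)
    dd, ii = tree.query(data.points, k=k + 1)
    out = []
    for i in range(data.n):
        row = [int(j) for j in ii[i] if j != i][:k]
        out.append(np.array(row, dtype=int))
    return out


def build_graph(
    data: Dataset,
    k: int,
    metric: Metric = EUCLIDEAN,
    connect: bool = True,
    dense_limit: int = DENSE_LIMIT,
) -> NeighborGraph:
    """Build the full symmetrized (and optionally connected) neighbor graph.

    Parameters
    ----------
    data, k, metric
        Point set, neighbor count, ambient metric.
    connect
        When False, component-bridging edges are skipped; geodesics between
        components are then infinite.  Used by the circle distance-error
        experiment, which measures errors on the raw graph.
    dense_limit
        Maximum n for which the full distance matrix is materialized.
        Above it, Euclidean neighbor search goes through a k-d tree and
        cross-component minima are computed blockwise.
    """
    n = data.n
    if n == 0:
        raise ValueError("cannot build a graph over an empty dataset")
    if n == 1:
        return NeighborGraph(
            data, k, metric, [np.empty(0, int)], [np.empty(0, int)], [np.empty(0, int)], {}
        )
    dist: np.ndarray | None = None
    if n <= dense_limit or metric.cdist_name is None:
        dist = pairwise_distances(data, metric)
        natural = natural_neighbors(dist, k)
    else:
        kk = min(k, n - 1)
        if kk < k:
            warnings.warn(f"k={k} >= n={n}; clamping to {n - 1}", stacklevel=2)
        natural = _knn_from_tree(data, kk)
    enforced = symmetrize(natural)

    def weight(i: int, j: int) -> float:
        if dist is not None:
            return float(dist[i, j])
        return metric(data.points[i], data.points[j])

    edges: dict[tuple[int, int], tuple[float, str]] = {}
    nat_sets = [set(a.tolist()) for a in natural]
    for i in range(n):
        for j in natural[i]:
            key = (min(i, int(j)), max(i, int(j)))
            if key in edges:
                continue
            prov = "natural" if (i in nat_sets[int(j)]) else "enforced"
            edges[key] = (weight(*key), prov)

    connecting: list[list[int]] = [[] for _ in range(n)]
    if connect:
        labels = connected_components(n, edges.keys())
        for i, j, w in connect_components(data, metric, labels, dist):
            edges[(i, j)] = (w, "connecting")
            connecting[i].append(j)
            connecting[j].append(i)

    return NeighborGraph(
        data,
        k,
        metric,
        natural,
        enforced,
        [np.array(sorted(c), dtype=int) for c in connecting],
        edges,
    )
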