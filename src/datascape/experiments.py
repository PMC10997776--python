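"""Quantitative synthetic experiments.

Two studies ship with the package:

* the *circle distance-error curve*: how well graph geodesics recover arc
  length on a unit circle as the neighbor count k varies, measured on the
  raw (unconnected) graph with disconnected pairs standardized to the
  maximal error 1;
* a *labelled-cohort benchmark*: stratified 4-fold evaluation of the
  datascape's unsupervised neighborhood risk score against held-out
  labels, with a plain k-NN-vote classifier as the reference point.

A cheap k-scan over component counts and circuit ranks supports choosing
k by tracking when the graph becomes connected and when its first
independent cycles appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc, dijkstra
from sklearn.model_selection import StratifiedKFold

from .core import Datascape, build_datascape
from .dataset import Dataset, Metric, EUCLIDEAN, pairwise_distances
from .graph import natural_neighbors, symmetrize
from .scoring import evaluate_auc, predict_score
from .simulate import arc_distances, gen_circle, gen_cohort

__all__ = [
    "ErrorCurve",
    "circle_error_experiment",
    "mean_standardized_error",
    "k_scan",
    "KScanResult",
    "cohort_benchmark",
    "knn_vote_scores",
]


# ---------------------------------------------------------------------------
# circle distance-error experiment


@dataclass(frozen=True)
class ErrorCurve:
    """Mean standardized geodesic-vs-arc error per k, on one circle sample."""

    ks: tuple[int, ...]
    errors: tuple[float, ...]
    n: int
    seed: int

    def argmin_k(self) -> int:
        return self.ks[int(np.argmin(self.errors))]

    def error_at(self, k: int) -> float:
        return self.errors[self.ks.index(k)]


def symmetric_knn_adjacency(dist: np.ndarray, k: int) -> sp.csr_matrix:
    """Natural ∪ enforced adjacency straight from a distance matrix.

    Equivalent to the edge set of :func:`datascape.graph.build_graph`
    without connecting edges, but skips per-edge bookkeeping — used inside
    k-sweeps where thousands of graphs are built.
    """
    natural = natural_neighbors(dist, k)
    n = dist.shape[0]
    rows, cols = [], []
    for i, neigh in enumerate(natural):
        rows.extend([i] * len(neigh))
        cols.extend(int(j) for j in neigh)
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    sym = a.maximum(a.T)  # symmetrization: union of directed k-NN relations
    return sym.multiply(dist).tocsr()


def mean_standardized_error(
    graph_dist: np.ndarray, true_dist: np.ndarray, max_dist: float = np.pi
) -> float:
    """Mean over unordered pairs of min(1, |d_G − d_true| / max_dist).

    Disconnected pairs (infinite d_G) are standardized to the maximal
    error 1.
    """
    n = graph_dist.shape[0]
    iu = np.triu_indices(n, k=1)
    g = graph_dist[iu]
    t = true_dist[iu]
    err = np.where(np.isfinite(g), np.minimum(np.abs(g - t) / max_dist, 1.0), 1.0)
    return float(err.mean())


def circle_error_experiment(
    n: int = 100, ks: Iterable[int] | None = None, seed: int = 0
) -> ErrorCurve:
    """Distance-error curve over k for one unit-circle sample.

    For each k, the symmetrized k-NN graph is built *without* connecting
    edges and all-pairs geodesics are compared with the true arc lengths.
    """
    data, theta = gen_circle(n, seed)
    true = arc_distances(theta)
    dist = pairwise_distances(data, EUCLIDEAN)
    if ks is None:
        ks = range(1, n)
    ks = tuple(int(k) for k in ks)
    errors = []
    for k in ks:
        adj = symmetric_knn_adjacency(dist, k)
        g = dijkstra(adj, directed=False)
        errors.append(mean_standardized_error(g, true))
    return ErrorCurve(ks, tuple(errors), n, seed)


# ---------------------------------------------------------------------------
# k-scan (component count and circuit rank per k)


@dataclass(frozen=True)
class KScanResult:
    """Per-k component count c(k) and circuit rank |E| − |V| + c."""

    ks: tuple[int, ...]
    components: tuple[int, ...]
    circuit_ranks: tuple[int, ...]

    def smallest_k_one_component(self) -> int | None:
        for k, c in zip(self.ks, self.components):
            if c == 1:
                return k
        return None

    def smallest_k_with_cycle(self) -> int | None:
        for k, r in zip(self.ks, self.circuit_ranks):
            if r >= 1:
                return k
        return None


def k_scan(
    data: Dataset, metric: Metric = EUCLIDEAN, ks: Iterable[int] | None = None
) -> KScanResult:
    """Scan k over raw (unconnected) graphs, tracking topology proxies.

    The component count proxies 0-dimensional features, the circuit rank
    proxies independent cycles; c(k) is non-increasing because the edge
    set grows with k.
    """
    dist = pairwise_distances(data, metric)
    n = data.n
    if ks is None:
        ks = range(1, n)
    ks = tuple(int(k) for k in ks)
    comps, ranks = [], []
    for k in ks:
        adj = symmetric_knn_adjacency(dist, k)
        c = int(_cc(adj, directed=False)[0])
        m = adj.nnz // 2
        comps.append(c)
        ranks.append(m - n + c)
    return KScanResult(ks, tuple(comps), tuple(ranks))


# ---------------------------------------------------------------------------
# labelled-cohort benchmark


def knn_vote_scores(
    train_pts: np.ndarray, train_labels: np.ndarray, test_pts: np.ndarray, k: int
) -> np.ndarray:
    """Reference classifier: positive fraction among the k nearest training points."""
    from scipy.spatial import cKDTree

    tree = cKDTree(train_pts)
    _, idx = tree.query(test_pts, k=min(k, len(train_pts)))
    idx = np.atleast_2d(idx)
    return train_labels[idx].mean(axis=1)


def cohort_benchmark(
    data: Dataset,
    k: int = 10,
    n_folds: int = 4,
    seed: int = 0,
    compare_knn: bool = False,
) -> dict:
    """Stratified n-fold AUC of the datascape risk score on held-out points.

    Per fold, the datascape is rebuilt on the training split only; each
    test point is inserted (k-NN insertion) and scored by the label ratio
    of its inserted neighbors.  With ``compare_knn`` a same-k
    nearest-neighbor-vote classifier is evaluated on the identical splits.
    """
    if data.labels is None:
        raise ValueError("cohort benchmark requires labels")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs, knn_aucs = [], []
    for train_ix, test_ix in skf.split(data.points, data.labels):
        train = Dataset(data.points[train_ix], labels=data.labels[train_ix])
        ds = build_datascape(train, k=k)
        scores = [
            predict_score(ds, None, q).score for q in data.points[test_ix]
        ]
        aucs.append(evaluate_auc(scores, data.labels[test_ix]))
        if compare_knn:
            ref = knn_vote_scores(
                train.points, np.asarray(train.labels, float), data.points[test_ix], k
            )
            knn_aucs.append(evaluate_auc(ref, data.labels[test_ix]))
    out = {"aucs": aucs, "mean_auc": float(np.mean(aucs))}
    if compare_knn:
        out["knn_aucs"] = knn_aucs
        out["knn_mean_auc"] = float(np.mean(knn_aucs))
    return out
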