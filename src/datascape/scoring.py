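"""In-shape sampling, neighborhood label-ratio risk scores, trajectories.

The risk score turns the datascape into an unsupervised classifier: a
point's score is the fraction of positively labelled points among its
graph neighbors (natural ∪ enforced; connecting neighbors are excluded
because they encode reachability, not similarity; the point itself is
excluded).  Out-of-sample points are scored after k-NN insertion.
Sampling draws convex combinations of each hull's vertices, so every
sample is guaranteed to lie inside the shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .core import Datascape
from .dataset import Dataset
from .geodesic import insert_point, insert_pair, geodesic_between_queries
from .hulls import LocalHull

__all__ = [
    "RiskScore",
    "Trajectory",
    "sample_in_hull",
    "sample_datascape",
    "label_ratio_scores",
    "predict_score",
    "evaluate_auc",
    "track_trajectory",
]


@dataclass(frozen=True)
class RiskScore:
    """Label ratio in a point's neighborhood, in [0, 1]."""

    point_id: object
    score: float
    neighborhood_size: int


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered states of one entity with per-state risk scores.

    ``geodesic_length`` is the shortest-path length between the first and
    last state after inserting both into the graph.
    """

    states: np.ndarray
    scores: tuple[RiskScore, ...]
    geodesic_length: float


def sample_in_hull(hull: LocalHull, m: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw m points inside a hull as flat-Dirichlet convex combinations.

    Weights are uniform on the vertex-weight simplex — rejection-free and
    dimension-independent, though not volume-uniform (samples concentrate
    toward vertex-dense regions).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    v = hull.vertices
    if m == 0:
        return np.empty((0, hull.d))
    if len(v) == 1:
        return np.repeat(v, m, axis=0)
    w = rng.dirichlet(np.ones(len(v)), size=m)
    return w @ v


def sample_datascape(
    ds: Datascape, per_hull: int, rng: np.random.Generator | int
) -> Dataset:
    """Exactly ``per_hull`` samples from each of the n local hulls.

    Every sample lies inside the shape by construction, so the generated
    cloud preserves the datascape's holes and cavities.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if per_hull == 0 or ds.n == 0:
        return Dataset(np.empty((0, ds.d)) if ds.n else np.empty((0, 1)))
    blocks = [sample_in_hull(ds.hull(i), per_hull, rng) for i in range(ds.n)]
    pts = np.vstack(blocks)
    ids = np.array(
        [f"{ds.data.ids[i]}#s{j}" for i in range(ds.n) for j in range(per_hull)],
        dtype=object,
    )
    return Dataset(pts, ids)


def _neighbor_label_ratio(ds: Datascape, labels: np.ndarray, i: int) -> RiskScore:
    neigh = ds.graph.neighbors(i, include_connecting=False)
    neigh = neigh[neigh != i]
    if len(neigh) == 0:
        return RiskScore(ds.data.ids[i], float("nan"), 0)
    return RiskScore(ds.data.ids[i], float(labels[neigh].mean()), int(len(neigh)))


def _resolve_labels(ds: Datascape, labels) -> np.ndarray:
    if labels is None:
        labels = ds.data.labels
    if labels is None:
        raise ValueError("labels are required for risk scoring")
    lab = np.asarray(labels, float)
    if lab.shape != (ds.n,):
        raise ValueError("labels must have one entry per dataset point")
    if np.isnan(lab).any():
        raise ValueError("missing labels are not allowed")
    return lab


def label_ratio_scores(ds: Datascape, labels: Sequence | None = None) -> list[RiskScore]:
    """Risk score for every dataset point: positive fraction of its neighbors."""
    lab = _resolve_labels(ds, labels)
    return [_neighbor_label_ratio(ds, lab, i) for i in range(ds.n)]


def predict_score(
    ds: Datascape, labels: Sequence | None, q: np.ndarray, tag: object = "query"
) -> RiskScore:
    """Risk score of an out-of-sample point via k-NN insertion."""
    lab = _resolve_labels(ds, labels)
    aug = insert_point(ds, q)
    neigh = [v for v, _ in aug.links[0]]
    return RiskScore(tag, float(lab[neigh].mean()), len(neigh))


def evaluate_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve of scores against binary labels (midrank ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs at least one positive and one negative label")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def track_trajectory(
    ds: Datascape, labels: Sequence | None, states: Sequence[np.ndarray]
) -> Trajectory:
    """Score each state of a trajectory and measure its endpoint geodesic.

    Per-state scores use k-NN insertion; the geodesic runs between the
    first and last state on the graph augmented with both of them.
    """
    states = np.atleast_2d(np.asarray(states, float))
    if states.shape[0] < 2:
        raise ValueError("a trajectory needs at least 2 states")
    scores = tuple(
        predict_score(ds, labels, s, tag=f"t{t}") for t, s in enumerate(states)
    )
    aug = insert_pair(ds, states[0], states[-1])
    length = geodesic_between_queries(aug)
    return Trajectory(states, scores, length)
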