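"""Local (neighborhood) convex hulls and point-membership tests.

Each point's neighborhood — the point itself plus its natural and enforced
graph neighbors, never the connecting neighbors — is summarized by its
convex hull.  The union of these hulls is the estimated support ("shape")
of the data; unlike a single global convex hull it preserves holes and
cavities.

Three hull representations are used, chosen automatically:

``facets``
    Full-dimensional neighborhoods in moderate dimension: quickhull
    (scipy ``ConvexHull``) facet half-spaces; membership is a vectorized
    half-space check.
``affine``
    Degenerate neighborhoods spanning an affine subspace of dimension
    < d: membership requires lying on the subspace (within tolerance) and
    inside the sub-dimensional hull, computed recursively after an
    orthonormal projection.  Rank-0 and rank-1 cases (single point,
    segment) are handled directly.
``lp``
    High-dimensional full-rank neighborhoods where facet enumeration
    explodes combinatorially: vertices are identified per point by a
    linear-program test and membership is an LP feasibility problem on the
    convex-combination system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

__all__ = ["LocalHull", "build_hull_from_points", "point_in_hull", "FACET_DIM_LIMIT"]

#: above this dimension facet enumeration is abandoned for LP membership
FACET_DIM_LIMIT = 8

#: relative boundary tolerance: eps = RELATIVE_EPS * hull diameter
RELATIVE_EPS = 1e-9


def _convex_combination_feasible(
    vertices: np.ndarray, q: np.ndarray, tol: float = 1e-9
) -> bool:
    """LP feasibility: is q = sum λ_i v_i with λ ≥ 0, sum λ = 1?"""
    m, d = vertices.shape
    if m == 1:
        return bool(np.linalg.norm(q - vertices[0]) <= max(tol, 1e-12))
    A_eq = np.vstack([vertices.T, np.ones(m)])
    b_eq = np.concatenate([q, [1.0]])
    res = linprog(
        np.zeros(m), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * m, method="highs"
    )
    return bool(res.status == 0)


def _lp_vertex_mask(points: np.ndarray, tol: float) -> np.ndarray:
    """True where a point is NOT a convex combination of the others."""
    m = points.shape[0]
    mask = np.zeros(m, dtype=bool)
    for i in range(m):
        others = np.delete(points, i, axis=0)
        mask[i] = not _convex_combination_feasible(others, points[i], tol)
    return mask


@dataclass
class LocalHull:
    """Convex hull of one point's graph neighborhood.

    Attributes
    ----------
    center_idx
        Row index of the neighborhood's center point.
    input_indices
        Row indices of the points the hull was built from
        ({center} ∪ N(center)).
    vertex_indices
        Subset of ``input_indices`` that are hull vertices (extreme points
        of the local hull).
    mode
        ``facets`` | ``affine`` | ``lp`` (see module docstring).
    equations
        Facet half-spaces ``[normal | offset]`` with inside meaning
        ``normal·x + offset <= 0`` (facet mode, and affine mode's sub-hull).
    origin, basis
        Affine frame of the degenerate subspace (affine mode): a point on
        the subspace and an orthonormal ``d x r`` basis.
    degenerate
        True when the neighborhood spans an affine subspace of dimension
        < d; membership then means lying *on* that lower-dimensional piece.
    """

    center_idx: int
    input_indices: np.ndarray
    vertex_indices: np.ndarray
    vertices: np.ndarray
    d: int
    mode: str
    eps: float
    diameter: float
    degenerate: bool
    equations: np.ndarray | None = None
    origin: np.ndarray | None = None
    basis: np.ndarray | None = None
    #: sub-dimensional interval (rank 1) or facet equations (rank >= 2)
    sub_equations: np.ndarray | None = None
    sub_interval: tuple[float, float] | None = None
    sub_rank: int = 0

    # -- membership ---------------------------------------------------------

    def contains_many(self, queries: np.ndarray, eps: float | None = None) -> np.ndarray:
        """Vectorized membership for a ``m x d`` query block."""
        q = np.atleast_2d(np.asarray(queries, float))
        if q.shape[1] != self.d:
            raise ValueError(f"dimension mismatch: hull d={self.d}, query d={q.shape[1]}")
        tol = self.eps if eps is None else eps
        if self.mode == "facets":
            vals = q @ self.equations[:, :-1].T + self.equations[:, -1]
            return (vals <= tol).all(axis=1)
        if self.mode == "lp":
            return np.array(
                [_convex_combination_feasible(self.vertices, row, tol) for row in q]
            )
        # affine mode
        rel = q - self.origin
        if self.sub_rank == 0:
            return np.linalg.norm(rel, axis=1) <= max(tol, 1e-12)
        proj = rel @ self.basis  # m x r coordinates in the subspace
        resid = np.linalg.norm(rel - proj @ self.basis.T, axis=1)
        on_plane = resid <= max(tol, 1e-12)
        if self.sub_rank == 1:
            lo, hi = self.sub_interval
            t = proj[:, 0]
            inside = (t >= lo - tol) & (t <= hi + tol)
        else:
            vals = proj @ self.sub_equations[:, :-1].T + self.sub_equations[:, -1]
            inside = (vals <= tol).all(axis=1)
        return on_plane & inside

    def contains(self, q: np.ndarray, eps: float | None = None) -> bool:
        return bool(self.contains_many(np.asarray(q, float)[None, :], eps)[0])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


def point_in_hull(hull: LocalHull, q: np.ndarray, eps: float | None = None) -> bool:
    """True when q lies in the hull within tolerance (boundary counts as inside)."""
    return hull.contains(q, eps)


def _affine_rank(centered: np.ndarray, scale: float) -> tuple[int, np.ndarray]:
    """Numerical affine rank and right singular vectors of centered points."""
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if scale <= 0:
        return 0, vt
    rank = int((s > max(s[0] if len(s) else 0.0, scale) * 1e-9).sum()) if len(s) else 0
    return rank, vt


def build_hull_from_points(
    coords: np.ndarray,
    input_indices: Sequence[int],
    center_idx: int,
    eps: float | None = None,
) -> LocalHull:
    """Build a :class:`LocalHull` over explicit coordinates.

    ``coords`` rows correspond to ``input_indices``; degeneracy (affine
    rank < d) is detected via SVD and routed to the affine representation.
    """
    coords = np.asarray(coords, float)
    idx = np.asarray(list(input_indices), dtype=int)
    d = coords.shape[1]
    # deduplicate exact coordinate repeats (keep first occurrence)
    _, first = np.unique(coords, axis=0, return_index=True)
    uniq = np.sort(first)
    ucoords = coords[uniq]
    uidx = idx[uniq]

    mean = ucoords.mean(axis=0)
    centered = ucoords - mean
    diam = 0.0
    if len(ucoords) > 1:
        lo, hi = ucoords.min(axis=0), ucoords.max(axis=0)
        diam = float(np.linalg.norm(hi - lo))
    tol = eps if eps is not None else max(RELATIVE_EPS * diam, 1e-12)

    rank, vt = _affine_rank(centered, diam)

    if len(ucoords) == 1 or rank == 0:
        return LocalHull(
            center_idx=center_idx,
            input_indices=idx,
            vertex_indices=uidx[:1],
            vertices=ucoords[:1],
            d=d,
            mode="affine",
            eps=tol,
            diameter=diam,
            degenerate=True,
            origin=ucoords[0].copy(),
            sub_rank=0,
        )

    if rank == d == 1:
        # 1-d ambient space: the hull is an interval; qhull needs d >= 2
        t = ucoords[:, 0]
        lo_i, hi_i = int(np.argmin(t)), int(np.argmax(t))
        vsel = np.unique([lo_i, hi_i])
        return LocalHull(
            center_idx=center_idx,
            input_indices=idx,
            vertex_indices=uidx[vsel],
            vertices=ucoords[vsel],
            d=1,
            mode="facets",
            eps=tol,
            diameter=diam,
            degenerate=False,
            equations=np.array([[1.0, -float(t[hi_i])], [-1.0, float(t[lo_i])]]),
        )

    if rank == d and d <= FACET_DIM_LIMIT:
        try:
            ch = ConvexHull(ucoords)
        except QhullError:
            ch = None
        if ch is not None:
            vmask = np.zeros(len(ucoords), dtype=bool)
            vmask[ch.vertices] = True
            return LocalHull(
                center_idx=center_idx,
                input_indices=idx,
                vertex_indices=uidx[vmask],
                vertices=ucoords[vmask],
                d=d,
                mode="facets",
                eps=tol,
                diameter=diam,
                degenerate=False,
                equations=ch.equations.copy(),
            )
        rank = min(rank, d - 1)  # qhull rejected: treat as numerically degenerate

    if rank == d:  # high-dimensional full-rank neighborhood: LP route
        vmask = _lp_vertex_mask(ucoords, tol)
        return LocalHull(
            center_idx=center_idx,
            input_indices=idx,
            vertex_indices=uidx[vmask],
            vertices=ucoords[vmask],
            d=d,
            mode="lp",
            eps=tol,
            diameter=diam,
            degenerate=False,
        )

    # degenerate: project onto the affine subspace and recurse in rank dims
    basis = vt[:rank].T  # d x r orthonormal
    proj = centered @ basis
    if rank == 1:
        t = proj[:, 0]
        order = np.argsort(t)
        lo_i, hi_i = order[0], order[-1]
        vsel = np.unique([lo_i, hi_i])
        return LocalHull(
            center_idx=center_idx,
            input_indices=idx,
            vertex_indices=uidx[vsel],
            vertices=ucoords[vsel],
            d=d,
            mode="affine",
            eps=tol,
            diameter=diam,
            degenerate=True,
            origin=mean,
            basis=basis,
            sub_interval=(float(t[lo_i]), float(t[hi_i])),
            sub_rank=1,
        )
    try:
        ch = ConvexHull(proj)
        vmask = np.zeros(len(ucoords), dtype=bool)
        vmask[ch.vertices] = True
        sub_eq = ch.equations.copy()
    except QhullError:
        vmask = _lp_vertex_mask(proj, tol)
        sub_eq = None
    if sub_eq is None:
        # fall back to an LP hull expressed in subspace coordinates
        hull = LocalHull(
            center_idx=center_idx,
            input_indices=idx,
            vertex_indices=uidx[vmask],
            vertices=ucoords[vmask],
            d=d,
            mode="lp",
            eps=tol,
            diameter=diam,
            degenerate=True,
        )
        return hull
    return LocalHull(
        center_idx=center_idx,
        input_indices=idx,
        vertex_indices=uidx[vmask],
        vertices=ucoords[vmask],
        d=d,
        mode="affine",
        eps=tol,
        diameter=diam,
        degenerate=True,
        origin=mean,
        basis=basis,
        sub_equations=sub_eq,
        sub_rank=rank,
    )
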