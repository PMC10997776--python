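"""Synthetic datasets: noisy sinusoid, torus, unit circle, annulus, cohort.

Every generator is seed-deterministic and returns the latent ground truth
its experiment needs (pre-noise coordinates for the sinusoid, angles for
the circle, class labels for the cohort) alongside the :class:`Dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset

__all__ = [
    "gen_sinusoid",
    "gen_torus",
    "gen_circle",
    "gen_annulus",
    "gen_cohort",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_sinusoid(n: int = 1000, seed=0) -> tuple[Dataset, dict]:
    """Noisy 3-d sinusoidal ribbon.

    ``x ~ U(0, 2π), y = cos(x), z = cos(x − 0.5)`` with uniform noise
    ``ε_x ~ U(−1, 1)`` and ``ε_y, ε_z ~ U(−0.3, 0.3)`` added per
    coordinate.  Returns the dataset and the latent pre-noise values.
    """
    rng = _rng(seed)
    x = rng.uniform(0.0, 2.0 * np.pi, n)
    y = np.cos(x)
    z = np.cos(x - 0.5)
    ex = rng.uniform(-1.0, 1.0, n)
    ey = rng.uniform(-0.3, 0.3, n)
    ez = rng.uniform(-0.3, 0.3, n)
    pts = np.column_stack([x + ex, y + ey, z + ez])
    latent = {"x": x, "y": y, "z": z, "eps": np.column_stack([ex, ey, ez])}
    return Dataset(pts), latent


def gen_torus(
    n: int = 1000, R: float = 2.0, r: float = 1.0, seed=0
) -> tuple[Dataset, dict]:
    """Points on a torus surface, uniform in the (u, v) angle parameters.

    ``((R + r cos v) cos u, (R + r cos v) sin u, r sin v)`` with
    ``u, v ~ U(0, 2π)``.  Note (u, v)-uniform sampling slightly
    over-weights the inner rim relative to surface-area-uniform sampling.
    """
    if not (R > r > 0):
        raise ValueError("torus radii must satisfy R > r > 0")
    rng = _rng(seed)
    u = rng.uniform(0.0, 2.0 * np.pi, n)
    v = rng.uniform(0.0, 2.0 * np.pi, n)
    pts = np.column_stack(
        [(R + r * np.cos(v)) * np.cos(u), (R + r * np.cos(v)) * np.sin(u), r * np.sin(v)]
    )
    return Dataset(pts), {"u": u, "v": v, "R": R, "r": r}


def gen_circle(n: int = 100, seed=0) -> tuple[Dataset, np.ndarray]:
    """n points on the unit circle with latent angles θ ~ U(0, 2π)."""
    if n < 2:
        raise ValueError("need at least 2 points on the circle")
    rng = _rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    return Dataset(pts), theta


def arc_distances(theta: np.ndarray) -> np.ndarray:
    """Pairwise ground-truth arc lengths on the unit circle (max π)."""
    diff = np.abs(theta[:, None] - theta[None, :])
    return np.minimum(diff, 2.0 * np.pi - diff)


def gen_annulus(
    n: int = 200, r_inner: float = 1.0, r_outer: float = 1.5, seed=0
) -> tuple[Dataset, dict]:
    """2-d annulus: radius ~ U(r_inner, r_outer), angle ~ U(0, 2π).

    The central cavity is the canonical example of a topological feature
    that the union of local hulls preserves but a global convex hull
    destroys.
    """
    if not (0 < r_inner < r_outer):
        raise ValueError("need 0 < r_inner < r_outer")
    rng = _rng(seed)
    rad = rng.uniform(r_inner, r_outer, n)
    ang = rng.uniform(0.0, 2.0 * np.pi, n)
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return Dataset(pts), {"radius": rad, "angle": ang}


def gen_cohort(
    n: int = 2000,
    separation: float = 2.0,
    d: int = 5,
    label_noise: float = 0.0,
    seed=0,
) -> Dataset:
    """Two-class Gaussian cohort standing in for a labelled clinical dataset.

    Two unit-variance point clouds in d dimensions whose class means are
    ``separation`` apart along the first axis; labels (0 = control,
    1 = case) are flipped independently at rate ``label_noise``.  At
    separation 0 the classes are statistically indistinguishable.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = _rng(seed)
    n1 = n // 2
    n0 = n - n1
    mean0 = np.zeros(d)
    mean1 = np.zeros(d)
    mean0[0] = -separation / 2.0
    mean1[0] = +separation / 2.0
    pts = np.vstack(
        [rng.normal(mean0, 1.0, (n0, d)), rng.normal(mean1, 1.0, (n1, d))]
    )
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    flip = rng.random(n) < label_noise
    labels = np.where(flip, 1 - labels, labels)
    perm = rng.permutation(n)
    return Dataset(pts[perm], labels=labels[perm])
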