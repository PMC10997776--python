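import numpy as np
import pytest

from datascape import Dataset, build_datascape


@pytest.fixture
def square_corners() -> Dataset:
    """The 4 corners of the unit square."""
    return Dataset(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def square_plus_center() -> Dataset:
    """Unit-square corners plus the center point (id 4)."""
    return Dataset(
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.5, 0.5]])
    )


@pytest.fixture(scope="session")
def sinusoid_datascape():
    """Shared 1000-point noisy-sinusoid datascape at k=10."""
    from datascape import gen_sinusoid

    data, latent = gen_sinusoid(1000, seed=7)
    ds = build_datascape(data, k=10)
    return ds, latent


def brute_force_pairwise(points: np.ndarray, metric) -> np.ndarray:
    """Independent double-loop distance matrix oracle."""
    n = len(points)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = metric(points[i], points[j])
    return out


def lp_in_hull(vertices: np.ndarray, q: np.ndarray) -> bool:
    """Independent LP-feasibility oracle for convex-combination membership."""
    from scipy.optimize import linprog

    m = vertices.shape[0]
    res = linprog(
        np.zeros(m),
        A_eq=np.vstack([vertices.T, np.ones(m)]),
        b_eq=np.concatenate([q, [1.0]]),
        bounds=[(0, None)] * m,
        method="highs",
    )
    return res.status == 0


def floyd_warshall_oracle(weights: np.ndarray) -> np.ndarray:
    """Textbook all-pairs dynamic-programming shortest paths.

    ``weights`` is dense with np.inf for missing edges and 0 diagonal.
    """
    d = weights.copy()
    n = d.shape[0]
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d
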