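"""Neighbor-graph construction: k-NN, symmetrization, connecting edges."""

import itertools

import numpy as np
import pytest

from datascape import (
    Dataset,
    EUCLIDEAN,
    build_graph,
    get_metric,
    natural_neighbors,
    pairwise_distances,
    symmetrize,
)
from datascape.graph import connect_components, connected_components

from conftest import brute_force_pairwise


class TestPairwiseDistances:
    def test_two_points_on_a_line(self):
        d = pairwise_distances(Dataset([[0.0], [3.0]]))
        np.testing.assert_allclose(d, [[0, 3], [3, 0]])

    def test_single_point(self):
        np.testing.assert_allclose(pairwise_distances(Dataset([[5.0]])), [[0.0]])

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "chebyshev"])
    def test_matches_double_loop_oracle(self, metric):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3))
        m = get_metric(metric)
        got = pairwise_distances(Dataset(pts), m)
        np.testing.assert_allclose(got, brute_force_pairwise(pts, m), atol=1e-12)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            Dataset([[0.0, np.nan]])


class TestNaturalNeighbors:
    def test_line_k1(self):
        dist = pairwise_distances(Dataset([[0.0], [1.0], [3.0]]))
        nn = natural_neighbors(dist, 1)
        assert [a.tolist() for a in nn] == [[1], [0], [1]]

    def test_complete_at_k_equals_n_minus_1(self):
        rng = np.random.default_rng(2)
        dist = pairwise_distances(Dataset(rng.normal(size=(6, 2))))
        nn = natural_neighbors(dist, 5)
        for i, a in enumerate(nn):
            assert sorted(a.tolist()) == [j for j in range(6) if j != i]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        dist = pairwise_distances(Dataset(rng.normal(size=(20, 3))))
        nn = natural_neighbors(dist, 4)
        for i in range(20):
            order = sorted(
                (j for j in range(20) if j != i), key=lambda j: (dist[i, j], j)
            )
            assert nn[i].tolist() == order[:4]

    def test_k_clamped_with_warning(self):
        dist = pairwise_distances(Dataset([[0.0], [1.0], [2.0]]))
        with pytest.warns(UserWarning, match="clamping"):
            nn = natural_neighbors(dist, 10)
        assert all(len(a) == 2 for a in nn)

    def test_ties_broken_by_ascending_index(self):
        # points 1 and 2 equidistant from point 0
        dist = pairwise_distances(Dataset([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]]))
        nn = natural_neighbors(dist, 1)
        assert nn[0].tolist() == [1]


class TestSymmetrize:
    def test_line_enforced_neighbor(self):
        dist = pairwise_distances(Dataset([[0.0], [1.0], [3.0]]))
        nat = natural_neighbors(dist, 1)
        enf = symmetrize(nat)
        # c's natural neighbor is b, but b's is a: c becomes enforced for b
        assert enf[1].tolist() == [2]
        assert enf[0].tolist() == [] and enf[2].tolist() == []

    def test_symmetric_input_is_fixed_point(self):
        dist = pairwise_distances(Dataset([[0.0], [1.0]]))
        enf = symmetrize(natural_neighbors(dist, 1))
        assert all(len(e) == 0 for e in enf)

    def test_symmetry_invariant_random(self):
        rng = np.random.default_rng(4)
        dist = pairwise_distances(Dataset(rng.normal(size=(30, 2))))
        nat = natural_neighbors(dist, 3)
        enf = symmetrize(nat)
        combined = [set(n.tolist()) | set(e.tolist()) for n, e in zip(nat, enf)]
        for i in range(30):
            for j in combined[i]:
                assert i in combined[j]


class TestConnectedComponents:
    def test_two_far_pairs(self):
        data = Dataset([[0.0], [1.0], [100.0], [101.0]])
        g = build_graph(data, k=1, connect=False)
        assert g.num_components() == 2

    def test_complete_graph_one_component(self):
        rng = np.random.default_rng(5)
        g = build_graph(Dataset(rng.normal(size=(8, 2))), k=7, connect=False)
        assert g.num_components() == 1

    def test_agrees_with_transitive_closure_oracle(self):
        rng = np.random.default_rng(6)
        n = 15
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.08]
        labels = connected_components(n, edges)
        # boolean matrix-power closure oracle
        adj = np.eye(n, dtype=bool)
        for i, j in edges:
            adj[i, j] = adj[j, i] = True
        reach = adj.copy()
        for _ in range(n):
            reach = reach | (reach @ adj)
        for i in range(n):
            for j in range(n):
                assert (labels[i] == labels[j]) == reach[i, j]


class TestConnectComponents:
    def test_single_component_empty(self):
        data = Dataset([[0.0], [1.0]])
        labels = np.zeros(2, int)
        assert connect_components(data, EUCLIDEAN, labels) == []

    def test_three_collinear_clusters_bridge_adjacent(self):
        pts = np.array([[0.0], [0.5], [10.0], [10.5], [25.0], [25.5]])
        data = Dataset(pts)
        g = build_graph(data, k=1, connect=True)
        conn = [(i, j) for (i, j), (_, p) in g.edges.items() if p == "connecting"]
        total = sum(w for (w, p) in g.edges.values() if p == "connecting")
        assert sorted(conn) == [(1, 2), (3, 4)]
        assert total == pytest.approx((10.0 - 0.5) + (25.0 - 10.5))

    def test_minimal_total_weight_vs_bruteforce(self):
        rng = np.random.default_rng(7)
        centers = rng.uniform(-50, 50, size=(5, 2))
        pts = np.vstack([c + 0.1 * rng.normal(size=(4, 2)) for c in centers])
        data = Dataset(pts)
        dist = pairwise_distances(data)
        labels = np.repeat(np.arange(5), 4)
        chosen = connect_components(data, EUCLIDEAN, labels, dist)
        got = sum(w for _, _, w in chosen)

        # oracle: enumerate all spanning subsets of the candidate meta-edges
        minima = {}
        for a, b in itertools.combinations(range(5), 2):
            ia, ib = np.where(labels == a)[0], np.where(labels == b)[0]
            minima[(a, b)] = dist[np.ix_(ia, ib)].min()
        best = np.inf
        cand = list(minima.items())
        for subset in itertools.chain.from_iterable(
            itertools.combinations(cand, r) for r in range(4, len(cand) + 1)
        ):
            adj = np.eye(5, dtype=bool)
            for (a, b), _ in subset:
                adj[a, b] = adj[b, a] = True
            reach = adj.copy()
            for _ in range(5):
                reach = reach | (reach @ adj)
            if reach.all():
                best = min(best, sum(w for _, w in subset))
        assert got == pytest.approx(best)


class TestBuildGraph:
    def test_unit_square_k1(self, square_corners):
        g = build_graph(square_corners, k=1)
        weights = sorted(w for (w, _) in g.edges.values())
        # each corner's nearest neighbor is a side-adjacent corner (tie-break
        # by index); symmetrization and connecting keep the graph connected
        assert all(w == pytest.approx(1.0) for w in weights)
        assert g.num_components(use_connecting=True) == 1

    def test_single_point(self):
        g = build_graph(Dataset([[1.0, 2.0]]), k=3)
        assert g.n == 1 and len(g.edges) == 0

    def test_weights_equal_ambient_distance(self):
        rng = np.random.default_rng(8)
        data = Dataset(rng.normal(size=(25, 3)))
        g = build_graph(data, k=4)
        for (i, j), (w, _) in g.edges.items():
            assert w == pytest.approx(np.linalg.norm(data.points[i] - data.points[j]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_edge_monotonicity_in_k(self, seed):
        rng = np.random.default_rng(seed)
        data = Dataset(rng.normal(size=(30, 2)))
        for k in range(1, 6):
            e_k = set(build_graph(data, k, connect=False).edges)
            e_k1 = set(build_graph(data, k + 1, connect=False).edges)
            assert e_k <= e_k1

    def test_complete_at_k_n_minus_1(self):
        rng = np.random.default_rng(9)
        data = Dataset(rng.normal(size=(10, 2)))
        g = build_graph(data, k=9)
        assert len(g.edges) == 45

    def test_connecting_edges_only_when_disconnected(self):
        near = Dataset(np.random.default_rng(10).normal(size=(10, 2)))
        g = build_graph(near, k=9)
        assert all(p != "connecting" for _, p in g.edges.values())
        far = Dataset(np.vstack([np.zeros((3, 2)) + [[0, 0], [0, 1], [1, 0]],
                                 100 + np.array([[0, 0], [0, 1], [1, 0]])]))
        g2 = build_graph(far, k=1)
        assert any(p == "connecting" for _, p in g2.edges.values())
        assert g2.num_components(use_connecting=True) == 1

    def test_duplicate_points_become_mutual_neighbors(self):
        data = Dataset([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        g = build_graph(data, k=1)
        assert (0, 1) in g.edges
        w, prov = g.edges[(0, 1)]
        assert w == 0.0 and prov == "natural"

    def test_circle_topology_typicality(self):
        """Over 20 seeds of 100 circle points: median k for one component
        <= 6 and median k for a first cycle <= 8."""
        from datascape import gen_circle, k_scan

        k_conn, k_cyc = [], []
        for seed in range(20):
            data, _ = gen_circle(100, seed=seed)
            res = k_scan(data, ks=range(1, 15))
            kc = res.smallest_k_one_component()
            k_conn.append(kc if kc is not None else 15)
            kcy = None
            for k, c, r in zip(res.ks, res.components, res.circuit_ranks):
                if c == 1 and r >= 1:
                    kcy = k
                    break
            k_cyc.append(kcy if kcy is not None else 15)
        assert np.median(k_conn) <= 6
        assert np.median(k_cyc) <= 8

    def test_large_n_tree_path_matches_dense(self):
        rng = np.random.default_rng(11)
        data = Dataset(rng.normal(size=(60, 2)))
        dense = build_graph(data, k=4, dense_limit=8192)
        sparse = build_graph(data, k=4, dense_limit=10)
        assert set(dense.edges) == set(sparse.edges)
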