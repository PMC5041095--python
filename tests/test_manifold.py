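"""kNN manifold, geodesics and template selection vs brute-force oracles."""

import numpy as np
import pytest

from geodereg.manifold import (
    build_graph,
    geodesics,
    min_connecting_k,
    pairwise_rc,
    select_template,
)
from geodereg.similarity import rc_similarity
from oracles import all_pairs_bruteforce, min_connecting_k_bruteforce

N_ORACLE_SEEDS = 20


def random_dist(rng, n):
    d = rng.random((n, n)) * 10
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestPairwiseRC:
    def test_identical_frames_all_zero(self):
        frames = np.ones((4, 8, 8))
        np.testing.assert_array_equal(pairwise_rc(frames), np.zeros((4, 4)))

    def test_duplicate_frame_consistency(self, rng):
        f0 = rng.random((8, 8))
        f1 = rng.random((8, 8))
        d = pairwise_rc(np.stack([f0, f1, f0]))
        assert d[0, 2] == 0.0
        assert d[0, 1] == pytest.approx(d[2, 1], rel=1e-12)

    def test_matches_elementwise_recomputation(self, rng):
        frames = rng.random((5, 8, 8))
        d = pairwise_rc(frames)
        assert d.shape == (5, 5)
        assert np.allclose(d, d.T) and not d.diagonal().any()
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert d[i, j] == pytest.approx(
                        rc_similarity(frames[i], frames[j]), rel=1e-12
                    )


class TestMinConnectingK:
    def test_chain_connects_at_one(self):
        # 3 collinear points, consecutive distances 1
        d = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        assert min_connecting_k(d) == 1

    def test_two_far_clusters_need_bridge(self):
        n = 6
        d = np.full((n, n), 100.0)
        for c in ([0, 1, 2], [3, 4, 5]):
            for i in c:
                for j in c:
                    d[i, j] = 0 if i == j else 1.0
        d += np.arange(n)[None, :] * 1e-3  # break ties deterministically
        d = np.maximum(d, d.T)
        np.fill_diagonal(d, 0)
        assert min_connecting_k(d) == min_connecting_k_bruteforce(d)
        assert min_connecting_k(d) >= 3

    def test_all_ties_connect_at_one(self):
        d = np.ones((5, 5)) - np.eye(5)
        assert min_connecting_k(d) == 1

    @pytest.mark.parametrize("seed", range(N_ORACLE_SEEDS))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dist(rng, int(rng.integers(4, 9)))
        assert min_connecting_k(d) == min_connecting_k_bruteforce(d)

    def test_tiny_matrix_rejected(self):
        with pytest.raises(ValueError):
            min_connecting_k(np.zeros((1, 1)))


class TestBuildGraph:
    def test_chain_distances_give_chain_edges(self):
        d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        g = build_graph(d, 1)
        assert set(g.edges) == {(0, 1), (1, 2), (2, 3)}

    def test_complete_graph_at_k_max(self):
        rng = np.random.default_rng(0)
        d = random_dist(rng, 5)
        g = build_graph(d, 4)
        assert len(g.edges) == 10

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            build_graph(np.zeros((4, 4)), 4)

    @pytest.mark.parametrize("seed", range(5))
    def test_union_symmetrized_edges_match_bruteforce(self, seed):
        from oracles import knn_edges_bruteforce

        rng = np.random.default_rng(seed)
        d = random_dist(rng, 7)
        g = build_graph(d, 2)
        assert set(g.edges) == knn_edges_bruteforce(d, 2)


class TestGeodesics:
    def test_triangle_detour(self):
        d = np.array([[0.0, 1, 3], [1, 0, 1], [3, 1, 0]])
        g = geodesics(build_graph(d, 2))
        assert g.dist[0, 2] == pytest.approx(2.0)
        assert g.paths[(0, 2)] == [0, 1, 2]

    def test_adjacent_nodes_have_two_node_path(self):
        d = np.array([[0.0, 1, 3], [1, 0, 1], [3, 1, 0]])
        g = geodesics(build_graph(d, 2))
        assert g.paths[(0, 1)] == [0, 1]

    def test_reverse_paths(self):
        rng = np.random.default_rng(3)
        d = random_dist(rng, 8)
        g = geodesics(build_graph(d, 3))
        for (i, j), p in g.paths.items():
            assert p[0] == i and p[-1] == j
            assert g.paths[(j, i)] == p[::-1]

    @pytest.mark.parametrize("seed", range(N_ORACLE_SEEDS))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        d = random_dist(rng, n)
        k = min_connecting_k(d)
        g = geodesics(build_graph(d, k))
        ref_dist, ref_paths = all_pairs_bruteforce(g.edges, n)
        np.testing.assert_allclose(g.dist, ref_dist, rtol=1e-12)
        for i in range(n):
            for j in range(i + 1, n):
                assert g.paths[(i, j)] == ref_paths[(i, j)]

    def test_path_lengths_sum_to_distance(self):
        rng = np.random.default_rng(5)
        d = random_dist(rng, 8)
        g = geodesics(build_graph(d, 2))
        edge_w = dict(g.edges)
        for (i, j), p in g.paths.items():
            if i == j:
                continue
            total = sum(edge_w[(min(a, b), max(a, b))] for a, b in zip(p, p[1:]))
            assert total == pytest.approx(g.dist[i, j], rel=1e-12)


class TestTemplate:
    def test_chain_center(self):
        d = np.abs(np.subtract.outer(np.arange(3.0), np.arange(3.0)))
        g = geodesics(build_graph(d, 1))
        assert select_template(g) == 1

    def test_star_hub(self):
        # node 0 close to everyone, others far apart
        n = 5
        d = np.full((n, n), 10.0)
        d[0, :] = d[:, 0] = 1.0
        np.fill_diagonal(d, 0)
        g = geodesics(build_graph(d, 1))
        assert select_template(g) == 0

    @pytest.mark.parametrize("seed", range(N_ORACLE_SEEDS))
    def test_matches_bruteforce_argmin(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dist(rng, 10)
        k = min_connecting_k(d)
        g = geodesics(build_graph(d, k))
        t = select_template(g)
        ref_dist, _ = all_pairs_bruteforce(g.edges, 10)
        assert t == int(np.argmin(ref_dist.sum(axis=1)))
        assert g.dist.sum(axis=1)[t] == min(g.dist.sum(axis=1))
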