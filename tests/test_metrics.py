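import numpy as np
import pytest

from swprop import (
    CLUSTERING_VARIANTS,
    DegenerateNetworkError,
    char_path_length,
    clustering_coefficient,
    generate_ring_lattice,
    local_clustering,
    make_network,
    shortest_path_matrix,
)

from _oracles import (
    brute_char_path_length,
    brute_local_clustering,
    random_symmetric_weights,
)


class TestLocalClustering:
    @pytest.mark.parametrize("variant", CLUSTERING_VARIANTS)
    def test_complete_triangle_is_one(self, triangle, variant):
        np.testing.assert_allclose(local_clustering(triangle, variant), 1.0)

    @pytest.mark.parametrize("variant", CLUSTERING_VARIANTS)
    def test_star_has_no_triangles(self, star4, variant):
        np.testing.assert_array_equal(local_clustering(star4, variant), 0.0)

    def test_onnela_weighted_triangle(self):
        # weights (1, 1, 1/8): each node's neighbour-pair term is
        # (1 * 1 * 1/8)^(1/3) = 1/2, counted twice over ordered pairs,
        # divided by k(k-1) = 2
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[1, 2] = m[2, 1] = 1.0
        m[0, 2] = m[2, 0] = 1.0 / 8.0
        net = make_network(m)
        np.testing.assert_allclose(local_clustering(net, "onnela"), 0.5)

    def test_unknown_variant_rejected(self, triangle):
        with pytest.raises(ValueError):
            local_clustering(triangle, "nonsense")

    @pytest.mark.parametrize("variant", ["onnela", "barrat", "zhang"])
    @pytest.mark.parametrize("seed", range(3))
    def test_weighted_variants_reduce_to_binary(self, variant, seed):
        rng = np.random.default_rng(seed)
        w = random_symmetric_weights(9, 0.5, rng, binary=True)
        net = make_network(w)
        np.testing.assert_allclose(
            local_clustering(net, variant), local_clustering(net, "binary"),
            atol=1e-12,
        )

    @pytest.mark.parametrize("variant", CLUSTERING_VARIANTS)
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, variant, seed):
        rng = np.random.default_rng(100 + seed)
        w = random_symmetric_weights(8, 0.6, rng)
        net = make_network(w)
        np.testing.assert_allclose(
            local_clustering(net, variant),
            brute_local_clustering(w, variant),
            atol=1e-12,
        )

    @pytest.mark.parametrize("variant", ["binary", "onnela", "barrat"])
    def test_values_in_unit_interval(self, variant, rng):
        w = random_symmetric_weights(10, 0.7, rng)
        c = local_clustering(make_network(w), variant)
        assert np.all(c >= 0) and np.all(c <= 1 + 1e-12)

    @pytest.mark.parametrize("variant", ["onnela", "zhang"])
    def test_weight_scale_invariance(self, variant, rng):
        w = random_symmetric_weights(8, 0.6, rng)
        net, scaled = make_network(w), make_network(7.3 * w)
        np.testing.assert_allclose(
            local_clustering(net, variant), local_clustering(scaled, variant),
            atol=1e-12,
        )


class TestClusteringCoefficient:
    def test_ring_lattice_closed_form(self):
        # k-nearest-neighbour ring: C = 3(r-1) / (2(2r-1))
        net = generate_ring_lattice(1000, 5)
        assert clustering_coefficient(net, "binary") == pytest.approx(2.0 / 3.0)

    def test_isolated_nodes_count_as_zero(self):
        m = np.zeros((5, 5))
        m[:3, :3] = 1.0
        np.fill_diagonal(m, 0.0)
        net = make_network(m)
        assert clustering_coefficient(net, "binary") == pytest.approx(3.0 / 5.0)


class TestShortestPaths:
    def test_single_edge_cost_is_reciprocal_weight(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 2.0
        d = shortest_path_matrix(make_network(m), weighted=True)
        assert d[0, 1] == pytest.approx(0.5)

    def test_two_hop_path_beats_weak_direct_edge(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[1, 2] = m[2, 1] = 1.0
        m[0, 2] = m[2, 0] = 0.25
        d = shortest_path_matrix(make_network(m), weighted=True)
        assert d[0, 2] == pytest.approx(2.0)

    def test_binary_hop_count(self, path3):
        d = shortest_path_matrix(path3, weighted=False)
        assert d[0, 2] == 2.0

    def test_unreachable_marked_infinite(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 1.0
        d = shortest_path_matrix(make_network(m), weighted=False)
        assert np.isinf(d[0, 2])

    @pytest.mark.parametrize("seed", range(3))
    def test_adding_an_edge_never_lengthens_paths(self, seed):
        rng = np.random.default_rng(200 + seed)
        w = random_symmetric_weights(10, 0.3, rng)
        net = make_network(w)
        d0 = shortest_path_matrix(net, weighted=True)
        absent = np.argwhere((w == 0) & ~np.eye(10, dtype=bool))
        i, j = absent[rng.integers(len(absent))]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 1.0
        d1 = shortest_path_matrix(make_network(w2), weighted=True)
        assert np.all(d1 <= d0 + 1e-12)


class TestCharPathLength:
    def test_complete_graph(self):
        net = make_network(np.ones((6, 6)) - np.eye(6))
        stats = char_path_length(net, weighted=False)
        assert stats.char_path_length == 1.0
        assert stats.n_unreachable_pairs == 0

    def test_path_graph_of_three(self, path3):
        stats = char_path_length(path3, weighted=False)
        assert stats.char_path_length == pytest.approx(4.0 / 3.0)

    def test_disconnected_pairs_excluded_and_counted(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 1.0
        stats = char_path_length(make_network(m), weighted=False)
        assert stats.char_path_length == 1.0
        assert stats.n_unreachable_pairs == 8

    def test_all_isolated_raises(self):
        net = make_network(np.zeros((3, 3)), allow_degenerate=True)
        with pytest.raises(DegenerateNetworkError):
            char_path_length(net, weighted=False)

    @pytest.mark.parametrize("weighted", [True, False])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_floyd_warshall(self, weighted, seed):
        rng = np.random.default_rng(300 + seed)
        w = random_symmetric_weights(8, 0.45, rng)
        net = make_network(w)
        expected = brute_char_path_length(w, weighted)
        got = char_path_length(net, weighted).char_path_length
        assert got == pytest.approx(expected, abs=1e-12)

    def test_weighted_distances_scale_inversely_with_weights(self, rng):
        w = random_symmetric_weights(8, 0.6, rng)
        lam = 3.7
        l1 = char_path_length(make_network(w), True).char_path_length
        l2 = char_path_length(make_network(lam * w), True).char_path_length
        assert l2 == pytest.approx(l1 / lam)

    def test_ring_lattice_path_length_oracle(self):
        # ring N=1000, r=5: hops(i,j) = ceil(d_ring / r); mean over pairs
        net = generate_ring_lattice(1000, 5)
        d = np.minimum(np.arange(1, 1000), 1000 - np.arange(1, 1000))
        hops = np.ceil(d / 5.0)
        expected = hops.mean()  # same for every source node on the ring
        got = char_path_length(net, weighted=False).char_path_length
        assert got == pytest.approx(expected)
        assert got == pytest.approx(50.45, abs=0.01)
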