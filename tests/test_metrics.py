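"""Weighted graph metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

import strokenet as sn

import oracles


def complete_graph(matrix_factory, n, w=1.0):
    return matrix_factory(n, [(i, j, w) for i in range(n) for j in range(i + 1, n)])


def star_graph(matrix_factory, n_leaves=3):
    return matrix_factory(n_leaves + 1, [(0, i, 1.0) for i in range(1, n_leaves + 1)])


class TestClosedForms:
    """Hand-derivable identities on canonical small graphs."""

    def test_triangle_unit_weights(self, matrix_factory):
        m = matrix_factory(3, [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)])
        assert np.allclose(sn.strength(m), [2, 2, 2])
        assert np.allclose(sn.local_clustering(m), [1, 1, 1])
        assert np.allclose(sn.betweenness(m), [0, 0, 0])
        assert sn.global_efficiency(m) == pytest.approx(1.0)

    def test_path_graph(self, matrix_factory):
        m = matrix_factory(3, [(0, 1, 0.5), (1, 2, 0.5)])
        assert np.allclose(sn.strength(m), [0.5, 1.0, 0.5])
        # degree-< 2 rule at the endpoints, missing triangle at the middle
        assert np.allclose(sn.local_clustering(m), [0, 0, 0])
        d = sn.shortest_path_lengths(m)
        assert d[0, 2] == pytest.approx(4.0)

    def test_unit_path_regional_efficiency(self, matrix_factory):
        m = matrix_factory(3, [(0, 1, 1.0), (1, 2, 1.0)])
        assert np.allclose(sn.regional_efficiency(m), [0.75, 1.0, 0.75])

    def test_star_betweenness_center_three(self, matrix_factory):
        m = star_graph(matrix_factory)
        assert np.allclose(sn.betweenness(m), [3, 0, 0, 0])

    def test_star_global_efficiency(self, matrix_factory):
        # 3 pairs at d=1 and 3 pairs at d=2 -> mean(1, .5, .5, .5, 1, 1) ... = 0.75
        assert sn.global_efficiency(star_graph(matrix_factory)) == pytest.approx(0.75)

    def test_star_vulnerability_center_and_leaf(self, matrix_factory):
        v = sn.vulnerability(star_graph(matrix_factory))
        assert v[0] == pytest.approx(0.75)  # removal isolates all leaves
        assert np.allclose(v[1:], -1 / 12)  # removing a leaf *raises* efficiency

    def test_star_global_vulnerability_is_max(self, matrix_factory):
        m = star_graph(matrix_factory)
        gm = sn.global_summary(sn.nodal_metrics(m), m)
        assert gm.global_vulnerability == pytest.approx(0.75)

    def test_four_cycle_tied_shortest_paths(self, matrix_factory):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 0, 1.0)]
        # two tied paths per opposite pair, half the credit to each intermediate
        assert np.allclose(sn.betweenness(matrix_factory(4, edges)), 0.5)

    def test_complete_graph_symmetry(self, matrix_factory):
        m = complete_graph(matrix_factory, 4)
        v = sn.vulnerability(m)
        assert np.allclose(v, v[0])
        gm = sn.global_summary(sn.nodal_metrics(m), m)
        assert gm.char_path_length == pytest.approx(1.0)

    def test_two_node_distance(self, matrix_factory):
        m = matrix_factory(2, [(0, 1, 0.5)])
        assert sn.shortest_path_lengths(m)[0, 1] == pytest.approx(2.0)

    def test_zero_matrix_global_summary(self, tiny_atlas_factory):
        m = sn.ConnectivityMatrix(np.zeros((4, 4)), tiny_atlas_factory(4))
        with pytest.warns(UserWarning, match="infinite|\\+inf|efficiency"):
            gm = sn.global_summary(sn.nodal_metrics(m), m)
        assert gm.global_strength == 0
        assert np.isinf(gm.char_path_length)
        assert sn.global_efficiency(m) == 0.0

    def test_isolated_node_efficiency_zero(self, matrix_factory):
        m = matrix_factory(3, [(0, 1, 1.0)])
        assert sn.regional_efficiency(m)[2] == 0.0


class TestWeightToLength:
    def test_inverse_map(self, matrix_factory):
        m = matrix_factory(2, [(0, 1, 0.5)])
        lengths = sn.weight_to_length(m)
        assert lengths[0, 1] == 2.0
        assert lengths[0, 0] == 0.0

    def test_absent_edge_infinite(self, matrix_factory):
        m = matrix_factory(3, [(0, 1, 0.5)])
        assert np.isinf(sn.weight_to_length(m)[0, 2])

    def test_monotone(self, random_matrix_factory):
        # larger weight never yields larger length; absent edges are +inf
        m = random_matrix_factory(8, seed=5)
        w = m.weights
        lengths = sn.weight_to_length(m)
        iu = np.triu_indices(8, 1)
        pos = w[iu] > 0
        order = np.argsort(w[iu][pos])
        assert np.all(np.diff(lengths[iu][pos][order]) <= 1e-15)
        assert np.all(np.isinf(lengths[iu][~pos]))


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("n,density", [(6, 0.5), (10, 0.35), (12, 0.3)])
class TestOracleEquivalence:
    """Random weighted graphs against the independent brute-force oracles."""

    def test_distances_match_floyd_warshall(self, random_matrix_factory, n, density, seed):
        m = random_matrix_factory(n, density=density, seed=seed)
        assert np.allclose(
            sn.shortest_path_lengths(m), oracles.floyd_warshall(m.weights), atol=1e-12
        )

    def test_all_metrics_match_oracles(self, random_matrix_factory, n, density, seed):
        m = random_matrix_factory(n, density=density, seed=seed)
        w = m.weights
        assert np.allclose(sn.strength(m), w.sum(axis=1), atol=1e-12)
        assert np.allclose(sn.local_clustering(m), oracles.onnela_clustering(w), atol=1e-12)
        assert np.allclose(sn.betweenness(m), oracles.betweenness(w), atol=1e-9)
        assert np.allclose(
            sn.regional_efficiency(m), oracles.regional_efficiency(w), atol=1e-12
        )
        assert sn.global_efficiency(m) == pytest.approx(
            oracles.global_efficiency(w), abs=1e-12
        )
        assert np.allclose(sn.vulnerability(m), oracles.vulnerability(w), atol=1e-12)


class TestInvariants:
    def test_adding_edge_never_decreases_efficiency(self, random_matrix_factory):
        m = random_matrix_factory(10, density=0.3, seed=9)
        before_d = sn.shortest_path_lengths(m)
        before_e = sn.global_efficiency(m)
        w = m.weights.copy()
        absent = np.argwhere((np.triu(np.ones_like(w), 1) > 0) & (w == 0))
        i, j = absent[0]
        w[i, j] = w[j, i] = 0.8
        m2 = sn.ConnectivityMatrix(w, m.atlas)
        after_d = sn.shortest_path_lengths(m2)
        assert sn.global_efficiency(m2) >= before_e
        finite = np.isfinite(before_d)
        assert np.all(after_d[finite] <= before_d[finite] + 1e-12)

    def test_degree_one_betweenness_and_low_degree_clustering_zero(
        self, random_matrix_factory
    ):
        m = random_matrix_factory(10, density=0.25, seed=2)
        deg = (m.weights > 0).sum(axis=1)
        b = sn.betweenness(m)
        c = sn.local_clustering(m)
        assert np.all(b[deg <= 1] == 0)
        assert np.all(c[deg < 2] == 0)

    def test_binary_matrix_clustering_equals_unweighted(self, random_matrix_factory):
        import networkx as nx

        m = random_matrix_factory(9, density=0.45, seed=4, unit_weights=True)
        g = nx.from_numpy_array(m.weights)
        expected = np.array([nx.clustering(g)[i] for i in range(9)])
        assert np.allclose(sn.local_clustering(m), expected, atol=1e-12)

    def test_char_path_length_times_efficiency_is_one(self, random_matrix_factory):
        for seed in range(5):
            m = random_matrix_factory(8, density=0.5, seed=seed)
            gm = sn.global_summary(sn.nodal_metrics(m), m)
            if gm.global_efficiency > 0:
                assert gm.char_path_length * gm.global_efficiency == pytest.approx(1.0)

    def test_global_summary_aggregation_rules(self, random_matrix_factory):
        m = random_matrix_factory(8, density=0.5, seed=13)
        nm = sn.nodal_metrics(m)
        gm = sn.global_summary(nm, m)
        assert gm.global_strength == pytest.approx(nm.strength.mean())
        assert gm.global_clustering == pytest.approx(nm.clustering.mean())
        assert gm.global_betweenness == pytest.approx(nm.betweenness.mean())
        assert gm.global_vulnerability == pytest.approx(nm.vulnerability.max())

    def test_vulnerability_needs_three_nodes(self, matrix_factory):
        with pytest.raises(ValueError):
            sn.vulnerability(matrix_factory(2, [(0, 1, 1.0)]))
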