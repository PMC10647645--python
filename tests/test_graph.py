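"""Graph-measure correctness: closed forms, brute-force oracles,
networkx cross-checks, and structural invariants."""

import numpy as np
import pytest

import networkx as nx

from dynconn.graph import (
    METRIC_NAMES,
    assortativity,
    betweenness_nodal,
    bfs_distances,
    clustering_and_transitivity,
    eccentricity_and_diameter,
    integration_metrics,
    kcore_nodal,
    metric_vector,
)

from .conftest import random_adjacency
from . import oracles


def complete(n):
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


def path_graph(n):
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


K4 = complete(4)
P4 = path_graph(4)
TWO_K2 = np.array(
    [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=np.int8
)
STAR4 = np.array(
    [[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]], dtype=np.int8
)


class TestClosedForms:
    def test_complete_graph(self):
        mv = metric_vector(K4)
        assert mv.clustering == 1.0
        assert mv.transitivity == 1.0
        assert mv.efficiency == 1.0
        assert mv.char_path_length == 1.0
        assert mv.degree == 3.0
        assert mv.betweenness == 0.0
        assert mv.eccentricity == 1.0
        assert mv.diameter == 1.0
        assert np.isnan(mv.assortativity)  # regular graph: zero degree variance
        assert mv.kcore == 3.0

    def test_path_graph(self):
        mv = metric_vector(P4)
        assert mv.clustering == 0.0 and mv.transitivity == 0.0
        # distances 1+2+3+1+2+1 over 6 unordered pairs
        assert mv.char_path_length == pytest.approx(10 / 6)
        assert mv.diameter == 3.0
        # nodal betweenness (0, 2, 2, 0)
        assert mv.betweenness == pytest.approx(1.0)
        np.testing.assert_allclose(betweenness_nodal(P4), [0, 2, 2, 0])
        # nodal eccentricities (3, 2, 2, 3)
        assert mv.eccentricity == pytest.approx(2.5)

    def test_two_disjoint_edges(self):
        mv = metric_vector(TWO_K2)
        # 4 reachable ordered pairs of 12
        assert mv.efficiency == pytest.approx(1 / 3)
        assert mv.char_path_length == 1.0
        d = bfs_distances(TWO_K2)
        assert np.isinf(d[0, 2])

    def test_star_graph_assortativity(self):
        assert assortativity(STAR4) == pytest.approx(-1.0)

    def test_k4_plus_pendant_coreness(self):
        a = np.zeros((5, 5), dtype=np.int8)
        a[:4, :4] = K4
        a[3, 4] = a[4, 3] = 1
        np.testing.assert_array_equal(kcore_nodal(a), [3, 3, 3, 3, 1])
        assert metric_vector(a).kcore == pytest.approx(2.6)

    def test_empty_graph_conventions(self):
        a = np.zeros((5, 5), dtype=np.int8)
        mv = metric_vector(a)
        assert mv.degree == 0.0 and mv.efficiency == 0.0
        assert mv.clustering == 0.0 and mv.transitivity == 0.0
        assert mv.kcore == 0.0
        assert np.isnan(mv.char_path_length)
        assert np.isnan(mv.assortativity)

    def test_isolated_node_plus_triangle(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[:3, :3] = complete(3)
        _, diam, nodal = eccentricity_and_diameter(bfs_distances(a))
        assert nodal[3] == 0.0
        assert diam == 1.0

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            metric_vector(np.zeros((1, 1), dtype=np.int8))


class TestBruteForceOracles:
    """Field-by-field agreement with independent naive implementations on
    random graphs spanning sizes and densities."""

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("density", [0.15, 0.4, 0.75])
    def test_distances_match_floyd_warshall(self, seed, density):
        rng = np.random.default_rng(1000 + seed)
        a = random_adjacency(rng, 12, density)
        np.testing.assert_array_equal(bfs_distances(a), oracles.floyd_warshall(a))

    @pytest.mark.parametrize("seed", range(60))
    def test_clustering_matches_triangle_enumeration(self, seed):
        rng = np.random.default_rng(2000 + seed)
        a = random_adjacency(rng, 10, rng.uniform(0.1, 0.9))
        c_mean, trans, nodal = clustering_and_transitivity(a)
        o_nodal, o_trans = oracles.triangle_clustering(a)
        np.testing.assert_allclose(nodal, o_nodal, atol=1e-12)
        assert trans == pytest.approx(o_trans, abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_betweenness_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(3000 + seed)
        a = random_adjacency(rng, 10, rng.uniform(0.15, 0.6))
        np.testing.assert_allclose(
            betweenness_nodal(a), oracles.betweenness_by_enumeration(a), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(40))
    def test_coreness_matches_repeated_pruning(self, seed):
        rng = np.random.default_rng(4000 + seed)
        a = random_adjacency(rng, 12, rng.uniform(0.1, 0.9))
        np.testing.assert_array_equal(kcore_nodal(a), oracles.coreness_by_pruning(a))

    @pytest.mark.parametrize("seed", range(40))
    def test_assortativity_matches_edge_list_correlation(self, seed):
        rng = np.random.default_rng(5000 + seed)
        a = random_adjacency(rng, 12, rng.uniform(0.15, 0.9))
        ours = assortativity(a)
        oracle = oracles.assortativity_by_edge_list(a)
        if np.isnan(oracle):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(oracle, abs=1e-10)


class TestNetworkxCrossCheck:
    """Agreement with a general-purpose graph library where conventions
    coincide (connected graphs)."""

    @pytest.mark.parametrize("seed", range(30))
    def test_connected_graph_metrics(self, seed):
        rng = np.random.default_rng(6000 + seed)
        a = random_adjacency(rng, 9, rng.uniform(0.35, 0.8))
        g = nx.from_numpy_array(a)
        if not nx.is_connected(g):
            a = a.copy()
            comps = list(nx.connected_components(g))
            for c1, c2 in zip(comps, comps[1:]):
                i, j = min(c1), min(c2)
                a[i, j] = a[j, i] = 1
            g = nx.from_numpy_array(a)
        mv = metric_vector(a)
        assert mv.clustering == pytest.approx(nx.average_clustering(g), abs=1e-10)
        assert mv.transitivity == pytest.approx(nx.transitivity(g), abs=1e-10)
        assert mv.efficiency == pytest.approx(nx.global_efficiency(g), abs=1e-10)
        assert mv.char_path_length == pytest.approx(
            nx.average_shortest_path_length(g), abs=1e-10
        )
        assert mv.diameter == pytest.approx(nx.diameter(g))
        assert mv.eccentricity == pytest.approx(
            np.mean(list(nx.eccentricity(g).values()))
        )
        nx_bc = nx.betweenness_centrality(g, normalized=False)
        assert mv.betweenness == pytest.approx(
            np.mean(list(nx_bc.values())), abs=1e-10
        )
        nx_core = nx.core_number(g)
        assert mv.kcore == pytest.approx(np.mean(list(nx_core.values())))
        r = assortativity(a)
        nx_r = nx.degree_assortativity_coefficient(g)
        if np.isnan(nx_r):
            assert np.isnan(r)
        else:
            assert r == pytest.approx(nx_r, abs=1e-8)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_isomorphism_invariance(self, seed):
        rng = np.random.default_rng(7000 + seed)
        a = random_adjacency(rng, 10, 0.4)
        perm = rng.permutation(10)
        b = a[np.ix_(perm, perm)]
        mv_a = metric_vector(a).as_dict()
        mv_b = metric_vector(b).as_dict()
        for name in METRIC_NAMES:
            if np.isnan(mv_a[name]):
                assert np.isnan(mv_b[name])
            else:
                assert mv_a[name] == pytest.approx(mv_b[name], abs=1e-10), name

    @pytest.mark.parametrize("seed", range(10))
    def test_edge_addition_monotonicity(self, seed):
        rng = np.random.default_rng(8000 + seed)
        a = random_adjacency(rng, 8, 0.3)
        zeros = np.argwhere(np.triu(a == 0, 1))
        if len(zeros) == 0:
            pytest.skip("graph already complete")
        i, j = zeros[rng.integers(len(zeros))]
        b = a.copy()
        b[i, j] = b[j, i] = 1
        for name in ("efficiency", "degree", "kcore"):
            before = getattr(metric_vector(a), name)
            after = getattr(metric_vector(b), name)
            assert after >= before - 1e-12, name

    def test_bounds_on_random_graphs(self):
        rng = np.random.default_rng(9000)
        for _ in range(300):
            n = int(rng.integers(4, 21))
            a = random_adjacency(rng, n, rng.uniform(0.1, 0.9))
            mv = metric_vector(a)
            assert 0 <= mv.clustering <= 1 and 0 <= mv.transitivity <= 1
            assert 0 <= mv.efficiency <= 1
            assert 0 <= mv.degree <= n - 1
            assert 0 <= mv.kcore <= n - 1
            assert np.isnan(mv.assortativity) or -1 - 1e-9 <= mv.assortativity <= 1 + 1e-9
            if np.isfinite(mv.char_path_length) and mv.char_path_length >= 1:
                assert mv.diameter >= mv.char_path_length - 1e-12
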