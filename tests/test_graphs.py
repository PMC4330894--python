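"""Weighted graph metrics against exhaustive brute-force oracles."""

import itertools

import numpy as np
import pytest

from munet import (char_path_length, clustering_coefficient,
                   global_efficiency, local_efficiency, normalize_weights,
                   shortest_path_matrix, weighted_graph)
from munet.errors import DisconnectedGraphError, EmptyNetworkError
from munet.graphs import metrics_from_thresholded
from munet.threshold import ThresholdedSL


# ------------------------------------------------------------- oracles

def oracle_clustering(W):
    n = len(W)
    c = np.zeros(n)
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        t = 0.0
        for j, h in itertools.combinations(range(n), 2):
            if j == i or h == i:
                continue
            t += (W[i, j] * W[i, h] * W[j, h]) ** (1 / 3)
        c[i] = 2 * t / (k * (k - 1))
    return c.mean()


def oracle_distances(W):
    """Floyd-Warshall on edge lengths 1/w."""
    n = len(W)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                d[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_char_path(d):
    n = len(d)
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return np.mean(vals)


def oracle_global_eff(d):
    n = len(d)
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for i in range(n) for j in range(n) if i != j]
    return np.mean(vals)


def oracle_local_eff(W):
    n = len(W)
    e = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        d_sub = oracle_distances(W[np.ix_(nbrs, nbrs)])
        total = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if j == h or not np.isfinite(d_sub[a, b]) or d_sub[a, b] == 0:
                    continue
                total += (W[i, j] * W[i, h] / d_sub[a, b]) ** (1 / 3)
        e[i] = total / (k * (k - 1))
    return e.mean()


def random_weighted(rng, n, density=0.5):
    W = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.uniform() < density:
            W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    return W


# ------------------------------------------------------------- tests

class TestAnalyticCases:
    def test_complete_unit_graph(self):
        n = 5
        W = np.ones((n, n)) - np.eye(n)
        g = weighted_graph(W)
        d = shortest_path_matrix(g)
        assert clustering_coefficient(g) == pytest.approx(1.0)
        assert local_efficiency(g) == pytest.approx(1.0)
        L, frac = char_path_length(d)
        assert (L, frac) == (pytest.approx(1.0), 0.0)
        assert global_efficiency(d) == pytest.approx(1.0)

    def test_star_graph_has_no_segregation(self):
        n = 6
        W = np.zeros((n, n))
        W[0, 1:] = W[1:, 0] = 1.0
        g = weighted_graph(W)
        assert clustering_coefficient(g) == 0.0
        assert local_efficiency(g) == 0.0

    def test_single_edge_distance_is_inverse_weight(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        d = shortest_path_matrix(weighted_graph(W))
        assert d[0, 1] == pytest.approx(2.0)

    def test_chain_path_sums(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        d = shortest_path_matrix(weighted_graph(W))
        assert d[0, 2] == pytest.approx(2.0)
        L, frac = char_path_length(d)
        assert L == pytest.approx(4.0 / 3.0)
        assert frac == 0.0

    def test_two_disjoint_edges(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        d = shortest_path_matrix(weighted_graph(W))
        L, frac = char_path_length(d)
        assert L == pytest.approx(1.0)
        assert frac == pytest.approx(2.0 / 3.0)

    def test_fully_disconnected_efficiency_zero(self):
        d = shortest_path_matrix(weighted_graph(np.zeros((4, 4))))
        assert global_efficiency(d) == 0.0
        with pytest.raises(DisconnectedGraphError):
            char_path_length(d)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        W = random_weighted(rng, n)
        g = weighted_graph(W)
        d = shortest_path_matrix(g)
        np.testing.assert_allclose(d, oracle_distances(W), atol=1e-12)
        assert clustering_coefficient(g) == pytest.approx(
            oracle_clustering(W), abs=1e-12)
        assert local_efficiency(g) == pytest.approx(
            oracle_local_eff(W), abs=1e-12)
        assert global_efficiency(d) == pytest.approx(
            oracle_global_eff(d), abs=1e-12)
        if np.isfinite(d[~np.eye(n, dtype=bool)]).any():
            L, _ = char_path_length(d)
            assert L == pytest.approx(oracle_char_path(d), abs=1e-12)

    def test_clustering_matches_networkx(self, rng):
        import networkx as nx
        W = random_weighted(rng, 8)
        g = normalize_weights(W)
        G = nx.from_numpy_array(g.W)
        assert clustering_coefficient(g) == pytest.approx(
            nx.average_clustering(G, weight="weight"), abs=1e-10)

    def test_distances_match_networkx_dijkstra(self, rng):
        import networkx as nx
        W = random_weighted(rng, 8)
        g = weighted_graph(W)
        d = shortest_path_matrix(g)
        G = nx.Graph()
        G.add_nodes_from(range(8))
        for i, j in zip(*np.nonzero(np.triu(W))):
            G.add_edge(int(i), int(j), length=1.0 / W[i, j])
        for i in range(8):
            lengths = nx.single_source_dijkstra_path_length(G, i,
                                                            weight="length")
            for j in range(8):
                expect = lengths.get(j, np.inf)
                assert d[i, j] == pytest.approx(expect, abs=1e-12)


class TestNormalization:
    def test_max_edge_maps_to_one_and_order_preserved(self, rng):
        W = random_weighted(rng, 6)
        g = normalize_weights(W)
        assert g.W.max() == pytest.approx(1.0)
        iu = np.triu_indices(6, k=1)
        assert np.array_equal(np.argsort(W[iu]), np.argsort(g.W[iu]))

    def test_single_edge(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        g = normalize_weights(W)
        assert np.count_nonzero(g.W) == 2
        assert g.W[0, 1] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyNetworkError):
            normalize_weights(np.zeros((3, 3)))

    def test_scale_invariance_of_segregation(self, rng):
        W = random_weighted(rng, 7)

        def seg(values):
            g = normalize_weights(values)
            return clustering_coefficient(g), local_efficiency(g)

        assert seg(W) == pytest.approx(seg(4.2 * W), abs=0)


class TestComputeAll:
    def _thresholded(self, W):
        iu = np.triu_indices(W.shape[0], k=1)
        edges = int(np.count_nonzero(W[iu]))
        return ThresholdedSL(values=W, threshold=0.0, n_retained=2 * edges,
                             edge_count=edges)

    def test_identical_conditions_identical_metrics(self, rng):
        W = random_weighted(rng, 8) * 0.5
        from munet.graphs import compute_all
        a, b = compute_all(self._thresholded(W), self._thresholded(W.copy()))
        assert a == b

    def test_metrics_bounds(self, rng):
        W = random_weighted(rng, 8) * 0.8
        m = metrics_from_thresholded(self._thresholded(W))
        assert 0 <= m.C <= 1 and 0 <= m.E_loc <= 1 and 0 <= m.E_glob <= 1
        assert m.L > 0
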