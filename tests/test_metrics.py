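"""Graph metrics against independent brute-force oracles.

Oracles: triangle enumeration for clustering, Floyd-Warshall for distances
and efficiencies, networkx exhaustive shortest-path enumeration for
betweenness. Closed-form cases (complete graphs, paths, stars, cycles) are
asserted exactly.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcnet
from fcnet.connectome import BinaryNetwork, SparsityGrid
from fcnet import metrics as M

from conftest import random_binary_network


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_clustering(a):
    n = a.shape[0]
    ci = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        k = len(nb)
        if k < 2:
            continue
        t = sum(a[u, v] for u, v in itertools.combinations(nb, 2))
        ci[i] = 2 * t / (k * (k - 1))
    return ci


def oracle_floyd_warshall(a):
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_global_efficiency(a):
    d = oracle_floyd_warshall(a)
    n = a.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0)
    inv[np.isinf(d)] = 0
    return inv.sum() / (n * (n - 1))


def oracle_local_efficiency(a):
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if len(nb) < 2:
            continue
        out[i] = oracle_global_efficiency(a[np.ix_(nb, nb)])
    return out


def oracle_betweenness(a):
    """Exhaustive shortest-path enumeration (networkx all_shortest_paths)."""
    G = nx.from_numpy_array(a)
    n = a.shape[0]
    b = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not nx.has_path(G, s, t):
            continue
        paths = list(nx.all_shortest_paths(G, s, t))
        for p in paths:
            for v in p[1:-1]:
                b[v] += 1.0 / len(paths)
    return b


def net_from_edges(n, edges):
    edges = list(edges)
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(a, sparsity=max(len(edges) / (n * (n - 1) / 2), 1e-6))


# ---------------------------------------------------------------------------
# closed-form cases
# ---------------------------------------------------------------------------

class TestClosedForm:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_metrics_are_one(self, n):
        g = net_from_edges(n, itertools.combinations(range(n), 2))
        _, cp = fcnet.clustering_coefficient(g)
        assert cp == 1.0
        assert fcnet.global_efficiency(g) == 1.0
        assert fcnet.local_efficiency(g)[1] == 1.0
        assert fcnet.characteristic_path_length(g) == 1.0

    def test_triangle_cp_one_star_cp_zero(self):
        tri = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert fcnet.clustering_coefficient(tri)[1] == 1.0
        star = net_from_edges(6, [(0, i) for i in range(1, 6)])
        assert fcnet.clustering_coefficient(star)[1] == 0.0
        assert fcnet.local_efficiency(star)[1] == 0.0

    def test_five_node_clustering_example(self):
        g = net_from_edges(5, [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)])
        ci, cp = fcnet.clustering_coefficient(g)
        np.testing.assert_allclose(ci, [1, 1, 1 / 3, 0, 0])
        assert cp == pytest.approx(7 / 15)

    def test_path_of_three(self):
        g = net_from_edges(3, [(0, 1), (1, 2)])
        d = fcnet.shortest_path_lengths(g)
        assert d[0, 2] == 2
        assert fcnet.characteristic_path_length(g) == pytest.approx(4 / 3)
        assert fcnet.global_efficiency(g) == pytest.approx(5 / 6)
        np.testing.assert_allclose(fcnet.betweenness(g), [0, 1, 0])

    def test_star_center_betweenness(self):
        g = net_from_edges(5, [(0, i) for i in range(1, 5)])
        b = fcnet.betweenness(g)
        assert b[0] == pytest.approx(6.0)  # all 4*3/2 pairs
        np.testing.assert_allclose(b[1:], 0.0)

    def test_cycle_c4_betweenness_half(self):
        g = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        np.testing.assert_allclose(fcnet.betweenness(g), 0.5)

    def test_two_disjoint_dyads_warn_but_lp_one(self):
        g = net_from_edges(4, [(0, 1), (2, 3)])
        with pytest.warns(UserWarning, match="fragmented"):
            assert fcnet.characteristic_path_length(g) == 1.0

    def test_empty_graph_lp_raises(self):
        g = net_from_edges(3, [])
        with pytest.raises(ValueError):
            fcnet.characteristic_path_length(g)

    def test_isolated_node_zero_efficiency(self):
        g = net_from_edges(4, [(0, 1), (0, 2), (1, 2)])
        assert fcnet.nodal_efficiency(g)[3] == 0.0


# ---------------------------------------------------------------------------
# randomized oracle agreement
# ---------------------------------------------------------------------------

class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(50))
    def test_all_metrics_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = random_binary_network(rng, n, p=float(rng.uniform(0.15, 0.7)))
        a = g.adjacency.astype(float)

        ci, cp = fcnet.clustering_coefficient(g)
        np.testing.assert_allclose(ci, oracle_clustering(a), atol=1e-12)

        d = fcnet.shortest_path_lengths(g)
        np.testing.assert_array_equal(d, oracle_floyd_warshall(a))

        assert fcnet.global_efficiency(g) == pytest.approx(
            oracle_global_efficiency(a), abs=1e-12
        )
        eloc_i, _ = fcnet.local_efficiency(g)
        np.testing.assert_allclose(eloc_i, oracle_local_efficiency(a), atol=1e-12)
        np.testing.assert_allclose(
            fcnet.betweenness(g), oracle_betweenness(g.adjacency), atol=1e-9
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_node_relabelling_permutes_metrics(self, seed):
        rng = np.random.default_rng(seed)
        g = random_binary_network(rng, 10, 0.4)
        perm = rng.permutation(10)
        a2 = g.adjacency[np.ix_(perm, perm)]
        g2 = BinaryNetwork(a2, g.sparsity)
        np.testing.assert_allclose(
            fcnet.clustering_coefficient(g2)[0],
            fcnet.clustering_coefficient(g)[0][perm],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            fcnet.betweenness(g2), fcnet.betweenness(g)[perm], atol=1e-9
        )
        assert fcnet.global_efficiency(g2) == pytest.approx(
            fcnet.global_efficiency(g), abs=1e-12
        )

    def test_mean_nodal_efficiency_equals_global(self, rng):
        for _ in range(5):
            g = random_binary_network(rng, 15, 0.3)
            assert fcnet.nodal_efficiency(g).mean() == pytest.approx(
                fcnet.global_efficiency(g), abs=1e-12
            )
            eloc_i, eloc = fcnet.local_efficiency(g)
            assert eloc_i.mean() == pytest.approx(eloc, abs=1e-12)


# ---------------------------------------------------------------------------
# null models and small-world ratios
# ---------------------------------------------------------------------------

class TestNullModels:
    def test_rewired_surrogate_preserves_degrees(self, rng):
        g = random_binary_network(rng, 20, 0.25)
        null = fcnet.randomize_preserving_degrees(g, seed=5)
        np.testing.assert_array_equal(null.degrees, g.degrees)
        assert not np.array_equal(null.adjacency, g.adjacency)

    def test_same_seed_same_ensemble(self, rng):
        g = random_binary_network(rng, 20, 0.25)
        a = fcnet.degree_preserving_nulls(g, n_nulls=10, seed=3)
        b = fcnet.degree_preserving_nulls(g, n_nulls=10, seed=3)
        assert a.cp_rand_mean == b.cp_rand_mean
        assert a.lp_rand_mean == b.lp_rand_mean

    def test_ring_lattice_nulls_lose_clustering(self):
        G = nx.watts_strogatz_graph(30, 4, 0.0)
        g = BinaryNetwork(nx.to_numpy_array(G, dtype=int), 4 / 29)
        _, cp = fcnet.clustering_coefficient(g)
        nulls = fcnet.degree_preserving_nulls(g, n_nulls=30, seed=1)
        assert nulls.cp_rand_mean < cp

    def test_complete_graph_small_world_ratios_are_one(self):
        g = net_from_edges(6, itertools.combinations(range(6), 2))
        with pytest.warns(UserWarning, match="no degree-preserving swap"):
            nulls = fcnet.degree_preserving_nulls(g, n_nulls=5, seed=0)
        gamma, lam, sigma = fcnet.small_world(g, nulls)
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_watts_strogatz_is_small_world(self):
        G = nx.watts_strogatz_graph(90, 10, 0.1, seed=4)
        g = BinaryNetwork(nx.to_numpy_array(G, dtype=int), 10 / 89)
        nulls = fcnet.degree_preserving_nulls(g, n_nulls=100, seed=2)
        gamma, lam, sigma = fcnet.small_world(g, nulls)
        assert sigma > 1
        assert gamma > 1

    def test_sigma_identity_holds_exactly(self, rng):
        g = random_binary_network(rng, 25, 0.2)
        nulls = fcnet.degree_preserving_nulls(g, n_nulls=20, seed=9)
        gamma, lam, sigma = fcnet.small_world(g, nulls)
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAuc:
    def test_constant_curve(self):
        grid = SparsityGrid()
        assert fcnet.auc(np.full(47, 2.0), grid) == pytest.approx(2 * 0.46)

    def test_zero_curve(self):
        assert fcnet.auc(np.zeros(47), SparsityGrid()) == 0.0

    def test_linear_ramp_is_triangle_area(self):
        grid = SparsityGrid()
        assert fcnet.auc(np.linspace(0, 1, 47), grid) == pytest.approx(0.23)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            fcnet.auc(np.zeros(10), SparsityGrid())

    def test_non_finite_raises(self):
        vals = np.zeros(47)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            fcnet.auc(vals, SparsityGrid())
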