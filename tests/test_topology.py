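"""Topology generation and graph-statistic tests against independent oracles."""
import numpy as np
import networkx as nx
import pytest
import scipy.sparse as sp

from presynet import SimulationConfig
from presynet.topology import (build_connectivity, clustering_coefficient,
                               generate_topology, load_topology,
                               mean_shortest_path, place_neurons,
                               sample_degrees, save_topology, shortest_paths,
                               small_world_index)


class TestPlacement:
    def test_points_inside_square(self, rng):
        pos = place_neurons(800, 100.0, rng)
        assert pos.shape == (800, 2)
        assert pos.min() >= 0 and pos.max() <= 100

    def test_minimal_case(self, rng):
        assert place_neurons(2, 1.0, rng).shape == (2, 2)

    def test_deterministic_given_seed(self):
        a = place_neurons(50, 10.0, np.random.default_rng(3))
        b = place_neurons(50, 10.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n,dims", [(1, 1.0), (5, 0.0), (5, -2.0)])
    def test_invalid_arguments(self, rng, n, dims):
        with pytest.raises(ValueError):
            place_neurons(n, dims, rng)


class TestDegrees:
    def test_mean_matches_connectivity_ratio(self, rng):
        # ensemble mean within 5 % of 0.05 * 799
        degs = np.concatenate([sample_degrees(800, 0.05, rng)
                               for _ in range(20)])
        assert degs.mean() == pytest.approx(0.05 * 799, rel=0.05)

    def test_bounds_and_integrality(self, rng):
        degs = sample_degrees(800, 0.05, rng)
        assert degs.dtype.kind == "i"
        assert degs.min() >= 1 and degs.max() <= 799

    def test_right_heavy_tail(self, rng):
        degs = sample_degrees(10_000, 0.05, rng)
        from scipy.stats import skew
        assert skew(degs) > 0

    def test_infeasible_ratio_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_degrees(10, 1.5, rng)
        with pytest.raises(ValueError):
            sample_degrees(800, 1e-5, rng)


class TestBuildConnectivity:
    def test_realized_connectivity_near_target(self, rng):
        cfg = SimulationConfig()
        topo = generate_topology(cfg, rng)
        assert 0.045 <= topo.connectivity_ratio_realized <= 0.055

    def test_invariants(self, rng):
        topo = generate_topology(SimulationConfig(n_neurons=300), rng)
        a = topo.adjacency.tocoo()
        assert not np.any(a.row == a.col)                     # no self-edges
        assert np.all(np.abs(a.data) <= 10.0)                 # A_max bound
        # sign consistency with the source neuron type
        assert np.all((a.data < 0) == topo.is_inhibitory[a.col])
        # inhibitory fraction within integer rounding
        assert abs(topo.is_inhibitory.mean() - 0.30) < 1 / 300

    def test_saturated_degrees_give_complete_graph(self, rng):
        pos = place_neurons(12, 10.0, rng)
        topo = build_connectivity(pos, np.full(12, 11),
                                  np.zeros(12, bool), rng)
        assert topo.n_edges == 12 * 11

    def test_raw_lognormal_median(self, rng):
        # truncation at 10 is negligible for these parameters
        pos = place_neurons(80, 100.0, rng)
        topo = build_connectivity(pos, np.full(80, 60), np.zeros(80, bool),
                                  rng, weight_mu=-0.874, weight_sigma=1.026)
        med = np.median(topo.adjacency.tocoo().data)
        assert med == pytest.approx(np.exp(-0.874), rel=0.1)

    def test_weight_mean_calibration(self, rng):
        """Realized weights match the truncated rescaled lognormal: the
        pre-truncation mean is weight_mean, then mass above A_max is
        resampled (oracle: scipy truncated-lognormal expectation)."""
        from scipy.stats import lognorm
        cfg = SimulationConfig(n_neurons=400)
        topo = generate_topology(cfg, rng)
        mean_w = np.abs(topo.adjacency.tocoo().data).mean()
        raw_mean = np.exp(cfg.weight_mu + cfg.weight_sigma ** 2 / 2)
        dist = lognorm(s=cfg.weight_sigma,
                       scale=np.exp(cfg.weight_mu) * cfg.weight_mean / raw_mean)
        expected = dist.expect(lambda x: x, lb=0, ub=cfg.a_max) / dist.cdf(cfg.a_max)
        assert mean_w == pytest.approx(expected, rel=0.05)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_neurons=150)
        t1 = generate_topology(cfg, np.random.default_rng(9))
        t2 = generate_topology(cfg, np.random.default_rng(9))
        assert (t1.adjacency != t2.adjacency).nnz == 0
        np.testing.assert_array_equal(t1.positions, t2.positions)


def _random_digraph(rng, n, p):
    a = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(a, 0)
    return sp.csr_matrix(a)


class TestShortestPaths:
    def test_complete_graph(self):
        a = sp.csr_matrix(np.ones((4, 4)) - np.eye(4))
        d = shortest_paths(a)
        off = ~np.eye(4, dtype=bool)
        assert np.all(d[off] == 1) and np.all(np.diag(d) == 0)

    def test_directed_chain(self):
        a = sp.csr_matrix(np.diag(np.ones(3), k=-1))   # a->b->c->d (col=src)
        d = shortest_paths(a)
        assert d[0, 3] == 3 and np.isinf(d[3, 0])

    def test_matches_bfs_oracle(self, rng):
        """Floyd-Warshall output equals per-source BFS on random digraphs."""
        for _ in range(25):
            n = int(rng.integers(5, 26))
            a = _random_digraph(rng, n, float(rng.uniform(0.05, 0.4)))
            d = shortest_paths(a)
            g = nx.from_scipy_sparse_array(a.T, create_using=nx.DiGraph)
            for src in range(n):
                lengths = nx.single_source_shortest_path_length(g, src)
                for dst in range(n):
                    expected = lengths.get(dst, np.inf)
                    assert d[src, dst] == expected


def _clustering_bruteforce(b: np.ndarray) -> float:
    """Exhaustive triangle / length-2-path enumeration on a symmetric 0/1
    matrix (the independent oracle)."""
    n = b.shape[0]
    triangles = 0
    paths2 = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if j != i and k != i and k != j:
                    if b[i, j] and b[j, k]:
                        paths2 += 1          # ordered path i-j-k through j
                        if b[k, i]:
                            triangles += 1   # closed
    return triangles / paths2 if paths2 else 0.0


class TestClustering:
    def test_triangle_graph(self):
        a = sp.csr_matrix(np.ones((3, 3)) - np.eye(3))
        assert clustering_coefficient(a) == 1.0

    def test_star_graph(self):
        a = np.zeros((5, 5))
        a[0, 1:] = 1
        assert clustering_coefficient(sp.csr_matrix(a)) == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 16))
            a = _random_digraph(rng, n, float(rng.uniform(0.1, 0.5)))
            b = ((a + a.T) != 0).toarray().astype(int)
            np.fill_diagonal(b, 0)
            assert clustering_coefficient(a) == pytest.approx(
                _clustering_bruteforce(b), abs=1e-12)


class TestSmallWorld:
    def test_er_graph_self_normalizes_to_one(self, rng):
        from presynet.topology import _er_reference, NetworkTopology
        n, m = 300, 3500
        er = _er_reference(n, m, rng)
        topo = NetworkTopology(positions=rng.random((n, 2)),
                               is_inhibitory=np.zeros(n, bool), adjacency=er)
        metrics = small_world_index(topo, n_reference=15, rng=rng)
        assert metrics.small_world_index == pytest.approx(1.0, abs=0.25)

    def test_ring_lattice_has_high_normalized_clustering(self, rng):
        # ring with k nearest neighbours: clustering 3(k-2)/(4(k-1)), long paths
        from presynet.topology import NetworkTopology
        g = nx.watts_strogatz_graph(200, 8, 0.0)
        a = sp.csr_matrix(nx.to_scipy_sparse_array(g))
        analytic = 3 * (4 - 1) / (2 * (2 * 4 - 1))   # = 0.6428... for k=8
        assert clustering_coefficient(a) == pytest.approx(analytic, rel=1e-9)
        topo = NetworkTopology(positions=rng.random((200, 2)),
                               is_inhibitory=np.zeros(200, bool), adjacency=a)
        metrics = small_world_index(topo, n_reference=10, rng=rng)
        assert metrics.normalized_clustering > 3.0

    def test_generated_topology_has_heavier_degree_tail_than_er(self, rng):
        """Excess kurtosis of the out-degree distribution exceeds a
        degree-matched E-R graph's, over an ensemble of seeds."""
        from scipy.stats import kurtosis
        cfg = SimulationConfig(n_neurons=400)
        wins = 0
        for seed in range(20):
            topo = generate_topology(cfg, np.random.default_rng(seed))
            out_deg = np.asarray((topo.adjacency != 0).sum(axis=0)).ravel()
            er_deg = rng.binomial(399, topo.connectivity_ratio_realized, 400)
            if kurtosis(out_deg) > kurtosis(er_deg):
                wins += 1
        assert wins >= 15


class TestRoundTrip:
    def test_edge_list_round_trip_lossless(self, rng, tmp_path):
        topo = generate_topology(SimulationConfig(n_neurons=120), rng)
        save_topology(topo, tmp_path / "edges.csv", tmp_path / "nodes.csv")
        back = load_topology(tmp_path / "edges.csv", tmp_path / "nodes.csv")
        assert (topo.adjacency != back.adjacency).nnz == 0
        np.testing.assert_array_equal(topo.positions, back.positions)
        np.testing.assert_array_equal(topo.is_inhibitory, back.is_inhibitory)
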