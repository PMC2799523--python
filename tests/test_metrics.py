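import numpy as np
import pytest

import restgraph as rg
from restgraph.metrics import fit_degree_distributions, n_to_1_connectivity

from conftest import random_graph
from oracles import (
    clustering_by_enumeration,
    global_efficiency_by_pairs,
    local_efficiency_by_pairs,
    mean_path_length,
)


class TestDegreesAndHubs:
    def test_complete_graph_degrees(self):
        k, mean_k = rg.degrees(rg.make_benchmark_graph("complete", 5))
        assert (k == 4).all() and mean_k == 4.0

    def test_star_graph_degrees(self):
        k, mean_k = rg.degrees(rg.make_benchmark_graph("star", 5))
        assert sorted(k) == [1, 1, 1, 1, 4]
        assert mean_k == pytest.approx(1.6)

    def test_edgeless_graph(self):
        g = rg.BinaryGraph(np.zeros((3, 3), dtype=bool))
        _, mean_k = rg.degrees(g)
        assert mean_k == 0.0

    def test_regular_graph_has_no_hubs(self):
        assert rg.hubs(rg.make_benchmark_graph("complete", 6)).size == 0

    def test_star_hub_is_center(self):
        g = rg.make_benchmark_graph("star", 5)
        center = int(np.argmax(g.degrees()))
        assert list(rg.hubs(g)) == [center]

    def test_path_hub_is_middle(self):
        # degrees (1, 2, 1), K = 4/3: only the middle node exceeds it
        g = rg.make_benchmark_graph("path", 3)
        assert list(rg.hubs(g)) == [1]

    def test_handshake_identity_over_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(3, 30)), rng.uniform(0.1, 0.9))
            k, _ = rg.degrees(g)
            assert k.sum() == 2 * g.n_edges
            assert k.sum() % 2 == 0


class TestClusteringAndPaths:
    def test_triangle_fully_clustered(self):
        c, c_net = rg.clustering(rg.make_benchmark_graph("complete", 3))
        assert np.allclose(c, 1.0) and c_net == 1.0

    def test_star_has_no_triangles(self):
        _, c_net = rg.clustering(rg.make_benchmark_graph("star", 4))
        assert c_net == 0.0

    @pytest.mark.parametrize("k", [4, 6, 8])
    def test_ring_lattice_closed_form(self, k):
        g = rg.make_benchmark_graph("ring_lattice", 100, k=k)
        _, c_net = rg.clustering(g)
        assert c_net == pytest.approx(3 * (k - 2) / (4 * (k - 1)), abs=1e-12)

    def test_complete_graph_unit_path_length(self):
        _, l_net = rg.path_lengths(rg.make_benchmark_graph("complete", 4))
        assert l_net == pytest.approx(1.0)

    def test_path_graph_mean_distance(self):
        _, l_net = rg.path_lengths(rg.make_benchmark_graph("path", 3))
        assert l_net == pytest.approx(4.0 / 3.0)

    def test_six_cycle_mean_distance(self):
        g = rg.make_benchmark_graph("ring_lattice", 6, k=2)
        l_vec, l_net = rg.path_lengths(g)
        assert np.allclose(l_vec, 1.8)
        assert l_net == pytest.approx(1.8)

    def test_disconnected_strict_mode_raises(self):
        g = rg.BinaryGraph(np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            rg.path_lengths(g, on_disconnected="strict")

    def test_disconnected_largest_mode_warns_and_masks(self, caplog):
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True  # path of 3 + 2 isolates
        g = rg.BinaryGraph(adj)
        with caplog.at_level("WARNING"):
            l_vec, l_net = rg.path_lengths(g)
        assert "disconnected" in caplog.text
        assert l_net == pytest.approx(4.0 / 3.0)
        assert np.isnan(l_vec[3]) and np.isnan(l_vec[4])


class TestEfficiency:
    def test_complete_graph_efficiencies(self):
        g = rg.make_benchmark_graph("complete", 5)
        assert rg.global_efficiency(g) == pytest.approx(1.0)
        assert rg.local_efficiency(g) == pytest.approx(1.0)

    def test_edgeless_graph_zero_efficiency(self):
        g = rg.BinaryGraph(np.zeros((4, 4), dtype=bool))
        assert rg.global_efficiency(g) == 0.0

    def test_path_graph_by_enumeration(self):
        g = rg.make_benchmark_graph("path", 3)
        assert rg.global_efficiency(g) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_two_triangles_component_size(self):
        adj = np.zeros((6, 6), dtype=bool)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = True
        assert rg.largest_component_size(rg.BinaryGraph(adj)) == 3


class TestBruteForceEquivalence:
    def test_metrics_match_enumeration_on_small_graphs(self):
        """C_i, L_net, E_glob, E_loc vs brute force on 50 seeded graphs (n <= 8)."""
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            g = random_graph(rng, n, rng.uniform(0.15, 0.95))
            adj = g.adjacency
            c, _ = rg.clustering(g)
            assert np.allclose(c, clustering_by_enumeration(adj), atol=1e-12)
            assert rg.global_efficiency(g) == pytest.approx(
                global_efficiency_by_pairs(adj), abs=1e-12
            )
            assert rg.local_efficiency(g) == pytest.approx(
                local_efficiency_by_pairs(adj), abs=1e-12
            )
            if g.n_edges > 0:
                _, l_net = rg.path_lengths(g)
                oracle = mean_path_length(adj)
                if np.isnan(oracle):
                    assert np.isnan(l_net)
                else:
                    assert l_net == pytest.approx(oracle, abs=1e-12)

    def test_network_metrics_matches_networkx(self):
        import networkx as nx

        g = rg.make_benchmark_graph("watts_strogatz", 40, k=4, p=0.2, seed=3)
        nxg = g.to_networkx()
        _, c_net = rg.clustering(g)
        assert c_net == pytest.approx(nx.average_clustering(nxg), abs=1e-12)
        _, l_net = rg.path_lengths(g)
        assert l_net == pytest.approx(
            nx.average_shortest_path_length(nxg), abs=1e-12
        )
        assert rg.global_efficiency(g) == pytest.approx(
            nx.global_efficiency(nxg), abs=1e-12
        )


class TestNto1Connectivity:
    def _matrix(self, r):
        return rg.ConnectivityMatrix(r, n_samples=200)

    def test_uncorrelated_network_is_uniform(self):
        r = np.eye(90)
        gamma, gamma_norm = n_to_1_connectivity(self._matrix(r))
        assert np.allclose(gamma, 89.0)
        assert np.allclose(gamma_norm, 1.0 / 90)

    def test_three_node_hand_value(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.6
        gamma, _ = n_to_1_connectivity(self._matrix(r))
        # d = 0.8, w = 1/0.64 = 1.5625; Gamma_1 = 1.5625 + 1.0
        assert gamma[0] == pytest.approx(2.5625)

    def test_gamma_increases_with_correlation_strength(self):
        vals = []
        for rho in (0.1, 0.4, 0.7):
            r = np.eye(3)
            r[0, 1] = r[1, 0] = rho
            gamma, _ = n_to_1_connectivity(self._matrix(r))
            vals.append(gamma[0])
        assert vals[0] < vals[1] < vals[2]

    def test_normalization_and_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 0.2, size=(20, 20))
        r = np.tanh(0.5 * (z + z.T))
        np.fill_diagonal(r, 1.0)
        gamma, gamma_norm = n_to_1_connectivity(self._matrix(r))
        assert gamma_norm.sum() == pytest.approx(1.0, abs=1e-12)
        perm = rng.permutation(20)
        gp, _ = n_to_1_connectivity(self._matrix(r[np.ix_(perm, perm)]))
        assert np.allclose(gp, gamma[perm], atol=1e-12)

    def test_perfect_correlation_rejected(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 1.0
        with pytest.raises(ValueError):
            n_to_1_connectivity(self._matrix(r))

    def test_exponential_kernel_available(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.6
        gamma, _ = n_to_1_connectivity(self._matrix(r), kernel="exponential")
        assert gamma[0] == pytest.approx(np.exp(-2 * 0.8) + np.exp(-2.0))


class TestDegreeDistributionFits:
    def test_exact_power_law_curve_recovered(self):
        # model-in-model recovery: feed an exact power-law cumulative curve
        from restgraph.metrics import _fit_one

        ks = np.arange(1.0, 30.0)
        curve = 1.5 * ks ** (0.4 - 1.0)
        fit = _fit_one("power_law", ks, curve)
        assert fit.r_square >= 0.999
        assert fit.parameters["tau"] == pytest.approx(0.4, abs=1e-4)

    def test_geometric_degrees_reject_pure_power_law(self):
        """Exponentially decaying degrees never look like a pure power law.

        The selected family is exponential or its truncated superset
        (whose fitted exponent then collapses toward tau = 1); the pure
        power law always loses.
        """
        rng = np.random.default_rng(42)
        taus = []
        for _ in range(20):
            k = rng.geometric(1.0 / 8.0, size=90)
            fits = {f.family: f for f in fit_degree_distributions(k)}
            best = min(fits.values(), key=lambda f: f.aic)
            assert best.family != "power_law"
            assert fits["exponential"].aic < fits["power_law"].aic
            taus.append(fits["truncated_power_law"].parameters["tau"])
        # the richer family imitates the exponential rather than adding
        # a genuine power-law component
        assert abs(np.mean(taus) - 1.0) < 0.15

    def test_truncated_power_law_degrees_recovered(self):
        rng = np.random.default_rng(7)
        support = np.arange(1, 90)
        pdf = support ** (0.5) * np.exp(-support / 15.0)
        pdf /= pdf.sum()
        wins = 0
        for _ in range(20):
            k = rng.choice(support, size=90, p=pdf)
            best = fit_degree_distributions(k)[0]
            if best.family == "truncated_power_law":
                wins += 1
        assert wins >= 18

    def test_parameter_counts_and_aic_ordering(self):
        rng = np.random.default_rng(9)
        fits = fit_degree_distributions(rng.integers(1, 30, size=90))
        counts = {f.family: len(f.parameters) for f in fits}
        assert counts == {
            "power_law": 2,
            "exponential": 2,
            "truncated_power_law": 3,
        }
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)

    def test_too_few_distinct_degrees_rejected(self):
        with pytest.raises(ValueError):
            fit_degree_distributions(np.array([3, 3, 3, 5, 5, 7, 9]))
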