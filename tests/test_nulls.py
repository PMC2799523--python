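import numpy as np
import pytest

import restgraph as rg
from restgraph.connectivity import ThresholdSpec
from restgraph.nulls import make_grid


class TestMaslovRewire:
    def test_degree_sequence_exactly_preserved(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            g = rg.make_benchmark_graph(
                "erdos_renyi", int(rng.integers(20, 80)), p=0.15, seed=seed
            )
            r = rg.maslov_rewire(g, seed=seed)
            assert np.array_equal(np.sort(r.degrees()), np.sort(g.degrees()))
            assert (r.degrees() == g.degrees()).all()  # per node, not just sorted
            assert not r.adjacency.diagonal().any()
            assert np.array_equal(r.adjacency, r.adjacency.T)

    def test_complete_graph_has_no_legal_swap(self):
        g = rg.make_benchmark_graph("complete", 4)
        r = rg.maslov_rewire(g, seed=1)
        assert np.array_equal(r.adjacency, g.adjacency)

    def test_rewiring_is_deterministic_per_seed(self):
        g = rg.make_benchmark_graph("watts_strogatz", 60, k=6, p=0.1, seed=2)
        a = rg.maslov_rewire(g, seed=33)
        b = rg.maslov_rewire(g, seed=33)
        c = rg.maslov_rewire(g, seed=34)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert not np.array_equal(a.adjacency, c.adjacency)

    def test_rewired_er_clustering_matches_er_expectation(self):
        # rewiring an ER graph should leave clustering near p
        n, p = 200, 0.05
        vals = []
        for seed in range(20):
            g = rg.make_benchmark_graph("erdos_renyi", n, p=p, seed=seed)
            r = rg.maslov_rewire(g, n_swaps=10 * g.n_edges, seed=seed + 100)
            _, c_net = rg.clustering(r)
            vals.append(c_net)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - p) < 3 * max(se, 1e-4)

    def test_rewiring_destroys_lattice_clustering(self):
        g = rg.make_benchmark_graph("ring_lattice", 100, k=6)
        _, c_lattice = rg.clustering(g)
        r = rg.maslov_rewire(g, seed=5)
        _, c_rand = rg.clustering(r)
        assert c_rand < c_lattice / 5


class TestNullEnsemble:
    def test_single_realization_of_swapfree_graph(self):
        g = rg.make_benchmark_graph("complete", 5)
        ens = rg.null_ensemble(g, n_random=1, seed=0)
        _, c_net = rg.clustering(g)
        assert ens.mean_C_rand == pytest.approx(c_net)

    def test_summary_is_reproducible(self):
        g = rg.make_benchmark_graph("watts_strogatz", 50, k=4, p=0.2, seed=1)
        a = rg.null_ensemble(g, n_random=10, seed=7)
        b = rg.null_ensemble(g, n_random=10, seed=7)
        assert a.mean_C_rand == b.mean_C_rand
        assert np.array_equal(a.L_rand, b.L_rand)

    def test_lattice_nulls_lose_clustering(self):
        g = rg.make_benchmark_graph("ring_lattice", 100, k=6)
        ens = rg.null_ensemble(g, n_random=20, seed=3)
        _, c_net = rg.clustering(g)
        assert ens.mean_C_rand * 5 < c_net

    def test_measure_selection_skips_unrequested(self):
        g = rg.make_benchmark_graph("erdos_renyi", 40, p=0.2, seed=4)
        ens = rg.null_ensemble(g, n_random=3, seed=1, measures=("efficiency",))
        assert np.isnan(ens.mean_C_rand)
        assert np.isfinite(ens.mean_Eglob_rand)


class TestSmallWorldIndices:
    def test_graph_against_itself_is_unity(self):
        g = rg.make_benchmark_graph("complete", 6)  # swap-free: nulls equal input
        ens = rg.null_ensemble(g, n_random=1, seed=0)
        idx = rg.small_world_indices(rg.network_metrics(g), ens)
        assert idx.gamma == pytest.approx(1.0)
        assert idx.lam == pytest.approx(1.0)
        assert idx.sigma == pytest.approx(1.0)

    def test_watts_strogatz_is_small_world(self):
        sigmas = []
        for seed in range(10):
            g = rg.make_benchmark_graph("watts_strogatz", 100, k=6, p=0.1, seed=seed)
            ens = rg.null_ensemble(
                g, n_random=20, seed=seed, measures=("clustering", "paths")
            )
            sigmas.append(rg.small_world_indices(rg.network_metrics(g), ens).sigma)
        assert min(sigmas) > 1.0

    def test_erdos_renyi_is_not_small_world(self):
        sigmas = []
        for seed in range(10):
            g = rg.make_benchmark_graph("erdos_renyi", 100, p=0.06, seed=seed)
            ens = rg.null_ensemble(
                g, n_random=20, seed=seed, measures=("clustering", "paths")
            )
            sigmas.append(rg.small_world_indices(rg.network_metrics(g), ens).sigma)
        assert 0.8 <= np.mean(sigmas) <= 1.2

    def test_zero_null_means_rejected(self):
        g = rg.make_benchmark_graph("path", 4)
        ens = rg.null_ensemble(g, n_random=1, seed=0)
        bad = rg.nulls.NullEnsembleSummary(
            1, 0.0, ens.mean_L_rand, 0.0, 0.0, ens.C_rand, ens.L_rand,
            ens.Eglob_rand, ens.Eloc_rand,
        )
        with pytest.raises(ValueError):
            rg.small_world_indices(rg.network_metrics(g), bad)


class TestTheoreticalRandom:
    def test_reference_values(self):
        c, l = rg.theoretical_random(9.0, 90)
        assert c == pytest.approx(0.1)
        assert l == pytest.approx(np.log(90) / np.log(9), abs=1e-12)

    def test_near_complete_boundary(self):
        c, _ = rg.theoretical_random(89.0, 90)
        assert c == pytest.approx(89 / 90)

    def test_closed_form_point(self):
        _, l = rg.theoretical_random(np.e, int(np.e**2) + 1)
        assert l == pytest.approx(np.log(int(np.e**2) + 1), abs=1e-12)
        with pytest.raises(ValueError):
            rg.theoretical_random(1.0, 90)


class TestGrids:
    def test_degree_grid_includes_endpoint_within_half_step(self):
        grid = make_grid(9.09, 34.8, 0.83)
        assert len(grid) == 32
        assert grid[0] == pytest.approx(9.09)
        assert grid[-1] == pytest.approx(34.82)

    def test_threshold_grid_step(self):
        grid = make_grid(0.005, 0.1, 0.005)
        assert np.allclose(np.diff(grid), 0.005)


class TestRegime:
    def _matrix(self, z, L=200):
        r = np.tanh(z)
        np.fill_diagonal(r, 1.0)
        return rg.ConnectivityMatrix(r, n_samples=L)

    def test_degenerate_flat_matrix(self):
        z = np.full((90, 90), 0.3)
        np.fill_diagonal(z, 0.0)
        result = rg.identify_regime(self._matrix(z), t_step=0.05, n_random=2, seed=0)
        # complete graph below 0.3, edgeless above: no rewiring freedom,
        # so the efficiency criteria cannot hold strictly
        assert result.is_empty
        assert (result.diagnostics["largest_component"] >= 1).all()

    def test_component_size_monotone_in_threshold(self, default_cohort_matrices):
        _, mats = default_cohort_matrices
        mean = rg.group_mean_zmatrix(mats["a"][:6])
        result = rg.identify_regime(mean, t_step=0.02, n_random=2, seed=1)
        comp = result.diagnostics["largest_component"].to_numpy()
        assert (np.diff(comp) <= 0).all()

    def test_in_regime_thresholds_are_connected_and_dense(self, default_cohort_matrices):
        _, mats = default_cohort_matrices
        mean = rg.group_mean_zmatrix(mats["b"])
        result = rg.identify_regime(mean, t_step=0.02, n_random=3, seed=2)
        d = result.diagnostics
        flagged = d[d["in_regime"]]
        if not result.is_empty:
            assert (flagged["largest_component"] == 90).all()
            assert (flagged["K"] >= 2 * np.log(90)).all()
            assert result.t_min <= result.t_max


class TestSweep:
    def _matrix(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 0.25, size=(n, n))
        z = 0.5 * (z + z.T)
        np.fill_diagonal(z, 0.0)
        r = np.tanh(z)
        np.fill_diagonal(r, 1.0)
        return rg.ConnectivityMatrix(r, n_samples=200, tag="m")

    def test_edge_count_non_increasing_in_threshold(self):
        frame = rg.sweep_metrics(
            [self._matrix()], make_grid(0.05, 0.4, 0.05), n_random=2, seed=0
        )
        assert (np.diff(frame["n_edges"]) <= 0).all()

    def test_single_point_matches_direct_calls(self):
        m = self._matrix(3)
        frame = rg.sweep_metrics([m], [0.2], n_random=3, seed=5, with_nulls=False)
        g = rg.binarize(m, ThresholdSpec("z_value", 0.2))
        met = rg.network_metrics(g)
        row = frame.iloc[0]
        assert row["K"] == pytest.approx(met.K)
        assert row["C_net"] == pytest.approx(met.C_net)
        assert row["E_glob"] == pytest.approx(met.E_glob)

    def test_degree_mode_hits_targets_from_below(self):
        m = self._matrix(4, n=40)
        grid = [5.0, 10.0, 15.0]
        frame = rg.sweep_metrics([m], grid, grid_mode="degree", n_random=2, seed=1, with_nulls=False)
        for target, got in zip(grid, frame["K"]):
            assert got <= target + 1e-9
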