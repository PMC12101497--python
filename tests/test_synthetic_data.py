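import numpy as np
import pytest

from wmcpm.behavior_scoring import cowan_k
from wmcpm.connectome import EdgeIndexMap
from wmcpm.synthetic_data import (
    GroundTruth,
    InvalidConfigurationError,
    TrialGenerativeParams,
    embed_behavior,
    make_atlas,
    make_ground_truth,
    simulate_change_detection_trials,
    simulate_dataset,
    simulate_timeseries,
)


class TestMakeAtlas:
    def test_default_268_nodes_10_networks(self):
        atlas = make_atlas(268)
        assert atlas.n_nodes == 268
        assert atlas.n_networks == 10
        assert sum(atlas.sizes().values()) == 268

    def test_single_network(self):
        atlas = make_atlas(20, [20], ["all"])
        assert set(atlas.labels) == {"all"}

    def test_exact_sizes(self):
        atlas = make_atlas(20, [5, 15], ["a", "b"], seed=3)
        assert atlas.sizes() == {"a": 5, "b": 15}

    def test_size_mismatch(self):
        with pytest.raises(InvalidConfigurationError):
            make_atlas(20, [5, 14], ["a", "b"])
        with pytest.raises(InvalidConfigurationError):
            make_atlas(20, [5, 15], ["a"])

    def test_seeded_determinism(self):
        a1 = make_atlas(30, [10, 20], ["a", "b"], seed=5)
        a2 = make_atlas(30, [10, 20], ["a", "b"], seed=5)
        assert np.array_equal(a1.labels, a2.labels)


class TestSimulateTimeseries:
    def test_within_exceeds_between(self):
        atlas = make_atlas(20, [10, 10], ["a", "b"])
        cohort = simulate_timeseries(20, atlas, n_timepoints=500,
                                     rho_within=0.5, rho_between=0.1, seed=2)
        same = atlas.network_index()[:, None] == atlas.network_index()[None, :]
        off = ~np.eye(20, dtype=bool)
        within, between = [], []
        for ts in cohort:
            r = np.corrcoef(ts.data)
            within.append(r[same & off].mean())
            between.append(r[~same].mean())
        assert np.mean(within) > np.mean(between)
        assert np.mean(within) == pytest.approx(0.5, abs=0.1)
        assert np.mean(between) == pytest.approx(0.1, abs=0.1)

    def test_independence_case(self):
        atlas = make_atlas(10, [5, 5], ["a", "b"])
        cohort = simulate_timeseries(20, atlas, n_timepoints=400,
                                     rho_within=0.0, rho_between=0.0, seed=7)
        off = ~np.eye(10, dtype=bool)
        mean_r = np.mean([np.corrcoef(ts.data)[off].mean() for ts in cohort])
        # SE of a mean of ~45*20 weakly dependent r's at T=400 is well under 0.01
        assert abs(mean_r) < 3 * 0.01

    def test_shape_contract(self):
        atlas = make_atlas(12, [6, 6], ["a", "b"])
        cohort = simulate_timeseries(3, atlas, n_timepoints=50, seed=0)
        assert len(cohort) == 3
        assert all(ts.data.shape == (12, 50) for ts in cohort)

    def test_seeded_determinism(self):
        atlas = make_atlas(8, [4, 4], ["a", "b"])
        c1 = simulate_timeseries(2, atlas, 30, seed=9)
        c2 = simulate_timeseries(2, atlas, 30, seed=9)
        for t1, t2 in zip(c1, c2):
            assert np.array_equal(t1.data, t2.data)

    def test_invalid_correlations(self):
        atlas = make_atlas(8, [4, 4], ["a", "b"])
        with pytest.raises(InvalidConfigurationError):
            simulate_timeseries(2, atlas, 30, rho_within=0.1, rho_between=0.5)


class TestEmbedBehavior:
    def test_noiseless_single_edge_identity(self, rng):
        X = rng.standard_normal((10, 45))
        truth = GroundTruth([7], [1.0], 0.0, "net", seed=0)
        assert np.array_equal(embed_behavior(X, truth), X[:, 7])

    def test_noiseless_linear_combination(self, rng):
        X = rng.standard_normal((15, 45))
        truth = GroundTruth([3, 9], [2.0, -1.0], 0.0, "net", seed=0)
        assert np.allclose(embed_behavior(X, truth), 2 * X[:, 3] - X[:, 9])

    def test_snr2_correlation_with_noiseless_predictor(self, rng):
        X = rng.standard_normal((60, 100))
        idx, w = np.array([1, 5, 9]), np.array([1.0, -0.5, 2.0])
        signal = X[:, idx] @ w
        noise_sd = signal.std() / 2.0  # SNR = 2
        truth = GroundTruth(idx, w, noise_sd, "net", seed=4)
        y = embed_behavior(X, truth)
        r = np.corrcoef(y, signal)[0, 1]
        assert r >= 0.8

    def test_index_out_of_range(self, rng):
        X = rng.standard_normal((5, 10))
        truth = GroundTruth([10], [1.0], 0.0, "net", seed=0)
        with pytest.raises(InvalidConfigurationError):
            embed_behavior(X, truth)

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((8, 20))
        truth = GroundTruth([2], [1.0], 0.5, "net", seed=123)
        assert np.array_equal(embed_behavior(X, truth), embed_behavior(X, truth))


class TestChangeDetectionTrials:
    def test_no_memory_case(self):
        p = TrialGenerativeParams(true_K=0, S=4, g=0.3,
                                  n_trials_change=10_000, n_trials_nochange=10_000)
        tc = simulate_change_detection_trials(p, seed=0)
        # H and F share the same expectation g; K estimate ~ 0
        assert abs(tc.cowan_k()) < 0.1

    @pytest.mark.parametrize("true_K,S,expected", [(4, 4, 4.0), (6, 4, 4.0)])
    def test_ceiling_at_set_size(self, true_K, S, expected):
        """d = min(K/S, 1): expected Cowan estimate is min(K, S), exactly at d=1."""
        p = TrialGenerativeParams(true_K=true_K, S=S, g=0.25,
                                  n_trials_change=2000, n_trials_nochange=2000)
        tc = simulate_change_detection_trials(p, seed=1)
        # d = 1: hits are certain, false alarms impossible -> estimate exact
        assert tc.hits == 2000 and tc.false_alarms == 0
        assert tc.cowan_k() == expected

    def test_recovery_chain(self):
        """Generate at true_K in {1,2,3}, score with cowan_k: bias < 0.1.

        A single 2,000-trial draw has Monte-Carlo error ~0.09 on the K
        estimate, so bias is measured as the mean error over seeded
        replicates (MC error of the mean ~0.015).
        """
        for true_K in (1, 2, 3):
            p = TrialGenerativeParams(true_K=true_K, S=4, g=0.4,
                                      n_trials_change=1000, n_trials_nochange=1000)
            est = [
                simulate_change_detection_trials(p, seed=1000 * true_K + r).cowan_k()
                for r in range(30)
            ]
            assert np.mean(est) == pytest.approx(true_K, abs=0.1)

    def test_invalid_params(self):
        with pytest.raises(InvalidConfigurationError):
            TrialGenerativeParams(true_K=-1, S=4, g=0.2,
                                  n_trials_change=10, n_trials_nochange=10)
        with pytest.raises(InvalidConfigurationError):
            TrialGenerativeParams(true_K=2, S=4, g=1.2,
                                  n_trials_change=10, n_trials_nochange=10)


class TestGroundTruthPlacement:
    def test_both_endpoints_inside_target(self, toy_atlas, toy_emap):
        truth = make_ground_truth(toy_atlas, toy_emap, n_signal_edges=3,
                                  target_network="B", seed=0)
        b_nodes = set(toy_atlas.nodes_of("B").tolist())
        for e in truth.signal_edge_indices:
            i, j = toy_emap.endpoints(int(e))
            assert i in b_nodes and j in b_nodes

    def test_either_endpoint_mode(self, toy_atlas, toy_emap):
        truth = make_ground_truth(toy_atlas, toy_emap, n_signal_edges=10,
                                  target_network="B", seed=0,
                                  both_endpoints=False)
        b_nodes = set(toy_atlas.nodes_of("B").tolist())
        assert any(
            (toy_emap.endpoints(int(e))[0] in b_nodes)
            != (toy_emap.endpoints(int(e))[1] in b_nodes)
            for e in truth.signal_edge_indices
        )

    def test_too_many_edges_requested(self, toy_atlas, toy_emap):
        with pytest.raises(InvalidConfigurationError):
            make_ground_truth(toy_atlas, toy_emap, n_signal_edges=7,
                              target_network="A", seed=0)  # C(3,2)=3 < 7


class TestSimulateDataset:
    def test_noiseless_multiple_correlation_is_one(self):
        ds = simulate_dataset(n_subjects=25, n_nodes=20,
                              network_sizes=[10, 10], network_names=["a", "b"],
                              n_timepoints=80, n_signal_edges=4,
                              target_network="b", snr=None, seed=3)
        signal = ds.X[:, ds.truth.signal_edge_indices] @ ds.truth.signal_weights
        assert np.corrcoef(ds.y, signal)[0, 1] == pytest.approx(1.0)

    def test_snr_calibration(self, small_cohort):
        ds = small_cohort
        signal = ds.X[:, ds.truth.signal_edge_indices] @ ds.truth.signal_weights
        assert signal.std() / ds.truth.noise_sd == pytest.approx(2.0, rel=1e-6)

    def test_bit_identical_reruns(self):
        kw = dict(n_subjects=6, n_nodes=12, network_sizes=[6, 6],
                  network_names=["a", "b"], n_timepoints=40,
                  n_signal_edges=2, target_network="b", seed=5)
        d1, d2 = simulate_dataset(**kw), simulate_dataset(**kw)
        assert np.array_equal(d1.X, d2.X)
        assert np.array_equal(d1.y, d2.y)
        assert np.array_equal(d1.truth.signal_edge_indices,
                              d2.truth.signal_edge_indices)

    def test_edge_map_matches_node_count(self, small_cohort):
        assert isinstance(small_cohort.emap, EdgeIndexMap)
        assert small_cohort.X.shape == (30, small_cohort.emap.n_edges)
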