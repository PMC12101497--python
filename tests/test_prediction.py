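import numpy as np
import pytest

from wmcpm.prediction import (
    PredictionConfig,
    fdr_correct,
    feature_count,
    loocv_predict,
    permutation_test,
    predict_component,
    rank_features_by_svr,
)


class TestFeatureCount:
    @pytest.mark.parametrize(
        "n,pm,expected",
        [(35778, 1, 35), (35778, 9, 322), (1000, 5, 5), (35778, 3, 107),
         (35778, 5, 178), (35778, 7, 250), (100, 1, 1)],
    )
    def test_floor_minimum_one(self, n, pm, expected):
        assert feature_count(n, pm) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            feature_count(0, 1)
        with pytest.raises(ValueError):
            feature_count(100, 0)


class TestRanking:
    def test_collinear_feature_ranked_first(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 30))
        y = 2.0 * X[:, 17]  # feature 17 perfectly collinear with y
        order, w = rank_features_by_svr(X, y)
        assert order[0] == 17
        assert np.abs(w)[17] == np.abs(w).max()

    def test_constant_target_degenerate(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 6))
        with pytest.warns(UserWarning, match="degenerate"):
            order, w = rank_features_by_svr(X, np.zeros(10))
        assert np.allclose(w, 0)
        assert np.array_equal(order, np.arange(6))

    def test_duplicated_columns_tie_deterministically(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 8))
        X[:, 5] = X[:, 2]  # duplicate column -> identical |weight|
        y = X[:, 2] + 0.1 * rng.standard_normal(30)
        order, w = rank_features_by_svr(X, y)
        assert w[2] == pytest.approx(w[5], abs=1e-12)
        # lower index wins the tie
        assert list(order).index(2) < list(order).index(5)

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            rank_features_by_svr(np.zeros((2, 4)), np.zeros(2))


class TestLoocv:
    def test_noiseless_signal_recovered(self):
        """A noiseless planted signal on 10 edges is recovered with high r.

        Recovery is high but not perfect even without noise: each fold's
        ranking fit sees only n-1 subjects against >1000 candidate edges and
        can miss weakly weighted signal edges. The frozen bound comes from
        the seeded run itself; the oracle-ceiling check below bounds it from
        above.
        """
        from wmcpm.synthetic_data import simulate_dataset

        ds = simulate_dataset(n_subjects=120, n_nodes=50,
                              network_sizes=[25, 25], network_names=["a", "b"],
                              n_timepoints=150, n_signal_edges=10,
                              target_network="b", snr=None, seed=21)
        res = loocv_predict(ds.X, ds.y, per_mille=9)
        assert res.n_features == feature_count(ds.X.shape[1], 9)
        assert res.r_observed >= 0.9

    def test_never_beats_oracle_given_true_edges(self):
        """LOOCV r at any threshold cannot exceed the true-signal-edge oracle."""
        from wmcpm.synthetic_data import simulate_dataset

        ds = simulate_dataset(n_subjects=40, n_nodes=20,
                              network_sizes=[10, 10], network_names=["a", "b"],
                              n_timepoints=100, n_signal_edges=4,
                              target_network="b", snr=None, seed=13)
        oracle = loocv_predict(ds.X[:, ds.truth.signal_edge_indices], ds.y,
                               per_mille=1000)  # keeps every true edge
        # near 1 but not exact: C=1 regularization and the eps-tube leave a
        # small residual even on noiseless data
        assert oracle.r_observed >= 0.98
        results = loocv_predict(ds.X, ds.y,
                                config=PredictionConfig(per_mille_thresholds=(1, 5, 9)))
        for res in results.values():
            assert res.r_observed <= oracle.r_observed + 1e-6

    def test_minimal_run_shape(self, rng):
        X = rng.standard_normal((4, 12))
        y = rng.standard_normal(4)
        res = loocv_predict(X, y, per_mille=9)
        assert len(res.folds) == 4
        assert sorted(fm.held_out_subject for fm in res.folds) == [0, 1, 2, 3]

    def test_selection_size_matches_threshold(self, small_cohort):
        res = loocv_predict(small_cohort.X, small_cohort.y, per_mille=9)
        k = feature_count(small_cohort.X.shape[1], 9)
        assert all(len(fm.selected_edge_indices) == k for fm in res.folds)

    def test_no_leakage_from_held_out_subject(self, small_cohort):
        """Perturbing a held-out score changes nothing about that fold."""
        X, y = small_cohort.X, small_cohort.y.copy()
        res1 = loocv_predict(X, y, per_mille=9)
        y2 = y.copy()
        y2[4] += 100.0  # wild perturbation of subject 4's score
        res2 = loocv_predict(X, y2, per_mille=9)
        f1 = next(f for f in res1.folds if f.held_out_subject == 4)
        f2 = next(f for f in res2.folds if f.held_out_subject == 4)
        assert np.array_equal(f1.selected_edge_indices, f2.selected_edge_indices)
        assert f1.prediction == f2.prediction

    def test_deterministic_across_runs(self, small_cohort):
        r1 = loocv_predict(small_cohort.X, small_cohort.y, per_mille=5)
        r2 = loocv_predict(small_cohort.X, small_cohort.y, per_mille=5)
        assert r1.r_observed == r2.r_observed
        for f1, f2 in zip(r1.folds, r2.folds):
            assert f1.prediction == f2.prediction
            assert np.array_equal(f1.selected_edge_indices, f2.selected_edge_indices)

    def test_multi_threshold_consistent_with_single(self, small_cohort):
        cfg = PredictionConfig(per_mille_thresholds=(1, 9))
        multi = loocv_predict(small_cohort.X, small_cohort.y, config=cfg)
        single = loocv_predict(small_cohort.X, small_cohort.y, per_mille=1,
                               config=cfg)
        assert multi[1].r_observed == pytest.approx(single.r_observed, abs=1e-9)


class TestPermutation:
    def test_single_permutation_support(self, small_cohort):
        cfg = PredictionConfig(n_permutations=1, seed=0)
        res = permutation_test(small_cohort.X, small_cohort.y, 9, cfg)
        assert res.p_permutation in (0.0, 1.0)
        assert res.p_permutation_unbiased in (0.5, 1.0)

    def test_observed_above_all_permuted_gives_zero(self):
        """Strong noiseless signal: observed r exceeds every permuted r."""
        from wmcpm.synthetic_data import simulate_dataset

        ds = simulate_dataset(n_subjects=40, n_nodes=20,
                              network_sizes=[10, 10], network_names=["a", "b"],
                              n_timepoints=100, n_signal_edges=3,
                              target_network="b", snr=None, seed=2)
        cfg = PredictionConfig(n_permutations=25, seed=5)
        res = permutation_test(ds.X, ds.y, 9, cfg)
        assert res.p_permutation == 0.0
        assert res.p_permutation_unbiased == pytest.approx(1 / 26)

    def test_null_distribution_reproducible(self, small_cohort):
        cfg = PredictionConfig(n_permutations=5, seed=33)
        r1 = permutation_test(small_cohort.X, small_cohort.y, 9, cfg)
        r2 = permutation_test(small_cohort.X, small_cohort.y, 9, cfg)
        assert np.array_equal(r1.null_r, r2.null_r)


class TestFdr:
    def test_uniform_small_p(self):
        flags, _ = fdr_correct([0.001] * 15)
        assert flags.all()

    def test_hand_applied_bh_thresholds(self):
        # BH cutoffs at m=3, alpha=.05: 0.0167, 0.0333, 0.05
        flags, _ = fdr_correct([0.01, 0.02, 0.20])
        assert list(flags) == [True, True, False]

    def test_single_p(self):
        flags, _ = fdr_correct([0.049])
        assert flags[0]

    def test_flags_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 20))
        flags, _ = fdr_correct(p)
        # once a larger p is rejected, every smaller p is too
        assert all(flags[i] or not flags[i + 1] for i in range(19))

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestPredictComponent:
    def test_full_analysis_on_small_cohort(self, small_cohort):
        cfg = PredictionConfig(per_mille_thresholds=(1, 9),
                               n_permutations=10, seed=3)
        results = predict_component(small_cohort.X, small_cohort.y, cfg)
        for t, res in results.items():
            assert -1 <= res.r_observed <= 1
            assert 0 <= res.p_permutation <= 1
            assert res.q_significant is not None
            assert len(res.null_r) == 10
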