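import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from septrial import (FeatureSpec, Recording, SEPTemplate, SimConfig,
                      SpatialFilterSpec, bandpass, build_balanced_epochs,
                      calibrate_decoder, crossvalidate, epoch,
                      estimate_n70_latency, extract_features, generate_run,
                      optimize_lambda, rsquared_map, select_electrodes,
                      spatial_filter, train_rlda)
from septrial.calibration import LAMBDA_GRID, MULTIVARIATE_SET, RSquaredMap
from septrial.core_io import EpochSet
from septrial.stats import auc
from conftest import CLEAN, noiseless_config, noiseless_template


def _ramp_recording(n=6000, events=(3000,)):
    data = np.arange(n, dtype=float)[None, :]
    return Recording(data, 300.0, ("Cz",), events=list(events))


class TestEpoching:
    def test_window_is_17_samples_at_300hz(self):
        rec = _ramp_recording()
        ep = epoch(rec, rec.events, (-25.0, 25.0), "stimulus+latency", 90.0)
        assert ep.data.shape == (1, 1, 17)

    def test_sep_epoch_spans_expected_samples(self):
        # event 3000 + 27 (90 ms) +/- 8 -> samples 3019..3035
        rec = _ramp_recording()
        ep = epoch(rec, rec.events, (-25.0, 25.0), "stimulus+latency", 90.0)
        assert np.array_equal(ep.data[0, 0], np.arange(3019, 3036))

    def test_rest_epoch_ends_at_stimulus_onset(self):
        rec = _ramp_recording()
        ep = epoch(rec, rec.events, (-50.0, 0.0), "pre-stimulus")
        assert ep.data[0, 0][-1] == 3000
        assert len(ep.data[0, 0]) == 17

    def test_balanced_set_has_one_pair_per_event(self, montage):
        rec, _ = generate_run(
            SimConfig(seed=0, n_trials=75, stim_freq_hz=2.0, **CLEAN),
            montage)
        epochs = build_balanced_epochs(bandpass(rec), FeatureSpec(("Cz",),
                                                                  90.0))
        assert epochs.n_trials == 150
        assert (epochs.labels == 1).sum() == (epochs.labels == -1).sum()

    def test_edge_events_dropped(self):
        rec = _ramp_recording(events=(5, 3000, 5995))
        # event 5995 + 27 +/- 8 runs past the end -> dropped
        sep = epoch(rec, rec.events, (-25.0, 25.0), "stimulus+latency", 90.0)
        assert sep.n_trials == 2
        # rest epoch of event 5 starts before sample 0 -> dropped
        rest = epoch(rec, rec.events, (-50.0, 0.0), "pre-stimulus")
        assert rest.n_trials == 2


class TestRSquared:
    def _epochs_from_values(self, values, labels):
        data = np.zeros((len(values), 1, 17))
        data[:, 0, 8] = values          # center sample carries the feature
        return EpochSet(data, (-25.0, 25.0), np.asarray(labels),
                        "stimulus+latency", ("Cz",))

    def test_known_correlation_gives_r2_08(self):
        values = [0, 1, 2, 3] * 2
        labels = [-1, -1, 1, 1] * 2
        rsq = rsquared_map(self._epochs_from_values(values, labels))
        assert rsq.at("Cz") == pytest.approx(0.8, abs=1e-12)

    def test_values_equal_labels_give_r2_1(self):
        labels = [-1, 1] * 4
        rsq = rsquared_map(self._epochs_from_values(labels, labels))
        assert rsq.at("Cz") == pytest.approx(1.0)

    def test_zero_variance_feature_gives_r2_0_p_1(self):
        rsq = rsquared_map(self._epochs_from_values([2.0] * 8,
                                                    [-1, 1] * 4))
        assert rsq.at("Cz") == 0.0
        assert rsq.p[0] == 1.0

    def test_null_mean_r2_and_type_I_rate(self):
        # Monte-Carlo null oracle: label-independent Gaussian features
        rng = np.random.default_rng(0)
        n = 150
        labels = np.array([-1, 1] * (n // 2))
        r2s, rejections = [], 0
        for _ in range(1000):
            values = rng.standard_normal(n)
            rsq = rsquared_map(self._epochs_from_values(values, labels))
            r2s.append(rsq.at("Cz"))
            rejections += rsq.p[0] < 0.05
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=1e-3)
        assert 0.03 < rejections / 1000 < 0.07

    def test_bonferroni_column(self, montage, short_run):
        rec, _ = short_run
        epochs = build_balanced_epochs(bandpass(rec),
                                       FeatureSpec(("Cz",), 90.0))
        rsq = rsquared_map(epochs)
        m = len(rsq.electrodes)
        expected = -np.log10(np.minimum(1.0, rsq.p * m))
        assert np.allclose(rsq.neglogp_bonf, expected)


class TestLatencyEstimation:
    def test_noiseless_run_recovers_90ms_exactly(self, montage):
        rec, _ = generate_run(noiseless_config(n_trials=20), montage,
                              noiseless_template())
        sp = spatial_filter(bandpass(rec), SpatialFilterSpec("laplacian"),
                            montage)
        assert estimate_n70_latency(sp) == pytest.approx(90.0)

    def test_pure_noise_raises_not_detected(self, montage):
        rec, _ = generate_run(
            SimConfig(seed=9, n_trials=30, stim_freq_hz=1.0, **CLEAN),
            montage, SEPTemplate().scaled(0.0))
        sp = spatial_filter(bandpass(rec), SpatialFilterSpec("laplacian"),
                            montage)
        with pytest.raises(ValueError, match="N70 not detected"):
            estimate_n70_latency(sp)

    def test_p40_mode_recovers_positive_peak(self, montage):
        rec, _ = generate_run(noiseless_config(n_trials=20), montage,
                              noiseless_template())
        sp = spatial_filter(bandpass(rec), SpatialFilterSpec("laplacian"),
                            montage)
        lat = estimate_n70_latency(sp, component="P40")
        assert lat == pytest.approx(40.0, abs=3.4)  # nearest sample

    def test_requires_minimum_trials(self, montage):
        rec, _ = generate_run(noiseless_config(n_trials=5), montage,
                              noiseless_template())
        with pytest.raises(ValueError, match="trials"):
            estimate_n70_latency(rec)


class TestElectrodeSelection:
    def _map(self, r2):
        r2 = np.asarray(r2, dtype=float)
        from septrial.core_io import CHANNELS_1020
        return RSquaredMap(CHANNELS_1020, r2, np.full(19, 0.5),
                           np.zeros(19), 100)

    def test_multivariate_is_fixed_centroparietal_set(self):
        r2 = np.zeros(19)
        assert select_electrodes(self._map(r2), "multivariate") \
            == MULTIVARIATE_SET

    def test_univariate_picks_argmax(self):
        r2 = np.zeros(19)
        r2[2] = 0.5                     # Fz
        assert select_electrodes(self._map(r2), "univariate") == ("Fz",)

    def test_all_equal_ties_resolve_to_cz(self):
        assert select_electrodes(self._map(np.full(19, 0.3)),
                                 "univariate") == ("Cz",)

    def test_bad_flagged_selection_errors_with_alternatives(self):
        r2 = np.zeros(19)
        r2[7] = 0.9                     # Cz
        with pytest.raises(ValueError, match="alternatives"):
            select_electrodes(self._map(r2), "univariate", bad=("Cz",))


class TestFeatures:
    def test_constant_epoch_rms_is_abs(self):
        data = np.full((3, 1, 17), -4.0)
        ep = EpochSet(data, (-25.0, 25.0), np.array([1, 1, -1]),
                      "stimulus+latency", ("Cz",))
        X, y = extract_features(ep, ("Cz",))
        assert np.allclose(X, 4.0)

    def test_unit_sine_rms_is_inv_sqrt2(self):
        t = np.arange(300) / 300.0
        data = np.sin(2 * np.pi * 10 * t)[None, None, :]
        ep = EpochSet(data, (0, 1000), np.array([1]), "stimulus+latency",
                      ("Cz",))
        X, _ = extract_features(ep, ("Cz",))
        assert X[0, 0] == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 3, (4, 2, 17))
        ep = EpochSet(data, (-25.0, 25.0), np.array([1, 1, -1, -1]),
                      "stimulus+latency", ("Cz", "Fz"))
        X, _ = extract_features(ep, ("Fz", "Cz"))
        for trial in range(4):
            for col, ch in enumerate((1, 0)):
                acc = 0.0
                for v in data[trial, ch]:
                    acc += v * v
                assert abs(X[trial, col] - np.sqrt(acc / 17)) < 1e-12


class TestRLDA:
    def test_lambda_1_weight_is_proportional_to_mean_difference(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal([0, 0], [1, 5], (30, 2)),
                       rng.normal([2, 1], [1, 5], (30, 2))])
        y = np.array([-1] * 30 + [1] * 30)
        model = train_rlda(X, y, 1.0)
        mu_diff = X[y == 1].mean(axis=0) - X[y == -1].mean(axis=0)
        cos = model.w @ mu_diff / (np.linalg.norm(model.w)
                                   * np.linalg.norm(mu_diff))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_univariate_midpoint_boundary(self):
        # class means 2 and 0 with pooled variance 1 -> w=2, b=-2
        a = 1 / np.sqrt(2)
        X = np.array([[2 - a], [2 + a], [-a], [a]])
        y = np.array([1, 1, -1, -1])
        model = train_rlda(X, y, 0.0)
        assert model.w[0] == pytest.approx(2.0, abs=1e-12)
        assert model.b == pytest.approx(-2.0, abs=1e-12)
        assert model.score(np.array([[1.0]]))[0] == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_weights_match_direct_inverse_oracle(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal([0, 0], 1, (40, 2)) @
                       np.array([[1.0, 0.6], [0.0, 0.8]]),
                       rng.normal([1.5, -0.5], 1, (40, 2))])
        y = np.array([-1] * 40 + [1] * 40)
        for lam in (0.0, 0.1, 0.5):
            model = train_rlda(X, y, lam)
            # independent oracle: pooled covariance by hand + explicit inverse
            pos, neg = X[y == 1], X[y == -1]
            mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
            cov = np.zeros((2, 2))
            for grp, mu in ((pos, mu_p), (neg, mu_n)):
                for row in grp:
                    d = (row - mu)[:, None]
                    cov += d @ d.T
            cov /= len(X) - 2
            reg = (1 - lam) * cov + lam * np.trace(cov) / 2 * np.eye(2)
            w = np.linalg.inv(reg) @ (mu_p - mu_n)
            assert np.allclose(model.w, w, atol=1e-10)

    def test_collinear_features_at_lambda_0_raise(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        y = np.array([1, 1, -1, -1])
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            train_rlda(X, y, 0.0)

    def test_matches_sklearn_shrinkage_lda_direction(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis").LinearDiscriminantAnalysis
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (50, 6)),
                       rng.normal(0.8, 1.3, (50, 6))])
        y = np.array([-1] * 50 + [1] * 50)
        for lam in (0.05, 0.3):
            mine = train_rlda(X, y, lam)
            ref = sklearn_lda(solver="lsqr", shrinkage=lam).fit(X, y)
            cos = mine.w @ ref.coef_[0] / (np.linalg.norm(mine.w)
                                           * np.linalg.norm(ref.coef_[0]))
            assert cos == pytest.approx(1.0, abs=1e-6)


class TestLambdaOptimization:
    def _data(self, seed=0, n=100, d=6, sep=1.0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n // 2, d)),
                       rng.normal(sep, 1, (n // 2, d))])
        y = np.array([-1] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_single_element_grid_returned(self):
        X, y = self._data()
        assert optimize_lambda(X, y, grid=(0.2,)) == 0.2

    def test_deterministic_for_fixed_seed(self):
        X, y = self._data()
        assert optimize_lambda(X, y, rng=5) == optimize_lambda(X, y, rng=5)

    def test_selected_lambda_maximizes_holdout_auc(self):
        X, y = self._data(seed=3)
        seed = 11
        lam_star = optimize_lambda(X, y, rng=seed)
        # exhaustive re-evaluation on the identical stratified split
        Xt, Xh, yt, yh = train_test_split(X, y, test_size=0.2, stratify=y,
                                          random_state=seed)
        best = max(auc(train_rlda(Xt, yt, lam).score(Xh), yh)
                   for lam in LAMBDA_GRID)
        got = auc(train_rlda(Xt, yt, lam_star).score(Xh), yh)
        assert got == pytest.approx(best, abs=1e-12)

    def test_empty_grid_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            optimize_lambda(X, y, grid=())


class TestCrossValidation:
    def test_perfect_separation_gives_median_1(self):
        X = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
        y = np.array([-1] * 20 + [1] * 20)
        bundle = crossvalidate(X, y, rng=0)
        assert bundle.median_auc == 1.0
        assert len(bundle.cv_aucs) == 5

    def test_permuted_labels_center_at_half(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (20, 2)),
                       rng.normal(1.5, 1, (20, 2))])
        aucs = []
        for rep in range(200):
            y = rng.permutation([-1] * 20 + [1] * 20)
            aucs.append(crossvalidate(X, y, rng=rep).median_auc)
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (30, 3)),
                       rng.normal(0.7, 1, (30, 3))])
        y = np.array([-1] * 30 + [1] * 30)
        a = crossvalidate(X, y, rng=7)
        b = crossvalidate(1000.0 * X, y, rng=7)
        assert np.allclose(a.cv_aucs, b.cv_aucs)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(np.zeros((6, 1)), np.array([1, -1] * 3), k=5)


class TestCalibrateDecoder:
    def test_univariate_calibration_recovers_simulated_truth(self, montage):
        rec, _ = generate_run(SimConfig(seed=2, stim_freq_hz=1.0), montage)
        res = calibrate_decoder(rec, montage, seed=0)
        assert res.model.feature_spec.electrodes == ("Cz",)
        assert abs(res.latency_ms - 90.0) <= 5.0
        assert res.bundle.median_auc > 0.6
        assert len(res.model.w) == 1

    def test_multivariate_uses_six_electrodes(self, montage):
        rec, _ = generate_run(SimConfig(seed=2, stim_freq_hz=1.0), montage)
        res = calibrate_decoder(rec, montage, mode="multivariate", seed=0)
        assert res.model.feature_spec.electrodes == MULTIVARIATE_SET
        assert len(res.model.w) == 6

    def test_label_symmetry_of_auc(self):
        scores = np.array([0.1, 0.9, 0.4, 0.8, 0.2, 0.7])
        y = np.array([-1, 1, -1, 1, -1, 1])
        assert auc(scores, y) == pytest.approx(1.0 - auc(-scores, y))
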