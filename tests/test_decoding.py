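"""Mahalanobis tuning-curve decoding: building blocks, oracles, invariants."""

import numpy as np
import pytest

from wmstates import decoding as dec
from wmstates import synthetic as syn


def _make_epochs(data, time_ms=None):
    time_ms = syn.default_time_axis() if time_ms is None else time_ms
    labels = [f"CH{i:02d}" for i in range(data.shape[1])]
    return syn.EpochsArray(data, time_ms, labels)


# --------------------------------------------------------------------------
# Noise residuals
# --------------------------------------------------------------------------

class TestNoiseResiduals:
    def test_identical_trials_give_zero_residuals(self):
        t = np.arange(0, 2000, 4.0)
        data = np.tile(np.random.default_rng(0).standard_normal((1, 3, len(t))),
                       (6, 1, 1))
        ep = _make_epochs(data, t)
        resid = dec.compute_noise_residuals(ep, np.zeros(6))
        assert np.allclose(resid, 0.0)

    def test_two_trial_antisymmetric_pair(self):
        t = np.arange(0, 2000, 4.0)
        p = np.random.default_rng(1).standard_normal(3)
        data = np.stack([np.tile(p[:, None], (1, len(t))),
                         np.tile(-p[:, None], (1, len(t)))])
        resid = dec.compute_noise_residuals(_make_epochs(data, t), np.zeros(2))
        assert np.allclose(resid[0], p) and np.allclose(resid[1], -p)

    def test_matches_brute_force_demeaning_oracle(self, rng):
        t = np.arange(-200, 2604, 4.0)
        data = rng.standard_normal((20, 4, len(t)))
        labels = rng.integers(0, 3, size=20)
        ep = _make_epochs(data, t)
        resid = dec.compute_noise_residuals(ep, labels)
        # oracle: residual per trial/timepoint, then window average
        m = (t >= 0) & (t <= 1800)
        oracle = np.empty((20, 4))
        for i in range(20):
            same = labels == labels[i]
            r = data[i] - data[same].mean(axis=0)
            oracle[i] = r[:, m].mean(axis=1)
        assert np.allclose(resid, oracle, atol=1e-12)

    def test_single_trial_orientation_warns(self, rng):
        t = np.arange(0, 2000, 4.0)
        ep = _make_epochs(rng.standard_normal((3, 2, len(t))), t)
        with pytest.warns(UserWarning, match="single trial"):
            resid = dec.compute_noise_residuals(ep, np.array([0, 0, 1]))
        assert np.allclose(resid[2], 0.0)


# --------------------------------------------------------------------------
# Ledoit-Wolf shrinkage covariance
# --------------------------------------------------------------------------

def _ledoit_wolf_oracle(X):
    """Literal transcription of the Ledoit-Wolf (2004) formulas."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    mu = np.trace(S) / p
    delta2 = ((S - mu * np.eye(p)) ** 2).sum() / p
    beta2_bar = sum(((np.outer(x, x) - S) ** 2).sum() for x in Xc) / (n ** 2 * p)
    beta2 = min(beta2_bar, delta2)
    rho = beta2 / delta2 if delta2 > 0 else 1.0
    return rho * mu * np.eye(p) + (1 - rho) * S, rho


class TestShrinkageCovariance:
    def test_matches_literal_formula_oracle(self, rng):
        X = rng.standard_normal((5, 3))
        est = dec.shrinkage_covariance(X)
        oracle_cov, oracle_rho = _ledoit_wolf_oracle(X)
        assert est.shrinkage_intensity == pytest.approx(oracle_rho, abs=1e-10)
        assert np.allclose(est.matrix, oracle_cov, atol=1e-10)

    def test_intensity_vanishes_for_large_n(self, rng):
        X = rng.standard_normal((10000, 5)) @ np.diag([1, 2, 3, 0.5, 1.5])
        est = dec.shrinkage_covariance(X)
        assert est.shrinkage_intensity < 0.05
        sample = np.cov(X.T, bias=True)
        assert np.allclose(est.matrix, sample, atol=0.05)

    def test_positive_definite_after_shrinkage(self, rng):
        # fewer rows than columns: sample covariance singular, shrunk one not
        X = rng.standard_normal((4, 8))
        est = dec.shrinkage_covariance(X)
        assert np.all(np.linalg.eigvalsh(est.matrix) > 0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            dec.shrinkage_covariance(np.ones((1, 3)))


# --------------------------------------------------------------------------
# Tuning curve and readouts
# --------------------------------------------------------------------------

class TestTuningCurve:
    def test_euclidean_reduction_under_identity_covariance(self):
        # under identity covariance the Mahalanobis distance to (3,4) is 5
        cov = dec.CovarianceEstimate(np.eye(2), 0.0)
        means = np.zeros((16, 2))
        means[0] = [3.0, 4.0]
        curve = dec.tuning_curve(np.zeros(2), means, cov)
        d = -curve.similarity  # centered distances: spread is preserved
        assert np.isclose(d.max() - d.min(), 5.0)
        assert curve.similarity.sum() == pytest.approx(0.0, abs=1e-10)

    def test_maximum_similarity_at_matching_bin(self, rng):
        cov = dec.CovarianceEstimate(np.eye(3), 0.0)
        means = rng.standard_normal((16, 3)) * 0.0
        means[8] = [1.0, 1.0, 1.0]     # bin at relative 0 deg after ordering?
        test = np.array([1.0, 1.0, 1.0])
        curve = dec.tuning_curve(test, means, cov)
        assert curve.similarity.argmax() == 8
        assert curve.similarity.sum() == pytest.approx(0.0, abs=1e-10)

    def test_distances_match_dense_solve_oracle(self, rng):
        A = rng.standard_normal((4, 4))
        cov = dec.CovarianceEstimate(A @ A.T + 4 * np.eye(4), 0.2)
        means = rng.standard_normal((16, 4))
        test = rng.standard_normal(4)
        curve = dec.tuning_curve(test, means, cov)
        inv = np.linalg.inv(cov.matrix)
        d = np.array([np.sqrt((m - test) @ inv @ (m - test)) for m in means])
        assert np.allclose(-(d - d.mean()), curve.similarity, atol=1e-10)

    def test_similarity_invariant_to_channelwise_offset(self, rng):
        A = rng.standard_normal((3, 3))
        cov = dec.CovarianceEstimate(A @ A.T + 3 * np.eye(3), 0.1)
        means = rng.standard_normal((16, 3))
        test = rng.standard_normal(3)
        shift = rng.standard_normal(3)
        c1 = dec.tuning_curve(test, means, cov)
        c2 = dec.tuning_curve(test + shift, means + shift, cov)
        assert np.allclose(c1.similarity, c2.similarity, atol=1e-9)


class TestReadouts:
    def test_cosine_flat_curve_is_zero(self):
        assert dec.cosine_vector_mean(np.full(16, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_of_cosine_curve_is_half(self):
        sim = np.cos(2 * np.deg2rad(dec.REL_BIN_CENTERS_DEG))
        assert dec.cosine_vector_mean(sim) == pytest.approx(0.5)

    def test_cosine_delta_at_zero(self):
        sim = np.zeros(16)
        sim[np.where(dec.REL_BIN_CENTERS_DEG == 0.0)[0][0]] = 1.0
        assert dec.cosine_vector_mean(sim) == pytest.approx(1.0 / 16)

    def test_slope_flat_profile_is_zero(self):
        assert dec.slope_readout(np.ones(8), syn.DV_LEVELS_DEG) == pytest.approx(0.0)

    def test_slope_exact_line(self):
        x = syn.DV_LEVELS_DEG
        assert dec.slope_readout(-x / 90.0, x) == pytest.approx(1.0 / 90.0)

    def test_slope_matches_least_squares_oracle(self, rng):
        x = syn.DV_LEVELS_DEG
        sim = rng.standard_normal(8)
        slope = np.polyfit(x, sim, 1)[0]
        assert dec.slope_readout(sim, x) == pytest.approx(-slope, abs=1e-12)


# --------------------------------------------------------------------------
# Spatiotemporal features
# --------------------------------------------------------------------------

class TestSpatiotemporalFeatures:
    def test_feature_dimension_17_channels(self):
        t = syn.default_time_axis()
        data = np.random.default_rng(0).standard_normal((2, 17, len(t)))
        feats = dec.spatiotemporal_features(_make_epochs(data))
        # 75 samples in [100, 400) ms post-target -> 7 complete blocks of 10
        assert feats.shape == (2, 17 * 7)

    def test_constant_trial_maps_to_zero_features(self):
        t = syn.default_time_axis()
        data = np.ones((1, 3, len(t))) * 7.5
        feats = dec.spatiotemporal_features(_make_epochs(data))
        assert np.allclose(feats, 0.0)

    def test_window_too_short_rejected(self, small_subject):
        _, epochs = small_subject
        with pytest.raises(ValueError):
            dec.spatiotemporal_features(epochs, window_ms=(100, 120))


# --------------------------------------------------------------------------
# Cross-validated decoders on planted data
# --------------------------------------------------------------------------

class TestDecodeTimeResolved:
    def test_needs_two_blocks(self, small_subject):
        trials, epochs = small_subject
        with pytest.raises(ValueError, match="blocks"):
            dec.decode_time_resolved(epochs, trials["theta_cued"],
                                     np.ones(len(trials)))

    def test_noiseless_planted_code_decodes_at_every_sample(self):
        # two identical blocks, near-zero noise, only the target code planted:
        # exact self-consistency makes the index positive at every in-window
        # sample
        import pandas as pd
        from conftest import full_grid_two_block_design
        trials = full_grid_two_block_design()
        model = syn.GenerativeModel(n_channels=6, n_eye_channels=0,
                                    noise_scale=1e-4, ar1=0.0, amp_linger=0.0,
                                    amp_active=0.0, amp_latent=0.0, amp_dv=0.0)
        model = model.materialize(np.random.default_rng(8))
        gains = pd.DataFrame({k: np.ones(len(trials)) for k in
                              ("gain_cued", "gain_uncued", "gain_linger")})
        epochs = syn.simulate_epochs(trials, model, seed=8, gains=gains)
        with pytest.warns(UserWarning, match="zero residual covariance"):
            series = dec.decode_time_resolved(epochs, trials["theta_target"],
                                              trials["block"].to_numpy(),
                                              baseline=False)
        m = (epochs.time_ms >= 900) & (epochs.time_ms <= 1300)  # target bump
        assert np.all(series.values[:, m] > 0)

    def test_shuffled_labels_not_significant(self):
        # label-permutation null over 10 small subjects (target labels cover
        # the grid; permutation preserves the multiset, breaks correspondence)
        from scipy import stats
        _, target_grid = syn.build_orientation_grids()
        means = []
        for s in range(10):
            trials, epochs = syn.simulate_subject(
                syn.SessionConfig(n_blocks=8), seed=600 + s)
            rng = np.random.default_rng(s)
            # balanced random labels: 8 copies of each grid orientation,
            # shuffled, so every leave-one-block-out bin stays populated
            labels = rng.permutation(np.tile(target_grid.values, 8))
            series = dec.decode_time_resolved(
                epochs, labels, trials["block"].to_numpy(),
                channels=syn.eeg_channels(epochs))
            means.append(series.values.mean())
        t, p = stats.ttest_1samp(means, 0.0, alternative="greater")
        assert p > 0.05

    def test_planted_cued_code_emerges_in_delay_and_grows(self, demo_experiment):
        perf, d = demo_experiment
        t = d["time_ms"]
        pre = d["tr_cued"][:, t < 0].mean()
        delay = d["tr_cued"][:, (t >= 300) & (t <= 800)].mean()
        post = d["tr_cued"][:, (t >= 900) & (t <= 1300)].mean()
        assert delay > pre + 0.05
        assert post > delay


class TestDecodeSpatiotemporal:
    def test_uncued_item_latent_state(self, demo_experiment):
        """Uncued item: no delay decoding, but target-evoked decodability."""
        from scipy import stats
        perf, d = demo_experiment
        t = d["time_ms"]
        delay = d["tr_uncued"][:, (t >= 300) & (t <= 800)].mean(axis=1)
        # time-resolved delay decoding of the uncued item is at chance
        assert stats.ttest_1samp(delay, 0.0).pvalue > 0.05
        # but the spatiotemporal post-target index is reliably positive
        by_subj = [d["st_uncued"][perf["subject"] == s].mean()
                   for s in sorted(perf["subject"].unique())]
        t_stat, p = stats.ttest_1samp(by_subj, 0.0, alternative="greater")
        assert p < 0.05

    def test_cued_exceeds_uncued_in_delay(self, demo_experiment):
        from scipy import stats
        perf, d = demo_experiment
        t = d["time_ms"]
        m = (t >= 300) & (t <= 800)
        diff = d["tr_cued"][:, m].mean(axis=1) - d["tr_uncued"][:, m].mean(axis=1)
        assert stats.ttest_1samp(diff, 0.0, alternative="greater").pvalue < 0.05


class TestDecodeCrossItem:
    def test_identical_labels_reproduce_regular_decoder(self, small_subject):
        trials, epochs = small_subject
        chans = syn.eeg_channels(epochs)
        blocks = trials["block"].to_numpy()
        regular = dec.decode_spatiotemporal(epochs, trials["theta_cued"], blocks,
                                            channels=chans)
        cross = dec.decode_cross_item(epochs, trials["theta_cued"],
                                      trials["theta_cued"], blocks,
                                      channels=chans)
        assert np.allclose(regular.values, cross.values)

    def test_shared_format_yields_positive_cross_index(self):
        from scipy import stats
        model = syn.GenerativeModel(shared_item_format=True, amp_linger=0.0)
        vals = []
        for s in range(5):
            trials, epochs = syn.simulate_subject(
                syn.SessionConfig(n_blocks=32), model=model, seed=700 + s)
            cross = dec.decode_cross_item(
                epochs, trials["theta_cued"], trials["theta_uncued"],
                trials["block"].to_numpy(), channels=syn.eeg_channels(epochs))
            vals.append(cross.values.mean())
        assert stats.ttest_1samp(vals, 0.0, alternative="greater").pvalue < 0.05

    def test_disjoint_format_yields_null_cross_index(self):
        model = syn.GenerativeModel(shared_item_format=False, amp_linger=0.0)
        vals = []
        for s in range(5):
            trials, epochs = syn.simulate_subject(
                syn.SessionConfig(n_blocks=32), model=model, seed=800 + s)
            cross = dec.decode_cross_item(
                epochs, trials["theta_cued"], trials["theta_uncued"],
                trials["block"].to_numpy(), channels=syn.eeg_channels(epochs))
            vals.append(cross.values.mean())
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 0.01


# --------------------------------------------------------------------------
# Readout-level invariants
# --------------------------------------------------------------------------

class TestInvariants:
    def test_permuted_label_readout_has_zero_mean(self, rng):
        """Cosine readout of label-permuted data: mean 0 over 200 permutations."""
        sims = rng.standard_normal((50, 16))
        vals = []
        for _ in range(200):
            perm = rng.permutation(16)
            vals.append(np.mean([dec.cosine_vector_mean(s[perm]) for s in sims]))
        vals = np.asarray(vals)
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-12

    def test_decoding_index_monotone_in_planted_gain(self):
        """Noiseless: spatiotemporal index rises monotonically with gain."""
        from scipy.stats import spearmanr
        import pandas as pd
        from conftest import full_grid_two_block_design
        trials = full_grid_two_block_design()
        model = syn.GenerativeModel(n_channels=6, n_eye_channels=0,
                                    noise_scale=1e-3, ar1=0.0,
                                    amp_linger=0.0).materialize(
            np.random.default_rng(3))
        gain_levels = np.linspace(0.5, 2.0, 10)
        idx_means = []
        for g in gain_levels:
            gains = pd.DataFrame({
                "gain_cued": np.full(len(trials), g),
                "gain_uncued": np.ones(len(trials)),
                "gain_linger": np.ones(len(trials))})
            epochs = syn.simulate_epochs(trials, model, seed=11, gains=gains)
            series = dec.decode_spatiotemporal(
                epochs, trials["theta_cued"], trials["block"].to_numpy(),
                baseline=False)
            idx_means.append(series.values.mean())
        rho = spearmanr(gain_levels, idx_means).statistic
        assert rho > 0.9

    def test_spatiotemporal_and_time_resolved_agree_in_sign(self, demo_experiment):
        perf, d = demo_experiment
        t = d["time_ms"]
        post = d["tr_cued"][:, (t >= 900) & (t <= 1300)].mean()
        assert np.sign(post) == np.sign(d["st_cued"].mean()) == 1.0


# --------------------------------------------------------------------------
# Eye-channel confound control
# --------------------------------------------------------------------------

class TestRegressOutEye:
    def _series(self, values):
        return dec.DecodingSeries(np.zeros((1, len(values))), "cosine", "cued",
                                  np.arange(len(values)) * 4.0,
                                  np.asarray(values, float))

    def test_orthogonal_eye_series_leaves_original(self, rng):
        y = rng.standard_normal(200)
        x = rng.standard_normal(200)
        x -= x @ (y - y.mean()) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        out = dec.regress_out_eye(self._series(y), self._series(x))
        assert np.allclose(out.mean_timecourse, y, atol=0.2)

    def test_identical_eye_series_flattens_to_intercept(self, rng):
        y = rng.standard_normal(200)
        out = dec.regress_out_eye(self._series(y), self._series(y))
        assert np.allclose(out.mean_timecourse, y.mean(), atol=1e-10)

    def test_partial_eye_contamination_matches_ols_oracle(self, rng):
        x = rng.standard_normal(300)
        y = 0.5 * x + 0.1 * rng.standard_normal(300)
        out = dec.regress_out_eye(self._series(y), self._series(x))
        xc = x - x.mean()
        slope = (xc * (y - y.mean())).sum() / (xc ** 2).sum()
        oracle = y - slope * xc
        assert np.allclose(out.mean_timecourse, oracle, atol=1e-12)
        assert out.mean_timecourse.var() < y.var()

    def test_constant_eye_series_warns(self, rng):
        y = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="constant"):
            out = dec.regress_out_eye(self._series(y), self._series(np.ones(100)))
        assert np.allclose(out.mean_timecourse, y)

    def test_eye_channel_decoding_is_null(self, small_subject):
        trials, epochs = small_subject
        eye = dec.decode_spatiotemporal(epochs, trials["theta_cued"],
                                        trials["block"].to_numpy(),
                                        channels=syn.eye_channels(epochs))
        assert abs(eye.values.mean()) < 0.05
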