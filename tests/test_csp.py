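"""CSP algebra, feature properties, and offline/online decoding behaviour."""

import dataclasses

import numpy as np
import pytest

import smrbci as sb
from smrbci.csp import AccuracyRecord, make_classifier
from tests.conftest import constant_depth_patient


class TestCovariances:
    def test_white_noise_covariance_is_half_identity(self):
        """2-channel iid unit noise: trace-normalised covariance -> I/2."""
        rng = np.random.default_rng(0)
        X1 = rng.standard_normal((500, 2, 200))
        X2 = rng.standard_normal((500, 2, 200))
        c1, c2 = sb.estimate_class_covariances(X1, X2)
        for c in (c1, c2):
            assert np.max(np.abs(c.cov - 0.5 * np.eye(2))) < 0.05

    def test_flat_channel_regularised_positive_definite(self, caplog):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3, 50))
        X[:, 2, :] = 0.0  # dead electrode
        with caplog.at_level("WARNING"):
            c1, _ = sb.estimate_class_covariances(X, X.copy())
        assert np.all(np.linalg.eigvalsh(c1.cov) > 0)

    def test_duplicate_input_identical_estimates(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 4, 100))
        a, _ = sb.estimate_class_covariances(X, X)
        b, _ = sb.estimate_class_covariances(X.copy(), X.copy())
        assert np.array_equal(a.cov, b.cov)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            sb.estimate_class_covariances(np.zeros((1, 2, 10)), np.zeros((3, 2, 10)))


class TestFitCSP:
    def test_analytic_two_channel_eigenvalues(self):
        """diag(4,1) vs diag(1,4): generalised eigenvalues are 0.8 and 0.2."""
        bank = sb.fit_csp(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), n_pairs=1)
        assert np.allclose(bank.eigenvalues, [0.8, 0.2], atol=1e-10)

    def test_whitening_constraint(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        C1, C2 = A @ A.T + 1e-3 * np.eye(6), B @ B.T + 1e-3 * np.eye(6)
        bank = sb.fit_csp(C1, C2)
        assert np.max(np.abs(bank.W @ (C1 + C2) @ bank.W.T - np.eye(6))) < 1e-8

    def test_equal_covariances_give_half_eigenvalues(self):
        C = np.diag([2.0, 3.0, 1.0])
        bank = sb.fit_csp(C, C.copy())
        assert np.allclose(bank.eigenvalues, 0.5, atol=1e-12)

    def test_eigenvalue_pairing_sums_to_one(self):
        """For each filter w: lambda_task + lambda_idle = 1 (shared whitening)."""
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 8))
        B = rng.standard_normal((8, 8))
        C1, C2 = A @ A.T + 1e-3 * np.eye(8), B @ B.T + 1e-3 * np.eye(8)
        bank = sb.fit_csp(C1, C2)
        lam_idle = np.diag(bank.W @ C2 @ bank.W.T)
        assert np.allclose(bank.eigenvalues + lam_idle, 1.0, atol=1e-10)

    def test_eigenvalues_sorted_descending_in_unit_interval(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((5, 5))
        C1 = A @ A.T + 1e-2 * np.eye(5)
        bank = sb.fit_csp(C1, np.eye(5))
        lam = bank.eigenvalues
        assert np.all(np.diff(lam) <= 1e-12)
        assert np.all((lam >= -1e-12) & (lam <= 1 + 1e-12))


class TestFeatures:
    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        bank = sb.fit_csp(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), n_pairs=1)
        ep = rng.standard_normal((2, 300))
        assert np.allclose(sb.extract_features(ep, bank),
                           sb.extract_features(17.0 * ep, bank), atol=1e-12)

    def test_feature_length_is_two_n_pairs(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((8, 8))
        bank = sb.fit_csp(A @ A.T + np.eye(8), np.eye(8), n_pairs=3)
        feats = sb.extract_features(rng.standard_normal((8, 100)), bank)
        assert feats.shape == (6,)

    def test_toy_classes_separate_on_first_filter(self):
        """Task trials (variance on ch1) out-score idle on filter 1 in >=95%."""
        rng = np.random.default_rng(8)
        bank = sb.fit_csp(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), n_pairs=1)
        wins = 0
        n = 200
        for _ in range(n):
            task = rng.standard_normal((2, 200)) * np.array([[2.0], [1.0]])
            idle = rng.standard_normal((2, 200)) * np.array([[1.0], [2.0]])
            wins += sb.extract_features(task, bank)[0] > sb.extract_features(idle, bank)[0]
        assert wins / n >= 0.95

    def test_zero_variance_projection_floored(self, caplog):
        bank = sb.fit_csp(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), n_pairs=1)
        with caplog.at_level("WARNING"):
            feats = sb.extract_features(np.zeros((2, 100)), bank)
        assert np.all(np.isfinite(feats))


class TestOfflineAccuracy:
    def test_strong_erd_session_decodes_above_090(self, strong_decode_epochs):
        rec = sb.offline_accuracy(strong_decode_epochs, "31", "lda", seed=0)
        assert rec.accuracy >= 0.9
        assert rec.n_trials == 90

    def test_shuffled_labels_give_chance_accuracy(self, strong_decode_epochs):
        """Label permutation destroys decodability: accuracy in 0.5 +/- 0.13."""
        ep = strong_decode_epochs
        rng = np.random.default_rng(123)
        shuffled = dataclasses.replace(ep, labels=ep.labels[rng.permutation(ep.n_trials)])
        rec = sb.offline_accuracy(shuffled, "31", "rf", seed=0)
        assert abs(rec.accuracy - 0.5) <= 0.13

    def test_no_signal_session_is_chance(self, sim_config):
        pat = constant_depth_patient(1.0)
        rec = sb.simulate_session(pat, 1, sim_config, np.random.default_rng(9))
        ep = sb.decoding_epochs(sb.bandpass(rec, 8, 30))
        r = sb.offline_accuracy(ep, "31", "lda", seed=0)
        assert abs(r.accuracy - 0.5) <= 0.15

    def test_seven_channel_subset_used(self, strong_decode_epochs):
        rec7 = sb.offline_accuracy(strong_decode_epochs, "7", "lda", seed=0)
        assert rec7.channel_set == "7"
        assert rec7.accuracy >= 0.85

    def test_fold_accuracy_invariant_to_trial_order_within_runs(self, strong_decode_epochs):
        ep = strong_decode_epochs
        rng = np.random.default_rng(77)
        perm = np.concatenate([rng.permutation(np.nonzero(ep.runs == r)[0])
                               for r in np.unique(ep.runs)])
        permuted = dataclasses.replace(ep, data=ep.data[perm], labels=ep.labels[perm],
                                       runs=ep.runs[perm])
        a = sb.offline_accuracy(ep, "31", "lda", seed=0).accuracy
        b = sb.offline_accuracy(permuted, "31", "lda", seed=0).accuracy
        assert a == b

    def test_separable_features_fit_perfectly(self):
        """Both classifier kinds reach 1.0 on linearly separable features."""
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(-3, 0.1, (20, 6)), rng.normal(3, 0.1, (20, 6))])
        y = np.array(["idle"] * 20 + ["task"] * 20)
        for kind in ("lda", "rf"):
            clf = make_classifier(kind, seed=0)
            clf.fit(X, y)
            assert (clf.predict(X) == y).all()


class TestOnlineAccuracy:
    def test_online_close_to_offline_when_stationary(self, strong_decode_epochs):
        on = sb.online_accuracy(strong_decode_epochs, "31", seed=0)
        off = sb.offline_accuracy(strong_decode_epochs, "31", "lda", seed=0)
        assert on.n_trials == 60
        assert abs(on.accuracy - off.accuracy) <= 0.1

    def test_deterministic_replay(self, strong_decode_epochs):
        a = sb.online_accuracy(strong_decode_epochs, "31", seed=0)
        b = sb.online_accuracy(strong_decode_epochs, "31", seed=0)
        assert a.accuracy == b.accuracy

    def test_run2_evaluation_scope(self, strong_decode_epochs):
        r = sb.online_accuracy(strong_decode_epochs, "31", eval_runs="run2", seed=0)
        assert r.n_trials == 30

    def test_adaptation_tracks_within_session_drift(self, sim_config):
        """With ERD deepening across the session, the adaptive decoder beats
        the frozen run-1 model in >= 80% of seeded replicates."""
        wins = ties = 0
        n_rep = 20
        cfg = dataclasses.replace(sim_config, trials_per_run=20,
                                  sensor_noise_std=4.0, mu_amplitude=2.0,
                                  beta_amplitude=1.0)
        for rep in range(n_rep):
            ep = _drifting_session_epochs(cfg, seed=100 + rep)
            adaptive = sb.online_accuracy(ep, "31", adapt=True, seed=0).accuracy
            frozen = sb.online_accuracy(ep, "31", adapt=False, seed=0).accuracy
            if adaptive > frozen:
                wins += 1
            elif adaptive == frozen:
                ties += 1
        assert (wins + ties) / n_rep >= 0.8


def _drifting_session_epochs(cfg, seed: int) -> sb.EpochSet:
    """Session whose ERD depth drifts from shallow to deep across trials."""
    rng = np.random.default_rng(seed)
    n_total = cfg.runs_per_session * cfg.trials_per_run
    fs = cfg.sampling_rate
    lo, hi = round((cfg.cue_time + 1.0) * fs), round((cfg.cue_time + 4.0) * fs)
    data, labels, runs = [], [], []
    for k in range(n_total):
        g = 0.9 - 0.6 * k / (n_total - 1)
        pat = constant_depth_patient(g)
        label = "task" if rng.random() < 0.5 else "idle"
        seg, _ = sb.simulate_trial(pat, 1, label, cfg, rng)
        data.append(seg[lo:hi].T)
        labels.append(label)
        runs.append(1 + k // cfg.trials_per_run)
    ep = sb.EpochSet(np.array(data), np.array(labels), np.array(runs, dtype=int),
                     (1.0, 4.0), fs, cfg.montage)
    return sb.bandpass(ep, 8.0, 30.0)


class TestTrendSummary:
    def _records(self, accs):
        return [AccuracyRecord("P", i + 1, "offline", "31", "rf", 90, a)
                for i, a in enumerate(accs)]

    def test_increasing_accuracies_peak_last(self):
        best, sub, mean = sb.session_trend_summary(self._records(np.linspace(0.5, 0.9, 12)))
        assert (best, sub) == (12, "last_six")
        assert abs(mean - 0.7) < 1e-9

    def test_decreasing_accuracies_peak_first(self):
        best, sub, _ = sb.session_trend_summary(self._records(np.linspace(0.9, 0.5, 12)))
        assert (best, sub) == (1, "first_six")

    def test_tie_resolves_to_later_session(self):
        accs = [0.6] * 12
        accs[5] = accs[6] = 0.9
        best, sub, _ = sb.session_trend_summary(self._records(accs))
        assert (best, sub) == (7, "last_six")

    def test_mixed_modes_rejected(self):
        recs = self._records([0.6] * 12)
        recs[0] = AccuracyRecord("P", 1, "online", "31", "lda", 60, 0.6)
        with pytest.raises(ValueError):
            sb.session_trend_summary(recs)
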