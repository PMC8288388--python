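"""P300 victim model: epoching, xDAWN, covariance features,
classification, input gradients and character voting."""

from types import SimpleNamespace

import numpy as np
import pytest
import scipy.linalg
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from spellbreak import p300, synth
from spellbreak.chars import p300_char_at


def epoch_arrays(session):
    eps = p300.extract_epochs(session)
    return np.stack([e.data for e in eps]), np.array([e.label for e in eps])


class TestEpochs:
    def test_counts_full_test_session(self):
        cfg = synth.P300SimConfig(n_test_chars=100, n_repeats=15, seed=0)
        sess = synth.make_p300_session(cfg, "test")
        eps = p300.extract_epochs(sess)
        labels = np.array([e.label for e in eps])
        assert len(eps) == 18000
        assert labels.sum() == 3000
        assert (labels == 0).sum() == 15000

    def test_single_repeat_trial_has_two_targets(self):
        cfg = synth.P300SimConfig(n_train_chars=1, n_repeats=1, seed=1)
        sess = synth.make_p300_session(cfg, "train")
        eps = p300.extract_epochs(sess)
        assert len(eps) == 12
        assert sum(e.label for e in eps) == 2

    def test_epoch_length_and_overlap(self, small_p300_train, small_p300_config):
        fs = small_p300_config.fs
        eps = p300.extract_epochs(small_p300_train)
        assert eps[0].data.shape == (16, round(0.600 * fs)) == (16, 144)
        # consecutive events share 600 - 175 = 425 ms of signal
        overlap = p300.epoch_length(fs) - small_p300_config.soa_samples
        assert overlap == round(0.425 * fs)
        assert np.array_equal(eps[0].data[:, -overlap:], eps[1].data[:, :overlap])

    def test_truncated_window_raises(self, small_p300_train):
        clipped = synth.P300Session(
            small_p300_train.signal[:, :-200],
            small_p300_train.events,
            small_p300_train.trials,
            small_p300_train.fs,
            "train",
            small_p300_train.n_repeats,
        )
        with pytest.raises(ValueError, match="extends past"):
            p300.extract_epochs(clipped)


class TestXdawn:
    def test_sixteen_filters_unit_norm(self, small_p300_train):
        data, labels = epoch_arrays(small_p300_train)
        filt = p300.fit_xdawn(data, labels)
        assert filt.stacked.shape == (16, 16)
        assert np.allclose(np.linalg.norm(filt.stacked, axis=0), 1.0)

    def test_recovers_generating_pattern_in_white_noise(self):
        cfg = synth.P300SimConfig(n_train_chars=10, seed=3, noise_model="white")
        data, labels = epoch_arrays(synth.make_p300_session(cfg, "train"))
        filt = p300.fit_xdawn(data, labels)
        a = cfg.pattern()
        cos = abs(filt.w_target[:, 0] @ a) / np.linalg.norm(filt.w_target[:, 0])
        assert cos >= 0.95

    def test_shuffled_labels_destroy_the_objective(self, small_p300_train, rng):
        """The evoked-to-total power ratio collapses under label shuffling."""
        data, labels = epoch_arrays(small_p300_train)

        def top_gev(lab):
            total = np.einsum("ncl,nkl->ck", data, data) / (data.shape[0] * data.shape[2])
            ev = data[lab == 1].mean(axis=0)
            sig = ev @ ev.T / ev.shape[1]
            return scipy.linalg.eigh(sig, total, eigvals_only=True)[-1]

        true_val = top_gev(labels)
        shuf_val = top_gev(rng.permutation(labels))
        assert true_val > 3.0 * shuf_val

    def test_single_class_rejected(self, small_p300_train):
        data, labels = epoch_arrays(small_p300_train)
        with pytest.raises(ValueError):
            p300.fit_xdawn(data, np.zeros_like(labels))


class TestSupertrialCovariance:
    def test_shape_symmetry_positive_definite(self, small_p300_train, small_p300_model):
        data, _ = epoch_arrays(small_p300_train)
        c = p300.supertrial_covariance(data[0], small_p300_model.filters, 0.01)
        assert c.shape == (32, 32)
        assert np.allclose(c, c.T)
        assert np.linalg.eigvalsh(c).min() > 0

    def test_deterministic_for_identical_epochs(self, small_p300_train, small_p300_model):
        data, _ = epoch_arrays(small_p300_train)
        c1 = p300.supertrial_covariance(data[3], small_p300_model.filters)
        c2 = p300.supertrial_covariance(data[3].copy(), small_p300_model.filters)
        assert np.array_equal(c1, c2)

    def test_zero_epoch_rank_at_most_sixteen(self, small_p300_model):
        zero = np.zeros((16, 144))
        c = p300.supertrial_covariance(zero, small_p300_model.filters, shrinkage=0.0)
        assert np.linalg.matrix_rank(c, tol=1e-10) <= 16

    def test_nonfinite_rejected(self, small_p300_model):
        bad = np.full((16, 144), np.nan)
        with pytest.raises(ValueError):
            p300.supertrial_covariance(bad, small_p300_model.filters)

    def test_features_invariant_to_channel_offsets(self, small_p300_train, small_p300_model):
        """Rows are centered before the covariance, so constant channel
        offsets do not move the features."""
        data, _ = epoch_arrays(small_p300_train)
        x = data[10]
        shifted = x + np.linspace(-3, 3, 16)[:, None]
        assert np.allclose(
            small_p300_model.features(x), small_p300_model.features(shifted), atol=1e-10
        )


class TestTrainingAndPrediction:
    def test_class_weight_ratio_is_five(self, small_p300_model):
        w = small_p300_model.class_weights
        assert w[1] / w[0] == pytest.approx(5.0)

    def test_training_epoch_balanced_accuracy(self, small_p300_train, small_p300_model):
        data, labels = epoch_arrays(small_p300_train)
        pred = small_p300_model.predict_proba(data) > 0.5
        assert balanced_accuracy_score(labels, pred) >= 0.85

    def test_target_probabilities_dominate(self, small_p300_test, small_p300_model):
        data, labels = epoch_arrays(small_p300_test)
        probs = small_p300_model.predict_proba(data)
        assert roc_auc_score(labels, probs) > 0.9

    def test_probabilities_in_unit_interval(self, small_p300_test, small_p300_model):
        data, _ = epoch_arrays(small_p300_test)
        probs = small_p300_model.predict_proba(data[:100])
        assert np.all((probs > 0) & (probs < 1))

    def test_retraining_reproduces_weights(self, small_p300_train, small_p300_model):
        again = p300.train(p300.P300ModelConfig(), small_p300_train)
        assert np.allclose(again.coef, small_p300_model.coef)
        assert again.intercept == pytest.approx(small_p300_model.intercept)

    def test_single_class_session_rejected(self, small_p300_train):
        bad = synth.P300Session(
            small_p300_train.signal,
            small_p300_train.events,
            [synth.P300TrialInfo(t.trial_index, -1, 20, "?") for t in small_p300_train.trials],
            small_p300_train.fs,
            "train",
            small_p300_train.n_repeats,
        )
        with pytest.raises(ValueError):
            p300.train(p300.P300ModelConfig(), bad)

    def test_shape_mismatch_rejected(self, small_p300_model):
        with pytest.raises(ValueError):
            small_p300_model.predict_proba(np.zeros((16, 100)))


class TestLossGradient:
    def test_matches_finite_differences(self, small_p300_test, small_p300_model, rng):
        data, _ = epoch_arrays(small_p300_test)
        x = data[17]
        for y in (0, 1):
            g = p300.loss_gradient(small_p300_model, x, y)
            assert g.shape == x.shape
            for _ in range(10):
                i, j = rng.integers(16), rng.integers(144)
                h = 1e-5
                xp, xm = x.copy(), x.copy()
                xp[i, j] += h
                xm[i, j] -= h

                def loss(z):
                    pr = small_p300_model.predict_proba(z)
                    return -np.log(pr) if y == 1 else -np.log(1 - pr)

                fd = (loss(xp) - loss(xm)) / (2 * h)
                assert abs(fd - g[i, j]) / max(abs(fd), 1e-8) < 1e-4

    def test_label_flip_scales_and_reverses(self, small_p300_test, small_p300_model):
        """grad J(X,0) = p * dlogit, grad J(X,1) = (p-1) * dlogit: the two
        are anti-parallel with ratio p/(1-p)."""
        data, _ = epoch_arrays(small_p300_test)
        x = data[5]
        pr = float(small_p300_model.predict_proba(x))
        g0 = p300.loss_gradient(small_p300_model, x, 0)
        g1 = p300.loss_gradient(small_p300_model, x, 1)
        assert np.allclose(g0 * (1 - pr), -g1 * pr, atol=1e-12)


class _ForcedModel(SimpleNamespace):
    """Duck-typed model returning prescribed probabilities per stimulus id."""

    def predict_proba(self, data):
        return np.array([self.table[sid] for sid in self.sids[: len(data)]])


class TestDecodeCharacter:
    def _forced(self, session, table, n_repeats):
        evs = session.trial_events(0, n_repeats)
        return _ForcedModel(
            epoch_len=144, table=table, sids=[e.stimulus_id for e in evs]
        )

    def test_forced_argmax(self, small_p300_train):
        table = {sid: 0.0 for sid in range(1, 13)}
        table[5] = 1.0  # row 5
        table[8] = 1.0  # column 2
        model = self._forced(small_p300_train, table, 15)
        got = p300.decode_character(model, small_p300_train, 0, 15)
        assert got == p300_char_at(5, 2) == "Z"

    def test_majority_mass_wins_over_noisy_repeat(self, small_p300_train):
        # row 3 collects 1.8 probability mass over two repeats, row 6 only
        # 0.9 from one noisy repeat; column 1 is clean
        table = {sid: 0.0 for sid in range(1, 13)}
        table[3] = 0.9
        table[6] = 0.45
        table[7] = 0.8
        model = self._forced(small_p300_train, table, 2)
        got = p300.decode_character(model, small_p300_train, 0, 2)
        assert got == p300_char_at(3, 1) == "M"

    def test_clean_decoding_accuracy(self, small_p300_test, small_p300_model):
        decoded = p300.decode_session(small_p300_model, small_p300_test, 15)
        truth = [t.target_char for t in small_p300_test.trials]
        assert np.mean([d == t for d, t in zip(decoded, truth)]) >= 0.85

    def test_user_score_nondecreasing_in_repeats(self, small_p300_test, small_p300_model):
        truth = [t.target_char for t in small_p300_test.trials]
        scores = []
        for nr in (5, 10, 15):
            dec = p300.decode_session(small_p300_model, small_p300_test, nr)
            scores.append(np.mean([d == t for d, t in zip(dec, truth)]))
        assert scores[0] <= scores[1] + 1e-12 and scores[1] <= scores[2] + 1e-12

    def test_excess_repeats_rejected(self, small_p300_test, small_p300_model):
        with pytest.raises(ValueError):
            p300.decode_character(small_p300_model, small_p300_test, 0, 16)
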