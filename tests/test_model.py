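"""The LSTM + additive-attention classifier and its training protocol."""

import numpy as np
import pytest

from phytosense.model import (LSTMAttentionClassifier, ModelConfig,
                              TrainingConfig, build_model)

from conftest import make_separable_toy


def loss_of(clf, X, y):
    p = np.clip(clf._forward(X, training=False)["prob"], 1e-12, 1 - 1e-12)
    return (-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            + clf.l2_factor * np.sum(clf.weights_["W1"] ** 2))


class TestArchitecture:
    def test_lstm_sequence_output_is_16_dimensional(self):
        clf = build_model(ModelConfig(), input_shape=(100, 230))
        clf.weights_ = clf._init_weights(230, np.random.default_rng(0))
        X = np.random.default_rng(1).normal(size=(2, 100, 230))
        cache = clf._forward(X, training=False)
        assert cache["Hseq"].shape == (2, 100, 16)

    def test_attention_weights_sum_to_one(self, toy_trained_model):
        clf, X, _ = toy_trained_model
        alpha = clf.attention_weights(X)
        assert alpha.shape == (len(X), X.shape[1])
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_output_probability_strictly_in_unit_interval(self, toy_trained_model):
        clf, X, _ = toy_trained_model
        p = clf.predict_proba(X)[:, 1]
        assert np.all((p > 0) & (p < 1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            build_model(input_shape=(0, 230))


class TestGradients:
    def test_parameter_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        clf = LSTMAttentionClassifier(lstm_units=5, dense_units=4,
                                      dropout=0.0, random_state=0)
        B, T, F = 3, 6, 7
        X = rng.normal(size=(B, T, F))
        y = np.array([0, 1, 1])
        clf.weights_ = clf._init_weights(F, np.random.default_rng(1))
        clf.input_shape_ = (T, F)
        cache = clf._forward(X, training=False)
        grads, _ = clf._backward(cache, (cache["prob"] - y) / B)
        eps = 1e-6
        for k, w in clf.weights_.items():
            idx = tuple(rng.integers(s) for s in w.shape)
            orig = w[idx]
            w[idx] = orig + eps
            lp = loss_of(clf, X, y)
            w[idx] = orig - eps
            lm = loss_of(clf, X, y)
            w[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-10), k

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        clf = LSTMAttentionClassifier(lstm_units=4, dense_units=3,
                                      dropout=0.0, random_state=0)
        X = rng.normal(size=(2, 5, 6))
        clf.weights_ = clf._init_weights(6, np.random.default_rng(3))
        clf.input_shape_ = (5, 6)
        dX = clf.input_gradient(X)
        eps = 1e-6
        i, t, f = 1, 2, 3
        orig = X[i, t, f]
        X[i, t, f] = orig + eps
        pp = clf._forward(X, training=False)["prob"][i]
        X[i, t, f] = orig - eps
        pm = clf._forward(X, training=False)["prob"][i]
        X[i, t, f] = orig
        assert dX[i, t, f] == pytest.approx((pp - pm) / (2 * eps), rel=1e-5)

    def test_every_trainable_tensor_receives_gradient(self):
        rng = np.random.default_rng(4)
        clf = LSTMAttentionClassifier(lstm_units=4, dense_units=3,
                                      dropout=0.0, random_state=0)
        X = rng.normal(size=(8, 5, 6))
        y = rng.integers(0, 2, size=8)
        clf.weights_ = clf._init_weights(6, np.random.default_rng(5))
        clf.input_shape_ = (5, 6)
        cache = clf._forward(X, training=False)
        grads, _ = clf._backward(cache, (cache["prob"] - y) / 8)
        for k, g in grads.items():
            assert np.any(g != 0), f"dead branch: {k}"


class TestTraining:
    def test_overfits_linearly_separable_toy_set(self, toy_trained_model):
        clf, X, y = toy_trained_model
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_early_stopping_halts_after_patience_plus_one_epochs(self):
        X, y = make_separable_toy(n=8)
        clf = LSTMAttentionClassifier(lstm_units=3, dense_units=3,
                                      early_stop_patience=4, dropout=0.0,
                                      random_state=0)
        clf._evaluate = lambda Xv, yv: (1.0, 0.5)  # val loss forced constant
        clf.fit(X, y, validation_data=(X, y))
        assert len(clf.history_.train_loss) == 5  # 1 best + patience

    def test_training_capped_at_max_epochs(self, toy_trained_model):
        clf, _, _ = toy_trained_model
        assert clf.history_.stopped_epoch <= clf.max_epochs
        assert len(clf.history_.train_loss) <= clf.max_epochs

    def test_plateau_halves_learning_rate(self):
        X, y = make_separable_toy(n=8)
        clf = LSTMAttentionClassifier(lstm_units=3, dense_units=3,
                                      plateau_patience=2,
                                      early_stop_patience=6, dropout=0.0,
                                      random_state=0)
        clf._evaluate = lambda Xv, yv: (1.0, 0.5)
        clf.fit(X, y, validation_data=(X, y))
        lrs = clf.history_.lr
        assert lrs[0] == pytest.approx(1e-3)
        assert min(lrs) < lrs[0]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))  # non-increasing

    def test_seeded_runs_identical(self):
        X, y = make_separable_toy(n=12, seed=3)
        hist = []
        for _ in range(2):
            clf = LSTMAttentionClassifier(lstm_units=4, dense_units=3,
                                          max_epochs=8, random_state=7)
            clf.fit(X, y, validation_data=(X, y))
            hist.append((clf.history_.val_loss, clf.weights_))
        assert hist[0][0] == hist[1][0]
        for k in hist[0][1]:
            np.testing.assert_array_equal(hist[0][1][k], hist[1][1][k])

    def test_empty_training_set_rejected(self):
        clf = LSTMAttentionClassifier()
        with pytest.raises(ValueError):
            clf.fit(np.zeros((0, 4, 5)), np.zeros(0))


class TestFineTuning:
    def test_zero_epochs_leaves_weights_bit_identical(self, toy_trained_model):
        clf, X, y = toy_trained_model
        before = {k: v.copy() for k, v in clf.weights_.items()}
        clf.fine_tune(X, y, validation_data=(X, y), max_epochs=0)
        for k in before:
            np.testing.assert_array_equal(clf.weights_[k], before[k])

    def test_reduced_learning_rate_recorded_in_history(self):
        X, y = make_separable_toy(n=12)
        clf = LSTMAttentionClassifier(lstm_units=4, dense_units=3,
                                      max_epochs=4, random_state=0)
        clf.fit(X, y, validation_data=(X, y))
        clf.fine_tune(X, y, validation_data=(X, y), max_epochs=3)
        assert clf.history_.lr[0] == pytest.approx(5e-4)

    def test_fine_tune_requires_reduced_rate(self, toy_trained_model):
        clf, X, y = toy_trained_model
        with pytest.raises(ValueError):
            clf.fine_tune(X, y, learning_rate=1e-2)

    def test_shape_mismatch_rejected(self, toy_trained_model):
        clf, X, y = toy_trained_model
        with pytest.raises(ValueError):
            clf.fine_tune(np.zeros((4, 9, 9)), np.zeros(4, dtype=int))


class TestPrediction:
    def test_boundary_probability_maps_to_light(self):
        clf = LSTMAttentionClassifier(threshold=0.5)
        # bypass the network: threshold semantics only
        clf.predict_proba = lambda X: np.array([[0.5, 0.5]])
        assert clf.predict(np.zeros((1, 2, 3))) == np.array([1])

    def test_duplicated_sample_same_probability(self, toy_trained_model):
        clf, X, _ = toy_trained_model
        p = clf.predict_proba(np.stack([X[0], X[0]]))[:, 1]
        assert p[0] == p[1]

    def test_save_load_roundtrip(self, toy_trained_model, tmp_path):
        clf, X, _ = toy_trained_model
        clf.save(tmp_path / "model.npz")
        back = LSTMAttentionClassifier.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.predict_proba(X),
                                      clf.predict_proba(X))

    def test_learning_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(fine_tune_lr=2e-3)
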