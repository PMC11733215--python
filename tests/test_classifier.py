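"""The NumPy temporal CNN: exactness of gradients, protocol, determinism."""

import numpy as np
import pytest

from fidgetfusion import (
    CNNConfig,
    CNNSnippetClassifier,
    TrainConfig,
    build_model,
    grid_search_light,
    load_classifier,
    predict_proba,
    save_classifier,
    train_model,
    train_with_restarts,
)
from fidgetfusion import nn
from fidgetfusion.classifier import DataError

TINY = CNNConfig(conv_layers=((4, 3), (4, 3), (4, 3)), fc_units=8)


def toy_problem(rng, n=40, frames=20, channels=3):
    """Linearly separable toy snippets: class 1 has a mean offset."""
    y = (np.arange(n) % 2).astype(float)
    X = rng.normal(0, 1, (n, frames, channels)).astype(np.float32)
    X[y == 1] += 1.5
    return X, y


class TestForwardOracle:
    def test_conv_matches_hand_computed_same_padding(self):
        """A 1-layer conv with hand-set weights equals the direct formula."""
        rng = np.random.default_rng(0)
        conv = nn.Conv1D(1, 1, 3, rng)
        conv.W[...] = np.array([[1.0], [2.0], [3.0]], dtype=np.float32)
        conv.b[...] = 0.5
        x = np.array([[[1.0], [2.0], [3.0], [4.0], [5.0]]], dtype=np.float32)
        out = conv.forward(x, training=False)[0, :, 0]
        # same padding: y[t] = 1*x[t-1] + 2*x[t] + 3*x[t+1] + 0.5 (zeros outside)
        expected = [1 * 0 + 2 * 1 + 3 * 2 + 0.5,
                    1 * 1 + 2 * 2 + 3 * 3 + 0.5,
                    1 * 2 + 2 * 3 + 3 * 4 + 0.5,
                    1 * 3 + 2 * 4 + 3 * 5 + 0.5,
                    1 * 4 + 2 * 5 + 3 * 0 + 0.5]
        np.testing.assert_allclose(out, expected, rtol=1e-6)

    def test_logit_zero_gives_probability_half(self):
        assert nn.sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_gradients_match_finite_differences(self):
        """Backprop through Conv/BN/ReLU/Dropout(0)/Dense is exact."""
        rng = np.random.default_rng(3)
        cfg = CNNConfig(conv_layers=((2, 3),), fc_units=3, dropout_rate=0.0,
                        input_shape=(6, 2))
        net = build_model(cfg, rng)
        # float64 weights for the numeric check
        for p in net.params():
            p_new = p.astype(np.float64)
        x = rng.normal(size=(3, 6, 2)).astype(np.float32)
        y = np.array([1.0, 0.0, 1.0], dtype=np.float32)

        logits = net.forward(x, training=True, rng=np.random.default_rng(0))
        _, dlogits = nn.bce_with_logits(logits, y)
        net.backward(dlogits)
        analytic = [g.copy() for g in net.grads()]

        eps = 1e-3
        for p, g in zip(net.params(), analytic):
            idx = (0,) * p.ndim
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = nn.bce_with_logits(
                net.forward(x, training=True, rng=np.random.default_rng(0)), y)
            p[idx] = orig - eps
            lm, _ = nn.bce_with_logits(
                net.forward(x, training=True, rng=np.random.default_rng(0)), y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(numeric, rel=2e-2, abs=2e-4)


class TestBuildModel:
    def test_forward_pass_returns_finite_logit(self):
        cfg = CNNConfig(conv_layers=((32, 5), (32, 5), (32, 5)), fc_units=64,
                        input_shape=(250, 60))
        net = build_model(cfg, np.random.default_rng(0))
        logit = net.forward(np.zeros((1, 250, 60), dtype=np.float32))
        assert logit.shape == (1,) and np.isfinite(logit[0])

    def test_parameter_count_deterministic(self):
        cfg = CNNConfig(conv_layers=((8, 5), (8, 5)), fc_units=16,
                        input_shape=(50, 6))
        n1 = sum(p.size for p in build_model(cfg, np.random.default_rng(0)).params())
        n2 = sum(p.size for p in build_model(cfg, np.random.default_rng(9)).params())
        assert n1 == n2

    def test_kernel_longer_than_frames_rejected(self):
        cfg = CNNConfig(conv_layers=((4, 21),), fc_units=4, input_shape=(10, 2))
        with pytest.raises(ValueError, match="kernel"):
            build_model(cfg, np.random.default_rng(0))


class TestTraining:
    def test_same_seed_reproduces_weights_and_log(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=4, patience=2, n_restarts=1, seed=5)
        a = train_model(X, y, TINY, tc)
        b = train_model(X, y, TINY, tc)
        assert a.training_log == b.training_log
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_separable_data_reaches_high_training_accuracy(self, rng):
        X, y = toy_problem(rng, n=60)
        tc = TrainConfig(batch_size=8, max_epochs=30, patience=10, n_restarts=1,
                         seed=5)
        fitted = train_model(X, y, TINY, tc)
        pred = (predict_proba(fitted, X) >= 0.5).astype(float)
        ba = 0.5 * (np.mean(pred[y == 1]) + np.mean(1 - pred[y == 0]))
        assert ba >= 0.95

    def test_shuffled_labels_stay_near_chance_loss(self, rng):
        X, _ = toy_problem(rng, n=64)
        y_perm = rng.permutation((np.arange(64) % 2).astype(float))
        tc = TrainConfig(batch_size=8, max_epochs=20, patience=5, n_restarts=1,
                         seed=5)
        fitted = train_model(X, y_perm, TINY, tc)
        # no-signal control: validation loss cannot drop well below ln 2
        assert fitted.best_val_loss > 0.45

    def test_single_class_training_set_rejected(self, rng):
        X, _ = toy_problem(rng, n=10)
        tc = TrainConfig(n_restarts=1)
        with pytest.raises(DataError):
            train_model(X, np.ones(10), TINY, tc)

    def test_early_stopping_restores_best_epoch(self, rng):
        X, y = toy_problem(rng, n=40)
        tc = TrainConfig(batch_size=8, max_epochs=40, patience=3, n_restarts=1,
                         seed=5)
        fitted = train_model(X, y, TINY, tc)
        val_losses = [row[2] for row in fitted.training_log]
        assert fitted.best_val_loss == pytest.approx(min(val_losses))


class TestRestarts:
    def test_one_restart_reduces_to_train_model(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=2, n_restarts=1, seed=9)
        single = train_model(X, y, TINY, tc)
        restarted = train_with_restarts(X, y, TINY, tc)
        assert restarted.best_val_loss == single.best_val_loss
        assert restarted.training_log == single.training_log

    def test_selects_minimum_validation_loss(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=2, n_restarts=3, seed=9)
        best = train_with_restarts(X, y, TINY, tc)
        losses = [train_with_restarts(X, y, TINY,
                                      TrainConfig(batch_size=8, max_epochs=3,
                                                  patience=2, n_restarts=1,
                                                  seed=tc.seed)).best_val_loss]
        assert best.best_val_loss <= losses[0]

    def test_same_master_seed_selects_same_restart(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=2, n_restarts=3, seed=4)
        a = train_with_restarts(X, y, TINY, tc)
        b = train_with_restarts(X, y, TINY, tc)
        assert a.restart_index == b.restart_index
        assert a.best_val_loss == b.best_val_loss


class TestPrediction:
    def test_probabilities_in_open_unit_interval(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=2, n_restarts=1, seed=1)
        fitted = train_model(X, y, TINY, tc)
        p = predict_proba(fitted, X)
        assert np.all((p > 0) & (p < 1))

    def test_repeated_inference_is_deterministic(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=2, n_restarts=1, seed=1)
        fitted = train_model(X, y, TINY, tc)
        np.testing.assert_array_equal(predict_proba(fitted, X), predict_proba(fitted, X))

    def test_shape_mismatch_rejected(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=2, patience=1, n_restarts=1, seed=1)
        fitted = train_model(X, y, TINY, tc)
        with pytest.raises(ValueError, match="shape"):
            predict_proba(fitted, np.zeros((2, 21, 3)))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=2, n_restarts=1, seed=1)
        fitted = train_model(X, y, TINY, tc)
        save_classifier(fitted, tmp_path / "ckpt")
        back = load_classifier(tmp_path / "ckpt")
        np.testing.assert_allclose(predict_proba(back, X), predict_proba(fitted, X),
                                   atol=1e-7)


class TestGridSearch:
    def test_single_config_grid_returns_it(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=2, n_restarts=1, seed=2)
        ranked = grid_search_light(X, y, [TINY], tc)
        assert len(ranked) == 1 and ranked[0][0] == TINY

    def test_ranking_sorted_by_validation_loss(self, rng):
        X, y = toy_problem(rng)
        tc = TrainConfig(batch_size=8, max_epochs=5, patience=3, n_restarts=1, seed=2)
        crippled = CNNConfig(conv_layers=((1, 1),), fc_units=1)
        ranked = grid_search_light(X, y, [crippled, TINY], tc)
        losses = [score for _, score in ranked]
        assert losses == sorted(losses)

    def test_empty_grid_rejected(self, rng):
        X, y = toy_problem(rng)
        with pytest.raises(ValueError):
            grid_search_light(X, y, [], TrainConfig(n_restarts=1))


class TestSklearnEstimator:
    def test_fit_predict_and_get_params(self, rng):
        X, y = toy_problem(rng)
        clf = CNNSnippetClassifier(conv_layers=((4, 3), (4, 3), (4, 3)), fc_units=8,
                                   batch_size=8, max_epochs=5, patience=3,
                                   n_restarts=1, random_state=0)
        clf.fit(X, y)
        assert set(clf.classes_) == {0.0, 1.0}
        proba = clf.predict_proba(X)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(clf.predict(X)) <= {0, 1}
        params = clf.get_params()
        assert params["n_restarts"] == 1
        clf.set_params(max_epochs=3)
        assert clf.max_epochs == 3

    def test_clone_compatible(self, rng):
        from sklearn.base import clone
        clf = CNNSnippetClassifier(n_restarts=2, random_state=7)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
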