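"""Architecture bookkeeping, training contracts and evaluation
arithmetic for the beat classifier."""

import numpy as np
import pytest

from conftest import tiny_spec
from pedecg import nn
from pedecg.model import (ConfusionMatrix, TrainConfig, build_model,
                          canonical_spec, confusion_accuracy, evaluate,
                          one_hot, train)


class TestCanonicalSpec:
    def test_flatten_width_38400(self):
        assert canonical_spec().flatten_width() == 38_400

    def test_output_layer_two_classes(self):
        assert canonical_spec().output_classes == 2

    def test_block_parameters_as_printed(self):
        blocks = canonical_spec().blocks
        assert [b.filters for b in blocks] == [128, 16, 8, 128]
        assert [b.dropout_rate for b in blocks] == [0.45, 0.1, 0.05, 0.4]
        assert [b.activation for b in blocks] == ["relu", "sigmoid", "relu",
                                                  "sigmoid"]
        assert [b.batch_norm for b in blocks] == [False, False, True, False]
        assert all(b.kernel_size == 3 and b.stride == 1 for b in blocks)

    def test_flatten_width_by_actual_shape_propagation(self):
        """Forward pass through the real layers reproduces the printed
        flatten width (independent of the arithmetic shortcut)."""
        net = build_model(canonical_spec(), TrainConfig(seed=0))
        x = np.random.default_rng(0).normal(size=(2, 1, 300))
        h = x.astype(nn.DTYPE)
        for layer in net.layers:
            h = layer.forward(h, False)
            if isinstance(layer, nn.Flatten):
                assert h.shape == (2, 38_400)
                break


class TestBuildAndForward:
    def test_softmax_probabilities_sum_to_one(self):
        net = build_model(tiny_spec(), TrainConfig(seed=1))
        p = net.predict_proba(np.zeros((3, 1, 300), dtype=np.float32))
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_shape_contract(self):
        net = build_model(tiny_spec(), TrainConfig(seed=1))
        p = net.predict_proba(
            np.random.default_rng(0).normal(size=(5, 1, 300)))
        assert p.shape == (5, 2)


def separable_arrays(n, seed=0, scale=1.0):
    """Two classes separated by a bump in samples 150..250."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, size=(n, 300))
    y = rng.integers(0, 2, n)
    X[y == 1, 150:250] += scale
    return X, y


class TestTraining:
    def test_seeded_training_is_reproducible(self):
        data = separable_arrays(120, seed=2)
        val = separable_arrays(40, seed=3)
        runs = []
        for _ in range(2):
            cfg = TrainConfig(max_epochs=3, batch_size=40, seed=7)
            fitted = train(build_model(tiny_spec(), cfg), data, val, cfg)
            runs.append(fitted.history)
        assert runs[0].equals(runs[1])

    def test_learns_separable_data(self):
        data = separable_arrays(200, seed=4)
        val = separable_arrays(80, seed=5)
        cfg = TrainConfig(max_epochs=8, batch_size=50, seed=1)
        fitted = train(build_model(tiny_spec(), cfg), data, val, cfg)
        _, acc = evaluate(fitted, val)
        assert acc >= 0.9

    def test_early_stopping_bounds_total_epochs(self):
        data = separable_arrays(100, seed=6)
        val = separable_arrays(40, seed=7)
        cfg = TrainConfig(max_epochs=30, early_stop_patience=3,
                          batch_size=50, seed=2)
        fitted = train(build_model(tiny_spec(), cfg), data, val, cfg)
        last_epoch = int(fitted.history.epoch.iloc[-1])
        assert last_epoch <= fitted.best_epoch + cfg.early_stop_patience

    def test_single_class_training_split_rejected(self):
        X, y = separable_arrays(50, seed=8)
        y[:] = 0
        cfg = TrainConfig(max_epochs=1, seed=0)
        with pytest.raises(ValueError):
            train(build_model(tiny_spec(), cfg), (X, y),
                  separable_arrays(10, seed=9), cfg)


class TestEvaluation:
    TABLE2 = [[2018, 99], [544, 200]]

    def test_validation_confusion_matrix_arithmetic(self):
        cm = ConfusionMatrix(self.TABLE2)
        assert cm.diagonal_sum == 2218
        fraction, percent = confusion_accuracy(cm)
        assert percent == 78
        assert fraction == pytest.approx(2218 / 2861)

    def test_perfect_and_constant_predictors(self):
        assert confusion_accuracy(ConfusionMatrix([[10, 0], [0, 10]]))[0] == 1.0
        # constant "normal" on 8 normal + 2 obese
        frac, _ = confusion_accuracy(ConfusionMatrix([[8, 0], [2, 0]]))
        assert frac == pytest.approx(0.8)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_accuracy(ConfusionMatrix([[0, 0], [0, 0]]))

    def test_evaluate_consistent_with_own_matrix(self, tiny_trained):
        fitted, ds = tiny_trained
        cm, acc = evaluate(fitted, ds.split("val"))
        assert acc == pytest.approx(confusion_accuracy(cm)[0])
        assert cm.total == len(ds.split("val")[1])


class TestEngine:
    def test_one_hot(self):
        np.testing.assert_array_equal(
            one_hot(np.array([0, 1, 1])),
            [[1, 0], [0, 1], [0, 1]])

    def test_conv_matches_direct_correlation(self):
        rng = np.random.default_rng(3)
        conv = nn.Conv1dSame(2, 3, 3, rng)
        x = rng.normal(size=(1, 2, 10)).astype(np.float32)
        y = conv.forward(x, False)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1)))
        for f in range(3):
            for l in range(10):
                expected = (conv.params["W"][f] * xp[0, :, l:l + 3]).sum() \
                    + conv.params["b"][f]
                assert y[0, f, l] == pytest.approx(expected, rel=1e-4,
                                                   abs=1e-5)

    def test_backprop_matches_finite_differences(self, float64_engine):
        """End-to-end parameter gradients agree with central differences
        on a tiny network (the anti-bug oracle for the engine)."""
        rng = np.random.default_rng(0)
        net = build_model(tiny_spec((3,)), TrainConfig(seed=11))
        x = rng.normal(size=(4, 1, 300))
        y = np.array([0, 1, 0, 1])
        hb = one_hot(y)

        def loss():
            return nn.cross_entropy(nn.softmax(net.forward(x, False)), hb)

        probs = nn.softmax(net.forward(x, False))
        net.backward_from_logits((probs - hb) / len(y))
        conv = net.layers[0]
        h = 1e-6
        for idx in [(0, 0, 0), (1, 0, 2), (2, 0, 1)]:
            w0 = conv.params["W"][idx]
            conv.params["W"][idx] = w0 + h
            up = loss()
            conv.params["W"][idx] = w0 - h
            down = loss()
            conv.params["W"][idx] = w0
            fd = (up - down) / (2 * h)
            assert conv.grads["W"][idx] == pytest.approx(fd, rel=1e-4,
                                                         abs=1e-9)
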