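"""Layer-block classifier: architecture, training, inference, rejection."""

import numpy as np
import pytest

from cathsf import (
    ClassifierConfig,
    build_classifier,
    load_classifier,
    predict_proba,
    predict_with_rejection,
    save_classifier,
    train_classifier,
)
from cathsf.classifier import _forward
from cathsf.errors import ConfigurationError, IntegrityError

_BN_EPS = 1e-5


def small_config(**kw):
    defaults = dict(n_layer_blocks=2, layer_size=16, dropout_rate=0.3,
                    input_type="AA", epochs=30, batch_size=16,
                    learning_rate=1e-2, seed=0)
    defaults.update(kw)
    return ClassifierConfig(**defaults)


def gaussian_blobs(n_classes=3, n_per_class=30, dim=6, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_classes, dim))
    centers *= sep / np.linalg.norm(centers, axis=1, keepdims=True)
    x = np.concatenate([centers[k] + rng.normal(0, 0.5, (n_per_class, dim))
                        for k in range(n_classes)])
    y = np.repeat(np.arange(n_classes), n_per_class)
    return x, y


class TestBuild:
    def test_layer_descriptor_list(self):
        cfg = ClassifierConfig(n_layer_blocks=2, layer_size=2048,
                               dropout_rate=0.3, input_type="AA+3Di")
        m = build_classifier(cfg, input_dim=16, n_classes=1740)
        assert m.architecture() == [
            "dense(2048)", "leaky_relu(0.05)", "batch_norm", "dropout(0.3)",
            "dense(2048)", "leaky_relu(0.05)", "batch_norm", "dropout(0.3)",
            "dense(1740)", "softmax"]

    def test_one_block_has_two_dense_matrices(self):
        m = build_classifier(small_config(n_layer_blocks=1), 8, n_classes=3)
        dense = [k for k in m.params if k.startswith("W")]
        assert sorted(dense) == ["W0", "Wout"]

    def test_seeded_init_is_deterministic(self):
        a = build_classifier(small_config(), 8, n_classes=3)
        b = build_classifier(small_config(), 8, n_classes=3)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_too_few_classes_rejected(self):
        with pytest.raises(ConfigurationError):
            build_classifier(small_config(), 8, n_classes=1)

    @pytest.mark.parametrize("kw", [
        dict(n_layer_blocks=0), dict(dropout_rate=1.0),
        dict(input_type="bogus"), dict(leaky_slope=0.0),
        dict(learning_rate=0.0),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small_config(**kw)


class TestTraining:
    def test_separable_data_reaches_full_train_accuracy(self):
        x, y = gaussian_blobs()
        m = build_classifier(small_config(dropout_rate=0.0), 6, n_classes=3)
        train_classifier(m, x, y, x, y)
        acc = (predict_proba(m, x).argmax(1) == y).mean()
        assert acc == 1.0

    def test_training_log_reproducible(self):
        x, y = gaussian_blobs()
        logs = []
        for _ in range(2):
            m = build_classifier(small_config(epochs=8), 6, n_classes=3)
            train_classifier(m, x, y, x, y)
            logs.append(m.training_log)
        assert logs[0] == logs[1]

    def test_dimension_mismatch_rejected(self):
        x, y = gaussian_blobs()
        m = build_classifier(small_config(), 9, n_classes=3)
        with pytest.raises(IntegrityError, match="shape"):
            train_classifier(m, x, y, x, y)

    def test_empty_training_set_rejected(self):
        m = build_classifier(small_config(), 6, n_classes=3)
        with pytest.raises(IntegrityError, match="empty"):
            train_classifier(m, np.empty((0, 6)), np.empty(0, int),
                             np.empty((0, 6)), np.empty(0, int))

    def test_gradients_match_finite_differences(self):
        """Analytic backprop (incl. the batch-norm path) against central
        finite differences on a tiny two-block network."""
        from cathsf.classifier import _backward, _xentropy

        rng = np.random.default_rng(4)
        cfg = small_config(n_layer_blocks=2, layer_size=4, dropout_rate=0.0)
        m = build_classifier(cfg, 3, n_classes=3)
        x = rng.standard_normal((12, 3))
        y = rng.integers(0, 3, 12)
        onehot = np.eye(3)[y]

        probs, cache = _forward(m, x, training=True)
        grads = _backward(m, cache, probs, onehot, None)

        def loss():
            p, _ = _forward(m, x, training=True)
            return _xentropy(p, y)

        for key in ("W0", "b1", "gamma0", "beta1", "Wout", "bout"):
            flat = m.params[key].ravel()
            for idx in [0, flat.size // 2]:
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-7), key


@pytest.fixture(scope="module")
def trained():
    x, y = gaussian_blobs()
    m = build_classifier(small_config(), 6, n_classes=3)
    return train_classifier(m, x, y, x, y), x, y


@pytest.fixture(scope="module")
def trained_crisp():
    x, y = gaussian_blobs(sep=8.0)
    m = build_classifier(small_config(dropout_rate=0.0), 6, n_classes=3)
    return train_classifier(m, x, y, x, y), x, y


class TestInference:
    def test_rows_sum_to_one(self, trained):
        m, x, _ = trained
        probs = predict_proba(m, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_identical_rows(self, trained):
        m, x, _ = trained
        probs = predict_proba(m, np.stack([x[0], x[0], x[1]]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_matches_independent_forward_pass(self, trained):
        """Inference equals a from-scratch matrix-arithmetic forward pass
        using running statistics, written without the library's layers."""
        m, x, _ = trained
        h = np.asarray(x[:5], dtype=float)
        p = m.params
        for b in range(m.config.n_layer_blocks):
            z = h @ p[f"W{b}"] + p[f"b{b}"]
            a = np.where(z > 0, z, m.config.leaky_slope * z)
            a = (a - p[f"rmean{b}"]) / np.sqrt(p[f"rvar{b}"] + _BN_EPS)
            h = p[f"gamma{b}"] * a + p[f"beta{b}"]
        logits = h @ p["Wout"] + p["bout"]
        expect = np.exp(logits - logits.max(1, keepdims=True))
        expect /= expect.sum(1, keepdims=True)
        np.testing.assert_allclose(predict_proba(m, x[:5]), expect,
                                   atol=1e-10)

    def test_untrained_model_refuses_to_predict(self):
        m = build_classifier(small_config(), 6, n_classes=3)
        with pytest.raises(ConfigurationError, match="trained"):
            predict_proba(m, np.zeros((1, 6)))

    def test_save_load_round_trip(self, trained, tmp_path):
        m, x, _ = trained
        save_classifier(m, str(tmp_path / "model"))
        back = load_classifier(str(tmp_path / "model"))
        np.testing.assert_array_equal(predict_proba(back, x),
                                      predict_proba(m, x))
        assert back.label_space == m.label_space


class TestRejection:
    def test_confident_calls_pass_threshold(self, trained_crisp):
        m, x, y = trained_crisp
        preds = predict_with_rejection(m, x, confidence_threshold=0.9)
        accepted = [p for p in preds if not p.rejected]
        assert accepted and all(p.confidence >= 0.9 for p in accepted)
        assert all(p.label is not None for p in accepted)

    def test_zero_threshold_never_rejects(self, trained_crisp):
        m, x, _ = trained_crisp
        preds = predict_with_rejection(m, x, confidence_threshold=0.0)
        assert not any(p.rejected for p in preds)

    def test_uniform_probabilities_rejected(self):
        """A model producing uniform output over many classes can never
        clear a 0.9 threshold; ties break to the lowest class index."""
        cfg = small_config(n_layer_blocks=1, layer_size=4)
        m = build_classifier(cfg, 3, n_classes=40)
        m.params["Wout"][:] = 0.0
        m.params["bout"][:] = 0.0
        m.trained = True
        preds = predict_with_rejection(m, np.zeros((2, 3)),
                                       confidence_threshold=0.9)
        assert all(p.rejected for p in preds)
        assert all(p.confidence == pytest.approx(1 / 40) for p in preds)
        accepted = predict_with_rejection(m, np.zeros((1, 3)),
                                          confidence_threshold=0.0)
        assert accepted[0].label == m.label_space[0]  # lowest-index tie win

    def test_rejection_rate_monotone_in_threshold(self, trained_crisp):
        m, x, _ = trained_crisp
        rates = [np.mean([p.rejected for p in
                          predict_with_rejection(m, x, t)])
                 for t in np.linspace(0, 1, 11)]
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_invalid_threshold_rejected(self, trained_crisp):
        m, x, _ = trained_crisp
        with pytest.raises(ConfigurationError):
            predict_with_rejection(m, x, confidence_threshold=1.5)
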