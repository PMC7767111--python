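import numpy as np
import pytest

from vcgmi._nn import DenseNet, flatten_params, set_flat_params
from vcgmi.classification import (
    CLASS_LABELS,
    ClassifierConfig,
    ClassifierModel,
    label_indices,
    one_hot,
    predict,
    smote_oversample,
    train_classifier,
)


def separable_gaussians(rng, n_classes=3, per_class=200, dim=52, sep=5.0):
    means = np.zeros((n_classes, dim))
    for k in range(n_classes):
        means[k, k] = sep  # unit-variance clusters 5 sigma apart
    X = np.vstack([rng.normal(means[k], 1.0, size=(per_class, dim)) for k in range(n_classes)])
    y = np.repeat(np.arange(n_classes), per_class)
    return X, y


class TestLabels:
    def test_twelve_fixed_labels(self):
        assert len(CLASS_LABELS) == 12
        assert CLASS_LABELS[0] == "AMI" and CLASS_LABELS[-1] == "HC"

    def test_string_mapping(self):
        np.testing.assert_array_equal(label_indices(["HC", "AMI"]), [11, 0])

    def test_unknown_label(self):
        with pytest.raises(KeyError, match="unknown"):
            label_indices(["NOPE"])

    def test_one_hot(self):
        oh = one_hot(np.array([0, 2]), 3)
        np.testing.assert_array_equal(oh, [[1, 0, 0], [0, 0, 1]])


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.repeat([0, 1], 10)
        X2, y2 = smote_oversample(X, y)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_target_counts(self, rng):
        X = rng.normal(size=(110, 6))
        y = np.array([0] * 100 + [1] * 10)
        X2, y2 = smote_oversample(X, y, k=5, seed=0)
        assert np.sum(y2 == 0) == 100
        assert np.sum(y2 == 1) == 100

    def test_originals_preserved(self, rng):
        X = rng.normal(size=(60, 5))
        y = np.array([0] * 50 + [1] * 10)
        X2, y2 = smote_oversample(X, y, seed=1)
        np.testing.assert_array_equal(X2[:60], X)
        np.testing.assert_array_equal(y2[:60], y)

    def test_synthetic_points_on_neighbor_segments(self, rng):
        X = rng.normal(size=(64, 3))
        y = np.array([0] * 50 + [1] * 14)
        k = 5
        X2, y2 = smote_oversample(X, y, k=k, seed=2)
        minority = X[y == 1]
        synth = X2[64:]
        assert np.all(y2[64:] == 1)
        for s in synth:
            on_segment = False
            for a_idx in range(len(minority)):
                a = minority[a_idx]
                # brute-force k nearest same-class neighbors of a
                d = np.linalg.norm(minority - a, axis=1)
                nn_idx = np.argsort(d)[1 : k + 1]
                for b in minority[nn_idx]:
                    ab = b - a
                    denom = np.dot(ab, ab)
                    if denom == 0:
                        continue
                    u = np.dot(s - a, ab) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.linalg.norm(a + u * ab - s) < 1e-9:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_k_lowered_for_tiny_class(self, rng):
        X = rng.normal(size=(23, 4))
        y = np.array([0] * 20 + [1] * 3)
        X2, y2 = smote_oversample(X, y, k=5, seed=3)
        assert np.sum(y2 == 1) == 20

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(11, 4))
        y = np.array([0] * 10 + [1])
        with pytest.raises(ValueError, match="cannot synthesize"):
            smote_oversample(X, y)

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.array([0] * 30 + [1] * 10)
        a = smote_oversample(X, y, seed=7)[0]
        b = smote_oversample(X, y, seed=7)[0]
        np.testing.assert_array_equal(a, b)


FAST = ClassifierConfig(epochs=40, batch_size=64, seed=0, patience=None, validation_fraction=0.0)


class TestTrainClassifier:
    def test_softmax_rows_normalized(self, rng):
        X, y = separable_gaussians(rng, per_class=50)
        cfg = ClassifierConfig(n_classes=3, hidden=(32, 16), epochs=5,
                               patience=None, validation_fraction=0.0)
        model = train_classifier(X, one_hot(y, 3), cfg)
        _, probs = predict(model, X[:20])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((probs > 0) & (probs < 1))

    def test_separable_gaussians_high_accuracy(self, rng):
        X, y = separable_gaussians(rng)
        order = rng.permutation(len(X))
        X, y = X[order], y[order]
        split = int(0.8 * len(X))
        cfg = ClassifierConfig(n_classes=3, hidden=(64, 32), epochs=40,
                               patience=None, validation_fraction=0.0)
        model = train_classifier(X[:split], one_hot(y[:split], 3), cfg)
        pred, _ = predict(model, X[split:])
        assert np.mean(pred == y[split:]) >= 0.99

    def test_training_loss_decreases(self, rng):
        X, y = separable_gaussians(rng, per_class=60)
        cfg = ClassifierConfig(n_classes=3, hidden=(32, 16), epochs=15,
                               patience=None, validation_fraction=0.0)
        model = train_classifier(X, one_hot(y, 3), cfg)
        smooth = np.convolve(model.history, np.ones(3) / 3, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_seeded_determinism(self, rng):
        X, y = separable_gaussians(rng, per_class=30)
        cfg = ClassifierConfig(n_classes=3, hidden=(16, 8), epochs=3,
                               patience=None, validation_fraction=0.0)
        a = train_classifier(X, one_hot(y, 3), cfg)
        b = train_classifier(X, one_hot(y, 3), cfg)
        for wa, wb in zip(a.net.params, b.net.params):
            np.testing.assert_array_equal(wa, wb)

    def test_wrong_width_rejected(self, rng):
        with pytest.raises(ValueError, match="expected 52"):
            train_classifier(rng.normal(size=(30, 10)), np.zeros((30, 12)))

    def test_default_topology(self):
        cfg = ClassifierConfig()
        assert (cfg.input_dim, *cfg.hidden, cfg.n_classes) == (52, 300, 275, 12)


class TestPredict:
    def _zero_model(self):
        cfg = ClassifierConfig(input_dim=4, hidden=(5, 5), n_classes=12)
        net = DenseNet((4, 5, 5, 12), output="softmax", seed=0)
        for W in net.weights:
            W[...] = 0.0
        return ClassifierModel(net, cfg)

    def test_uniform_probabilities_tie_to_lowest_index(self):
        model = self._zero_model()
        idx, probs = predict(model, np.ones((3, 4)))
        np.testing.assert_allclose(probs, 1 / 12, atol=1e-12)
        np.testing.assert_array_equal(idx, 0)

    def test_row_independence(self, rng):
        X, y = separable_gaussians(rng, per_class=30)
        cfg = ClassifierConfig(n_classes=3, hidden=(16, 8), epochs=5,
                               patience=None, validation_fraction=0.0)
        model = train_classifier(X, one_hot(y, 3), cfg)
        single, _ = predict(model, X[:1])
        doubled, _ = predict(model, np.vstack([X[:1], X[:1], X[1:5]]))
        assert doubled[0] == doubled[1] == single[0]

    def test_width_mismatch(self, rng):
        model = self._zero_model()
        with pytest.raises(ValueError, match="does not match"):
            predict(model, rng.normal(size=(2, 7)))


class TestGradientCheck:
    def test_softmax_cross_entropy_backward(self, rng):
        net = DenseNet((4, 6, 3), output="softmax", seed=2)
        X = rng.normal(size=(8, 4))
        y = one_hot(rng.integers(0, 3, size=8), 3)
        _, grads = net.loss_and_gradients(X, y)
        analytic = np.concatenate([g.ravel() for g in grads])
        flat0 = flatten_params(net.params)
        numeric = np.zeros_like(flat0)
        h = 1e-6
        for j in range(len(flat0)):
            for sign in (1, -1):
                fp = flat0.copy()
                fp[j] += sign * h
                set_flat_params(net.params, fp)
                numeric[j] += sign * net.loss(X, y)
        set_flat_params(net.params, flat0)
        numeric /= 2 * h
        rel = np.abs(numeric - analytic) / np.maximum(1e-6, np.abs(numeric) + np.abs(analytic))
        assert rel.max() < 1e-4
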