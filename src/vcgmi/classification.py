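"""SMOTE balancing and the per-beat multilayer-perceptron classifier.

The classifier maps the 52 spline features through two ReLU hidden layers
(300 and 275 units) to a 12-way softmax trained with cross-entropy against
one-hot targets. Class imbalance is corrected beforehand by synthetic
minority oversampling: each synthetic point lies on the segment between a
minority point and one of its k nearest same-class neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ._nn import DenseNet
from .synthetic_ecg import CLASS_LABELS

__all__ = [
    "CLASS_LABELS",
    "label_indices",
    "one_hot",
    "ClassifierConfig",
    "ClassifierModel",
    "smote_oversample",
    "train_classifier",
    "predict",
]

log = logging.getLogger(__name__)


def label_indices(y, labels: tuple[str, ...] = CLASS_LABELS) -> np.ndarray:
    """Map string labels (or pass through integer indices) to class indices."""
    y = np.asarray(y)
    if y.dtype.kind in "iu":
        return y.astype(int)
    lookup = {lab: k for k, lab in enumerate(labels)}
    try:
        return np.array([lookup[v] for v in y])
    except KeyError as exc:
        raise KeyError(f"unknown class label {exc.args[0]!r}; expected one of {labels}") from None


def one_hot(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y_idx), n_classes))
    out[np.arange(len(y_idx)), y_idx] = 1.0
    return out


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class up to the majority-class count.

    Each synthetic sample is ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]``,
    ``x`` a minority point and ``x_nn`` one of its ``k`` nearest Euclidean
    same-class neighbors. Original rows are returned unchanged (first), with
    synthetic rows appended. A class smaller than ``k + 1`` uses a reduced
    neighbor count; a singleton class cannot be interpolated and raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return X, y
    new_X = [X]
    new_y = [y]
    for cls, count in zip(classes, counts):
        deficit = int(target - count)
        if deficit == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls!r} has {count} member(s); cannot synthesize neighbors"
            )
        Xc = X[y == cls]
        k_eff = min(k, count - 1)
        if k_eff < k:
            log.info("smote: class %r has %d members, lowering k to %d", cls, count, k_eff)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        neighbors = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, count, size=deficit)
        pick = rng.integers(0, k_eff, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)[:, None]
        seeds = Xc[base]
        nbrs = Xc[neighbors[base, pick]]
        new_X.append(seeds + u * (nbrs - seeds))
        new_y.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


@dataclass(frozen=True)
class ClassifierConfig:
    """Topology and optimization settings for the beat classifier."""

    input_dim: int = 52
    hidden: tuple[int, int] = (300, 275)
    n_classes: int = 12
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.1
    patience: int | None = 10


@dataclass
class ClassifierModel:
    net: DenseNet
    config: ClassifierConfig
    labels: tuple[str, ...] = CLASS_LABELS

    @property
    def history(self) -> list[float]:
        return self.net.history


def train_classifier(
    X: np.ndarray, y_onehot: np.ndarray, config: ClassifierConfig = ClassifierConfig()
) -> ClassifierModel:
    """Train the softmax MLP; aborts with diagnostics on non-finite loss."""
    X = np.asarray(X, dtype=float)
    y_onehot = np.atleast_2d(np.asarray(y_onehot, dtype=float))
    if X.shape[1] != config.input_dim:
        raise ValueError(f"expected {config.input_dim} features, got {X.shape[1]}")
    if len(X) < config.n_classes:
        raise ValueError("fewer training rows than classes")
    net = DenseNet(
        (config.input_dim, *config.hidden, config.n_classes),
        output="softmax",
        seed=config.seed,
    )
    validation = None
    Xt, Yt = X, y_onehot
    if config.validation_fraction > 0 and config.patience is not None:
        rng = np.random.default_rng(config.seed + 1)
        order = rng.permutation(len(X))
        n_val = max(1, int(round(config.validation_fraction * len(X))))
        val_idx, train_idx = order[:n_val], order[n_val:]
        validation = (X[val_idx], y_onehot[val_idx])
        Xt, Yt = X[train_idx], y_onehot[train_idx]
    net.fit(
        Xt,
        Yt,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        shuffle_seed=config.seed + 2,
        validation=validation,
        patience=config.patience,
    )
    return ClassifierModel(net, config)


def predict(model: ClassifierModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax of softmax, ties to the lowest index) and probabilities."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model input {model.config.input_dim}"
        )
    probs = model.net.predict(X)
    return probs.argmax(axis=1), probs
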