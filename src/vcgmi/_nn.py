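"""Small fully-connected network engine (numpy, float64, seeded).

Shared by the feedforward synthesis baseline (linear output, mean-squared
error) and the beat classifier (softmax output, cross-entropy). Written for
determinism and gradient-checkability rather than speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DenseNet", "AdamState", "adam_update", "flatten_params", "set_flat_params"]


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class AdamState:
    """First/second moment accumulators for one list of parameter arrays."""

    m: list[np.ndarray]
    v: list[np.ndarray]
    t: int = 0

    @classmethod
    def like(cls, params: list[np.ndarray]) -> "AdamState":
        return cls([np.zeros_like(p) for p in params], [np.zeros_like(p) for p in params])


def adam_update(
    params: list[np.ndarray],
    grads: list[np.ndarray],
    state: AdamState,
    lr: float = 1e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """In-place Adam step on ``params``."""
    state.t += 1
    for p, g, m, v in zip(params, grads, state.m, state.v):
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        mhat = m / (1 - beta1**state.t)
        vhat = v / (1 - beta2**state.t)
        p -= lr * mhat / (np.sqrt(vhat) + eps)


def flatten_params(params: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([p.ravel() for p in params])


def set_flat_params(params: list[np.ndarray], flat: np.ndarray) -> None:
    offset = 0
    for p in params:
        p[...] = flat[offset : offset + p.size].reshape(p.shape)
        offset += p.size


@dataclass
class DenseNet:
    """Multilayer perceptron with ReLU hidden layers.

    ``output`` is "linear" (trained with mean-squared error) or "softmax"
    (trained with cross-entropy against one-hot targets).
    """

    sizes: tuple[int, ...]
    output: str = "linear"
    seed: int = 0
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.output not in ("linear", "softmax"):
            raise ValueError(f"unknown output type {self.output!r}")
        if not self.weights:
            rng = np.random.default_rng(self.seed)
            for fan_in, fan_out in zip(self.sizes, self.sizes[1:]):
                scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
                self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
                self.biases.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return [a for pair in zip(self.weights, self.biases) for a in pair]

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Return layer activations, input first, network output last."""
        acts = [np.asarray(X, dtype=float)]
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            last = k == len(self.weights) - 1
            if last:
                acts.append(softmax(z) if self.output == "softmax" else z)
            else:
                acts.append(relu(z))
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(X))[-1]

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        out = self.predict(X)
        if self.output == "softmax":
            return float(-np.mean(np.sum(Y * np.log(out + 1e-300), axis=1)))
        return float(np.mean((out - Y) ** 2))

    def loss_and_gradients(
        self, X: np.ndarray, Y: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        """Backpropagation; gradient list parallels :attr:`params`."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        acts = self._forward(X)
        out = acts[-1]
        n = X.shape[0]
        if self.output == "softmax":
            loss = float(-np.mean(np.sum(Y * np.log(out + 1e-300), axis=1)))
            delta = (out - Y) / n
        else:
            loss = float(np.mean((out - Y) ** 2))
            delta = 2.0 * (out - Y) / out.size
        grads: list[np.ndarray] = []
        for k in range(len(self.weights) - 1, -1, -1):
            gW = acts[k].T @ delta
            gb = delta.sum(axis=0)
            grads[:0] = [gW, gb]
            if k > 0:
                delta = (delta @ self.weights[k].T) * (acts[k] > 0)
        return loss, grads

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 64,
        lr: float = 1e-3,
        shuffle_seed: int | None = None,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        patience: int | None = None,
    ) -> list[float]:
        """Mini-batch Adam training; records mean epoch loss in ``history``.

        With ``validation`` and ``patience`` set, stops once validation loss
        has not improved for ``patience`` epochs and restores the best
        parameters.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        rng = np.random.default_rng(self.seed if shuffle_seed is None else shuffle_seed)
        state = AdamState.like(self.params)
        best_val = np.inf
        best_params: np.ndarray | None = None
        since_best = 0
        for _ in range(epochs):
            order = rng.permutation(len(X))
            epoch_losses = []
            for start in range(0, len(X), batch_size):
                idx = order[start : start + batch_size]
                loss, grads = self.loss_and_gradients(X[idx], Y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss ({loss}) at epoch {len(self.history)}; "
                        "lower the learning rate or standardize the inputs"
                    )
                adam_update(self.params, grads, state, lr=lr)
                epoch_losses.append(loss)
            self.history.append(float(np.mean(epoch_losses)))
            if validation is not None and patience is not None:
                val = self.loss(*validation)
                if val < best_val - 1e-12:
                    best_val = val
                    best_params = flatten_params(self.params).copy()
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        if best_params is not None:
            set_flat_params(self.params, best_params)
        return self.history
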