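"""A fully-connected binary classifier trained by Adam on cross-entropy.

Implemented directly on NumPy: forward/backward passes for dense layers
with ReLU activations, a sigmoid output, inverted dropout after each hidden
layer (active only during training), Adam updates, and early stopping that
restores the best-validation-loss weights.  All randomness (initialization,
batch shuffling, dropout masks) flows from one seeded generator, so a fixed
seed reproduces training bit-for-bit on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DTIModelConfig


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # computed in float64 so moderate logits stay strictly inside (0, 1)
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, clip: float = 1e-7
) -> float:
    """Mean binary cross-entropy with probability clipping."""
    p = np.clip(probs, clip, 1.0 - clip)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


@dataclass
class TrainingHistory:
    """Per-epoch loss and accuracy on the training and validation sets."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None
    best_epoch: int | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class DenseNetwork:
    """Dense ReLU network with sigmoid output and inverted dropout."""

    #: all parameters and activations are float32: halves memory traffic on
    #: the dense matmuls with no effect at these accuracy scales
    dtype = np.float32

    def __init__(self, layer_sizes: tuple[int, ...], dropout: float, rng: np.random.Generator):
        self.layer_sizes = tuple(layer_sizes)
        self.dropout = dropout
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        n_layers = len(layer_sizes) - 1
        for layer, (fan_in, fan_out) in enumerate(
            zip(layer_sizes[:-1], layer_sizes[1:])
        ):
            if layer == n_layers - 1:
                # zero-initialized sigmoid head: the untrained classifier
                # outputs exactly 0.5, and gradients still reach every layer
                w = np.zeros((fan_in, fan_out), dtype=self.dtype)
            else:
                # He initialization for the ReLU stack
                scale = np.sqrt(2.0 / fan_in)
                w = rng.normal(0.0, scale, (fan_in, fan_out)).astype(self.dtype)
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out, dtype=self.dtype))

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1

    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Forward pass; dropout is applied only when an rng is supplied."""
        cache = []
        a = np.asarray(X, dtype=self.dtype)
        for layer in range(self.n_hidden):
            z = a @ self.weights[layer] + self.biases[layer]
            h = np.maximum(z, 0.0)
            mask = None
            if rng is not None and self.dropout > 0:
                keep = 1.0 - self.dropout
                mask = (rng.random(h.shape) < keep).astype(self.dtype) / self.dtype(keep)
                h = h * mask
            cache.append((a, z, mask))
            a = h
        z_out = a @ self.weights[-1] + self.biases[-1]
        probs = _sigmoid(z_out[:, 0])
        cache.append((a, z_out, None))
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference pass (dropout disabled)."""
        probs, _ = self.forward(X)
        return probs

    def backward(
        self, cache: list, probs: np.ndarray, labels: np.ndarray
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of mean binary cross-entropy w.r.t. every (W, b).

        Sigmoid + cross-entropy collapse to the residual (p - y) at the
        output logit, so no probability clipping enters the gradient.
        """
        n = labels.shape[0]
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)
        a_last, _, _ = cache[-1]
        delta = ((probs - labels) / n)[:, None].astype(self.dtype)  # dL/dz_out
        grads[-1] = (a_last.T @ delta, delta.sum(axis=0))
        upstream = delta @ self.weights[-1].T
        for layer in range(self.n_hidden - 1, -1, -1):
            a_in, z, mask = cache[layer]
            if mask is not None:
                upstream = upstream * mask
            delta = upstream * (z > 0)
            grads[layer] = (a_in.T @ delta, delta.sum(axis=0))
            if layer:
                upstream = delta @ self.weights[layer].T
        return grads

    def get_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(w.copy(), b.copy()) for w, b in zip(self.weights, self.biases)]

    def set_weights(self, snapshot) -> None:
        self.weights = [w.copy() for w, _ in snapshot]
        self.biases = [b.copy() for _, b in snapshot]


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, net: DenseNetwork, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            (np.zeros_like(w), np.zeros_like(b))
            for w, b in zip(net.weights, net.biases)
        ]
        self.v = [
            (np.zeros_like(w), np.zeros_like(b))
            for w, b in zip(net.weights, net.biases)
        ]

    def step(self, net: DenseNetwork, grads) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, (gw, gb) in enumerate(grads):
            mw, mb = self.m[i]
            vw, vb = self.v[i]
            mw *= self.beta1; mw += (1 - self.beta1) * gw
            mb *= self.beta1; mb += (1 - self.beta1) * gb
            vw *= self.beta2; vw += (1 - self.beta2) * gw**2
            vb *= self.beta2; vb += (1 - self.beta2) * gb**2
            net.weights[i] -= self.lr * (mw / b1c) / (np.sqrt(vw / b2c) + self.eps)
            net.biases[i] -= self.lr * (mb / b1c) / (np.sqrt(vb / b2c) + self.eps)


def train_dnn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: DTIModelConfig,
    seed: int | None = None,
) -> tuple[DenseNetwork, TrainingHistory]:
    """Train the classifier with early stopping on validation loss.

    Dropout is active only during training; per-epoch history records loss
    and accuracy on both sets computed in inference mode.  Training stops
    when validation loss has not improved for ``early_stopping_patience``
    epochs, and the best-validation-loss weights are restored.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    if X_train.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"input dimension {X_train.shape[1]} does not match the "
            f"configured input layer {config.layer_sizes[0]}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    net = DenseNetwork(config.layer_sizes, config.dropout, rng)
    opt = Adam(net, config.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_snapshot = net.get_weights()
    patience = 0
    n = len(X_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs, cache = net.forward(X_train[idx], rng=rng)
            grads = net.backward(cache, probs, y_train[idx])
            opt.step(net, grads)
        p_train = net.predict_proba(X_train)
        p_val = net.predict_proba(X_val)
        history.train_loss.append(
            binary_cross_entropy(p_train, y_train, config.prob_clip)
        )
        history.train_accuracy.append(float(np.mean((p_train >= 0.5) == y_train)))
        val_loss = binary_cross_entropy(p_val, y_val, config.prob_clip)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(float(np.mean((p_val >= 0.5) == y_val)))
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_snapshot = net.get_weights()
            history.best_epoch = epoch
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stopping_patience:
                history.stopped_epoch = epoch
                break
    net.set_weights(best_snapshot)
    return net, history
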