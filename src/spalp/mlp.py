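"""Feed-forward classifier mapping fused pair features to association probability.

ReLU hidden layers, affine output with 2-class softmax, cross-entropy loss
minimized by full-batch Adam for a fixed number of iterations. All
randomness flows from the config seed, so training is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optim import Adam
from .dataset import FeatureTable


@dataclass(frozen=True)
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (128, 64)
    max_iter: int = 300
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("at least one positive hidden layer size required")
        if self.max_iter < 1 or self.learning_rate <= 0:
            raise ValueError("max_iter and learning_rate must be positive")


@dataclass
class MLPModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig
    trained: bool = False

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights/biases length mismatch")
        for l in range(len(self.weights) - 1):
            if self.weights[l].shape[1] != self.weights[l + 1].shape[0]:
                raise ValueError("consecutive layer shapes do not chain")
        for w, b in zip(self.weights, self.biases):
            if w.shape[1] != b.shape[0]:
                raise ValueError("bias shape does not match layer width")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError("non-finite parameters")

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=1, keepdims=True)


def _check_x(model: MLPModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.input_dim:
        raise ValueError(f"input must be 2-D with {model.input_dim} columns, got {x.shape}")
    return x


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Class probabilities, shape (n_rows, 2); rows sum to 1."""
    x = _check_x(model, x)
    a = x
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        a = relu(a @ w + b)
    logits = a @ model.weights[-1] + model.biases[-1]
    return _softmax(logits)


def predict_proba(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Probability of class 1 (association) per row."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    return forward(model, x)[:, 1]


def _forward_cache(model: MLPModel, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    activations = [x]
    a = x
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        a = relu(a @ w + b)
        activations.append(a)
    probs = _softmax(a @ model.weights[-1] + model.biases[-1])
    return activations, probs


def _loss_and_grads(
    model: MLPModel, x: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    n = x.shape[0]
    activations, probs = _forward_cache(model, x)
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads_w: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * len(model.biases)  # type: ignore[list-item]
    delta = dlogits
    for l in range(len(model.weights) - 1, -1, -1):
        grads_w[l] = activations[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ model.weights[l].T) * (activations[l] > 0)
    grads: list[np.ndarray] = []
    for gw, gb in zip(grads_w, grads_b):
        grads.extend([gw, gb])
    return loss, grads


def fit(x: np.ndarray, y: np.ndarray, config: MLPConfig) -> MLPModel:
    """Train on a feature matrix and binary label vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 2 or y.shape != (x.shape[0],):
        raise ValueError("x must be 2-D and y a matching label vector")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be binary")
    rng = np.random.default_rng(config.seed)
    sizes = (x.shape[1], *config.hidden_sizes, 2)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    model = MLPModel(weights=weights, biases=biases, config=config)
    params: list[np.ndarray] = []
    for w, b in zip(weights, biases):
        params.extend([w, b])
    opt = Adam(params, lr=config.learning_rate)
    for it in range(config.max_iter):
        loss, grads = _loss_and_grads(model, x, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"MLP loss became non-finite at iteration {it}")
        opt.step(grads)
    model.trained = True
    return model


def train_mlp(table: FeatureTable, config: MLPConfig) -> MLPModel:
    """Train the classifier on a fused feature table."""
    return fit(table.matrix, table.labels, config)
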