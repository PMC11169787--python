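"""Sparse autoencoder for latent features of the association matrix.

Single sigmoid hidden layer and sigmoid output layer. The training
objective is

    J = mean_i 0.5 * ||y(x_i) - x_i||^2  +  beta * sum_j KL(rho || rho_hat_j)

where ``rho_hat_j`` is the mean activation of hidden unit j over the batch
and KL is the Bernoulli Kullback-Leibler divergence (natural log). Trained
full-batch by Adam; deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam

_RHO_CLAMP = 1e-8


@dataclass(frozen=True)
class AEConfig:
    latent_dim: int = 128
    rho: float = 0.05
    beta: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate and epochs must be positive")


@dataclass
class AEModel:
    w_enc: np.ndarray
    b_enc: np.ndarray
    w_dec: np.ndarray
    b_dec: np.ndarray
    config: AEConfig

    def __post_init__(self) -> None:
        d, k = self.w_enc.shape
        if k != self.config.latent_dim:
            raise ValueError("encoder width does not match config.latent_dim")
        if self.w_dec.shape != (k, d):
            raise ValueError("decoder shape inconsistent with encoder")
        for arr in (self.w_enc, self.b_enc, self.w_dec, self.b_dec):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite model parameters")

    @property
    def input_dim(self) -> int:
        return self.w_enc.shape[0]


@dataclass
class LossTrace:
    """Per-epoch (reconstruction, sparsity, total) loss records."""

    reconstruction: list[float] = field(default_factory=list)
    sparsity: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)

    def append(self, recon: float, sparse: float, total: float) -> None:
        self.reconstruction.append(recon)
        self.sparsity.append(sparse)
        self.total.append(total)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check_input(model: AEModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.input_dim:
        raise ValueError(
            f"input must be 2-D with {model.input_dim} columns, got {x.shape}"
        )
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    return x


def encode(model: AEModel, x: np.ndarray) -> np.ndarray:
    """Hidden activations; shape (n_rows, latent_dim), entries in (0, 1)."""
    x = _check_input(model, x)
    return _sigmoid(x @ model.w_enc + model.b_enc)


def decode(model: AEModel, h: np.ndarray) -> np.ndarray:
    return _sigmoid(h @ model.w_dec + model.b_dec)


def reconstruction_loss(model: AEModel, x: np.ndarray) -> float:
    """Mean over samples of 0.5 * squared reconstruction error."""
    x = _check_input(model, x)
    y = decode(model, encode(model, x))
    return float(0.5 * np.square(y - x).sum(axis=1).mean())


def kl_bernoulli(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    rho_hat = np.clip(rho_hat, _RHO_CLAMP, 1.0 - _RHO_CLAMP)
    return rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log(
        (1.0 - rho) / (1.0 - rho_hat)
    )


def sparsity_penalty(model: AEModel, x: np.ndarray) -> float:
    """Sum over hidden units of KL(rho || mean activation)."""
    h = encode(model, x)
    return float(kl_bernoulli(model.config.rho, h.mean(axis=0)).sum())


def loss_and_grads(
    model: AEModel, x: np.ndarray
) -> tuple[float, float, float, list[np.ndarray]]:
    """Objective terms and analytic gradients w.r.t. (w_enc, b_enc, w_dec, b_dec)."""
    x = _check_input(model, x)
    cfg = model.config
    n = x.shape[0]

    h = _sigmoid(x @ model.w_enc + model.b_enc)
    y = _sigmoid(h @ model.w_dec + model.b_dec)

    residual = y - x
    recon = float(0.5 * np.square(residual).sum(axis=1).mean())
    rho_hat = np.clip(h.mean(axis=0), _RHO_CLAMP, 1.0 - _RHO_CLAMP)
    sparse = float(kl_bernoulli(cfg.rho, rho_hat).sum())
    total = recon + cfg.beta * sparse

    dz2 = (residual / n) * y * (1.0 - y)
    g_w_dec = h.T @ dz2
    g_b_dec = dz2.sum(axis=0)

    dh = dz2 @ model.w_dec.T
    if cfg.beta > 0:
        dkl = -cfg.rho / rho_hat + (1.0 - cfg.rho) / (1.0 - rho_hat)
        dh = dh + cfg.beta * dkl / n
    dz1 = dh * h * (1.0 - h)
    g_w_enc = x.T @ dz1
    g_b_enc = dz1.sum(axis=0)

    return recon, sparse, total, [g_w_enc, g_b_enc, g_w_dec, g_b_dec]


def _init_model(input_dim: int, config: AEConfig, rng: np.random.Generator) -> AEModel:
    k = config.latent_dim

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return AEModel(
        w_enc=glorot(input_dim, k),
        b_enc=np.zeros(k),
        w_dec=glorot(k, input_dim),
        b_dec=np.zeros(input_dim),
        config=config,
    )


def train_autoencoder(x: np.ndarray, config: AEConfig) -> tuple[AEModel, LossTrace]:
    """Minimize reconstruction + beta * sparsity by Adam.

    Full-batch by default; with ``batch_size`` set, samples are shuffled
    each epoch from the seeded generator and the trace records per-epoch
    batch-averaged losses.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("training input must be a 2-D matrix")
    if not np.isfinite(x).all():
        raise ValueError("non-finite training input")
    rng = np.random.default_rng(config.seed)
    model = _init_model(x.shape[1], config, rng)
    params = [model.w_enc, model.b_enc, model.w_dec, model.b_dec]
    opt = Adam(params, lr=config.learning_rate)
    trace = LossTrace()
    n = x.shape[0]
    batch = config.batch_size or n
    for epoch in range(config.epochs):
        if batch >= n:
            recon, sparse, total, grads = loss_and_grads(model, x)
            opt.step(grads)
            epoch_losses = [(recon, sparse, total)]
        else:
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, batch):
                xb = x[order[start : start + batch]]
                recon, sparse, total, grads = loss_and_grads(model, xb)
                opt.step(grads)
                epoch_losses.append((recon, sparse, total))
        means = [float(np.mean([e[i] for e in epoch_losses])) for i in range(3)]
        if not np.isfinite(means[2]):
            raise FloatingPointError(
                f"autoencoder loss became non-finite at epoch {epoch}"
            )
        trace.append(*means)
    return model, trace
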