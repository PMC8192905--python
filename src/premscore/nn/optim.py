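"""Loss, gradient clipping, Adam, and the learning-rate protocol.

The loss is the mean negative log-likelihood of the true classes plus an L2
penalty ``lambda / (2 N_b) * sum(w^2)`` over all weights except biases (and
batch-norm scale/shift).  Gradients are clipped by rescaling whenever the
global gradient norm exceeds the threshold ``theta``.  Weights are updated
with Adam using bias-corrected first and second moment estimates.

The learning rate is scheduled per training epoch: a linear warm-up from
``1e-7 * N_b`` to ``1e-6 * N_b`` over the first 12 epochs, then exponential
cool-down ``1e-6 * N_b * exp(-alpha * (i - 12))`` with ``alpha = 0.06``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError

__all__ = [
    "TrainConfig",
    "OptimizerState",
    "nll_l2_loss",
    "clip_gradients",
    "adam_update",
    "learning_rate",
]

_P_FLOOR = 1e-12  # probability clamp inside the log


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 256
    l2_lambda: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    clip_norm: float = 0.1
    warmup_epochs: int = 12
    lr_start_per_sample: float = 1e-7
    lr_peak_per_sample: float = 1e-6
    cooldown_rate: float = 0.06
    min_epochs: int = 12
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ConfigError("beta1, beta2 must lie in [0, 1)")
        if self.clip_norm <= 0:
            raise ConfigError("clip_norm must be positive")
        if self.min_epochs > self.max_epochs:
            raise ConfigError("min_epochs must not exceed max_epochs")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


def nll_l2_loss(probs: np.ndarray, targets: np.ndarray,
                weights: list[np.ndarray] | None = None,
                l2_lambda: float = 0.0) -> float:
    """Mean negative log-likelihood plus the L2 penalty.

    ``probs`` is (N_b, K) of score probabilities, ``targets`` the true class
    indices; ``weights`` are the decayed (non-bias) weight arrays.
    """
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets)
    n_b = len(targets)
    if n_b < 1:
        raise ConfigError("batch must contain at least one item")
    p_true = np.clip(probs[np.arange(n_b), targets], _P_FLOOR, None)
    loss = -np.mean(np.log(p_true))
    if weights and l2_lambda > 0:
        loss += l2_lambda / (2.0 * n_b) * sum(
            float(np.sum(np.asarray(w, dtype=np.float64) ** 2)) for w in weights
        )
    return float(loss)


def clip_gradients(grads, theta: float):
    """Rescale so the global L2 norm does not exceed ``theta``.

    Accepts a single array (returned as an array) or a list of arrays
    (clipped jointly by the norm of their concatenation).
    """
    single = isinstance(grads, np.ndarray)
    glist = [np.asarray(grads)] if single else [np.asarray(g) for g in grads]
    norm = math.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in glist))
    if norm <= theta or norm == 0.0:
        out = [g.copy() for g in glist]
    else:
        scale = theta / norm
        out = [g * scale for g in glist]
    return out[0] if single else out


@dataclass
class OptimizerState:
    """Per-weight Adam accumulators (first/second moments, step counter)."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros_like(cls, w: np.ndarray) -> "OptimizerState":
        return cls(m=np.zeros_like(w), v=np.zeros_like(w), t=0)


def adam_update(w: np.ndarray, g: np.ndarray, state: OptimizerState, eta: float,
                beta1: float = 0.9, beta2: float = 0.999,
                epsilon: float = 1e-8) -> tuple[np.ndarray, OptimizerState]:
    """One Adam step with bias-corrected moment estimates.

    Gradient clipping, if any, must already have been applied to ``g``.
    """
    t = state.t + 1
    m = (1.0 - beta1) * g + beta1 * state.m
    v = (1.0 - beta2) * g * g + beta2 * state.v
    m_hat = m / (1.0 - beta1**t)
    v_hat = v / (1.0 - beta2**t)
    w_new = w - eta * m_hat / (np.sqrt(v_hat) + epsilon)
    return w_new, OptimizerState(m=m, v=v, t=t)


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Per-epoch learning rate (epochs are 1-based).

    Linear warm-up from ``lr_start * N_b`` (epoch 1) to ``lr_peak * N_b``
    (epoch ``warmup_epochs``), then exponential cool-down.
    """
    if epoch < 1:
        raise ConfigError("training epochs are 1-based")
    n_b = cfg.batch_size
    if epoch <= cfg.warmup_epochs:
        frac = (epoch - 1) / max(1, cfg.warmup_epochs - 1)
        per_sample = cfg.lr_start_per_sample + frac * (
            cfg.lr_peak_per_sample - cfg.lr_start_per_sample
        )
        return n_b * per_sample
    return n_b * cfg.lr_peak_per_sample * math.exp(
        -cfg.cooldown_rate * (epoch - cfg.warmup_epochs)
    )
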