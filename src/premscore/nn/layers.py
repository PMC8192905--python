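"""Neural-network building blocks with explicit forward/backward passes.

Everything runs in float32 on the CPU.  Convolutions are "valid"
(no padding); that choice is load-bearing: it is the only padding mode under
which the stride pattern (1,2,1,2,1,2,1,2) maps a 1920-sample input to the
113 positions whose flattening gives the classifier its 10848 features.

Activations flow in channels-last layout (batch, length, channels) so the
im2col matrix and the GEMM operands are contiguous without transposes;
convolution weights are stored (out_channels, in_channels, kernel_len).

Each layer exposes ``forward(x, train=..., rng=...)``, ``backward(dout)``
and ``params()``; parameters carry a ``decay`` flag so the L2 penalty can
exclude biases and batch-norm parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "Flatten",
    "Linear",
    "softmax",
]

DTYPE = np.float32


class Param:
    """A learnable array with its gradient and weight-decay eligibility."""

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool, name: str):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Valid (unpadded) 1-D convolution, stride >= 1, He-initialised.

    Input/output are (batch, length, channels); weights (out, in, kernel).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_len: int, stride: int,
                 rng: np.random.Generator, name: str = "conv"):
        std = np.sqrt(2.0 / (in_ch * kernel_len))
        self.W = Param(rng.normal(0.0, std, (out_ch, in_ch, kernel_len)),
                       decay=True, name=f"{name}.W")
        self.b = Param(np.zeros(out_ch), decay=False, name=f"{name}.b")
        self.stride = stride
        self.kernel_len = kernel_len
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _shifted(self, x: np.ndarray, t: int, l_out: int) -> np.ndarray:
        # view of the t-th tap's input positions: (N, L_out, C)
        s = self.stride
        return x[:, t : t + s * (l_out - 1) + 1 : s, :]

    def forward(self, x, *, train=False, rng=None):
        # shift-and-sum convolution: one (C x O) GEMM per kernel tap, no im2col
        k, s = self.kernel_len, self.stride
        n, length, c = x.shape
        l_out = (length - k) // s + 1
        o = self.W.value.shape[0]
        out = np.empty((n, l_out, o), dtype=x.dtype)
        out[...] = self.b.value
        for t in range(k):
            out += self._shifted(x, t, l_out) @ self.W.value[:, :, t].T
        self._cache = (x, l_out)
        return out

    def backward(self, dout):
        x, l_out = self._cache
        k, s = self.kernel_len, self.stride
        dx = np.zeros_like(x)
        for t in range(k):
            xv = self._shifted(x, t, l_out)
            self.W.grad[:, :, t] = np.tensordot(dout, xv, axes=([0, 1], [0, 1]))
            dx[:, t : t + s * (l_out - 1) + 1 : s, :] += dout @ np.ascontiguousarray(
                self.W.value[:, :, t])
        self.b.grad[...] = dout.sum(axis=(0, 1))
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length) of (N, L, C) input."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(n_channels), decay=False, name=f"{name}.gamma")
        self.beta = Param(np.zeros(n_channels), decay=False, name=f"{name}.beta")
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, *, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 1))
            xc = x - mean
            var = np.mean(xc * xc, axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = xc
            xhat *= inv_std
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dout):
        xhat, inv_std = self._cache
        self.gamma.grad[...] = (dout * xhat).sum(axis=(0, 1))
        self.beta.grad[...] = dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        term = (
            dxhat
            - dxhat.mean(axis=(0, 1), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 1), keepdims=True)
        )
        term *= inv_std
        return term


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, *, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "fc"):
        std = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, std, (n_in, n_out)), decay=True,
                       name=f"{name}.W")
        self.b = Param(np.zeros(n_out), decay=False, name=f"{name}.b")
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad[...] = self._x.T @ dout
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
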