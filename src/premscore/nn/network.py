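"""The sleep-staging network: convolutional feature extractor + classifier.

Architecture (defaults in parentheses):

* input batch normalisation of the single EEG channel,
* 8 convolutional layers of 96 kernels of width 5, valid convolutions,
  strides alternating (1, 2, 1, 2, 1, 2, 1, 2); each block is
  conv -> ReLU -> batchnorm, with dropout (p = 0.2) on every second block,
* flatten (113 positions x 96 kernels = 10848 features under defaults),
  dropout,
* fully connected hidden layer of 80 ReLU units with dropout,
* fully connected output layer with softmax over 3 or 5 stages.

The predicted stage is the argmax of the score probabilities, with the
lowest class index winning ties.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..errors import ConfigError
from .layers import (
    DTYPE,
    BatchNorm1d,
    Conv1d,
    Dropout,
    Flatten,
    Layer,
    Linear,
    Param,
    ReLU,
    softmax,
)

__all__ = ["ModelConfig", "conv_output_lengths", "SleepNet", "build_network"]


@dataclass(frozen=True)
class ModelConfig:
    n_kernels: int = 96
    kernel_len: int = 5
    n_conv_layers: int = 8
    stride_pattern: tuple[int, ...] = (1, 2, 1, 2, 1, 2, 1, 2)
    p_dropout: float = 0.2
    fc_hidden: int = 80
    num_classes: int = 5
    input_len: int = 1920

    def __post_init__(self) -> None:
        if len(self.stride_pattern) != self.n_conv_layers:
            raise ConfigError("stride_pattern length must equal n_conv_layers")
        if self.num_classes not in (3, 5):
            raise ConfigError("num_classes must be 3 or 5")
        if not (0.0 <= self.p_dropout < 1.0):
            raise ConfigError("p_dropout must lie in [0, 1)")

    @property
    def flatten_width(self) -> int:
        lengths = conv_output_lengths(self.input_len, self.kernel_len,
                                      self.stride_pattern)
        return lengths[-1] * self.n_kernels


def conv_output_lengths(input_len: int, kernel_len: int,
                        stride_pattern) -> list[int]:
    """Per-layer output lengths of the valid-convolution chain:
    ``L_out = floor((L_in - kernel_len) / stride) + 1``."""
    lengths = []
    length = input_len
    for stride in stride_pattern:
        if length < kernel_len:
            raise ConfigError(
                f"intermediate length {length} < kernel length {kernel_len}"
            )
        length = (length - kernel_len) // stride + 1
        lengths.append(length)
    return lengths


class SleepNet:
    """Feature extractor + classifier over (N, input_len) batches.

    ``classes_`` maps output neurons to stage codes; output neuron ``j``
    scores stage ``classes_[j]``.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int | None = None,
                 classes: np.ndarray | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        if classes is None:
            classes = np.arange(cfg.num_classes)
        classes = np.asarray(classes, dtype=np.int64)
        if len(classes) != cfg.num_classes:
            raise ConfigError("classes must have num_classes entries")
        self.classes_ = classes

        layers: list[Layer] = [BatchNorm1d(1, name="bn_in")]
        in_ch = 1
        for i, stride in enumerate(cfg.stride_pattern):
            layers.append(Conv1d(in_ch, cfg.n_kernels, cfg.kernel_len, stride,
                                 rng, name=f"conv{i + 1}"))
            layers.append(ReLU())
            layers.append(BatchNorm1d(cfg.n_kernels, name=f"bn{i + 1}"))
            if (i + 1) % 2 == 0:
                layers.append(Dropout(cfg.p_dropout))
            in_ch = cfg.n_kernels
        layers.append(Flatten())
        layers.append(Dropout(cfg.p_dropout))
        layers.append(Linear(cfg.flatten_width, cfg.fc_hidden, rng, name="fc1"))
        layers.append(ReLU())
        layers.append(Dropout(cfg.p_dropout))
        layers.append(Linear(cfg.fc_hidden, cfg.num_classes, rng, name="fc2"))
        self.layers = layers

    # ------------------------------------------------------------------
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, X: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a (N, input_len) batch."""
        if X.ndim != 2 or X.shape[1] != self.cfg.input_len:
            raise ConfigError(
                f"expected input of shape (N, {self.cfg.input_len}), got {X.shape}"
            )
        h = np.ascontiguousarray(X, dtype=DTYPE)[:, :, None]
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(DTYPE)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Score probabilities in evaluation mode (dropout off,
        batchnorm running statistics)."""
        out = []
        for i in range(0, len(X), batch_size):
            out.append(softmax(self.forward(X[i : i + batch_size], train=False)))
        return np.concatenate(out) if out else np.zeros((0, self.cfg.num_classes))

    def predict(self, X: np.ndarray, batch_size: int = 256
                ) -> tuple[np.ndarray, np.ndarray]:
        """Return (probabilities, predicted stage codes)."""
        probs = self.predict_proba(X, batch_size)
        return probs, self.classes_[np.argmax(probs, axis=1)]

    # ------------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        extras = iter(state[len(params) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = next(extras)
                layer.running_var[...] = next(extras)

    # ------------------------------------------------------------------
    def save(self, path) -> Path:
        """Checkpoint: npz of weights + JSON-encoded config and class codes."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps({
            "config": {**asdict(self.cfg),
                       "stride_pattern": list(self.cfg.stride_pattern)},
            "classes": self.classes_.tolist(),
            "format_version": 1,
        })
        arrays = {f"arr{i:03d}": a for i, a in enumerate(self.get_weights())}
        np.savez(path, meta=np.array(meta), **arrays)
        return path

    @classmethod
    def load(cls, path) -> "SleepNet":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg_d = meta["config"]
            cfg_d["stride_pattern"] = tuple(cfg_d["stride_pattern"])
            cfg = ModelConfig(**cfg_d)
            net = cls(cfg, rng=0, classes=np.array(meta["classes"]))
            n = len([k for k in data.files if k.startswith("arr")])
            net.set_weights([data[f"arr{i:03d}"] for i in range(n)])
        return net


def build_network(cfg: ModelConfig, rng=None, classes=None) -> SleepNet:
    """Construct an initialised network from a configuration."""
    return SleepNet(cfg, rng=rng, classes=classes)
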