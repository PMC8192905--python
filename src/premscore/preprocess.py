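"""Signal conditioning and context-window construction.

The classifier consumes 30 s of signal (three consecutive 10-s epochs) at
64 Hz.  Raw recordings are therefore (1) low-pass filtered with a 4th-order
Butterworth at 25.6 Hz, applied forward and backward so the net phase shift
is zero and the effective magnitude response is the squared single-pass
response, (2) downsampled to 64 Hz by linear interpolation on the grid
``t_k = k / fs_out`` anchored at t = 0, and (3) cut into 10-s epochs of 640
samples each.

Filtering precedes resampling (resampling first would alias), and epoching
happens after resampling so the non-integer samples-per-epoch of native
rates like 992.06 Hz never arises.

The window for epoch ``k`` spans epochs (k-1, k, k+1) and is labeled with
epoch k's stage.  At the recording boundaries the missing neighbor epoch is
replaced by a copy of the edge epoch, so every scored epoch receives a
prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import AlignmentError, ConfigError, DataError
from .io import Hypnogram, Recording

__all__ = [
    "PreprocessConfig",
    "ContextWindow",
    "antialias_filter",
    "resample_linear",
    "preprocess_recording",
    "make_windows",
    "windows_to_array",
]


@dataclass(frozen=True)
class PreprocessConfig:
    filter_order: int = 4
    critical_hz: float = 25.6
    target_fs: float = 64.0
    epoch_len_s: float = 10.0
    context_epochs: int = 3

    def __post_init__(self) -> None:
        for name in ("filter_order", "critical_hz", "target_fs", "epoch_len_s",
                     "context_epochs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.context_epochs % 2 != 1:
            raise ConfigError("context_epochs must be odd (centered window)")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_len_s * self.target_fs))

    @property
    def window_len(self) -> int:
        """T, the network input length (1920 under defaults)."""
        return self.context_epochs * self.samples_per_epoch


@dataclass
class ContextWindow:
    """Three consecutive preprocessed epochs with the middle epoch's label.

    ``source`` is the preprocessed recording extended by one replicated
    epoch at each end, and ``start`` is the window's offset inside it, so
    augmentation operators can pull samples beyond the window.
    """

    signal: np.ndarray
    label: int
    center_epoch: int
    source: np.ndarray
    start: int

    def gather(self, positions: np.ndarray) -> np.ndarray:
        """Source samples at ``positions`` with edge-sample replication."""
        idx = np.clip(positions, 0, len(self.source) - 1)
        return self.source[idx]


def antialias_filter(x: np.ndarray, fs: float,
                     cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward and backward pass).

    Edge transients are controlled by odd-reflection padding of length
    ``3 * (filter_order + 1)``; the magnitude contract holds on interior
    samples.
    """
    x = np.asarray(x, dtype=np.float64)
    padlen = 3 * (cfg.filter_order + 1)
    if len(x) <= padlen:
        raise DataError(
            f"signal of {len(x)} samples too short to filter (need > {padlen})"
        )
    b, a = sps.butter(cfg.filter_order, cfg.critical_hz, btype="lowpass", fs=fs)
    return sps.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def resample_linear(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Linear-interpolation resampling on the grid ``k / fs_out``.

    Output length is ``floor((len(x) - 1) * fs_out / fs_in) + 1`` — every
    output time lies inside the input's time support.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ConfigError("sampling rates must be positive")
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0:
        raise DataError("cannot resample an empty signal")
    n_out = int(math.floor((len(x) - 1) * fs_out / fs_in + 1e-9)) + 1
    t_out = np.arange(n_out) / fs_out
    t_in = np.arange(len(x)) / fs_in
    return np.interp(t_out, t_in, x)


def preprocess_recording(rec: Recording,
                         cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Anti-alias filter at the native rate, then resample to ``target_fs``."""
    filtered = antialias_filter(rec.samples, rec.fs, cfg)
    resampled = resample_linear(filtered, rec.fs, cfg.target_fs)
    return Recording(samples=resampled, fs=cfg.target_fs,
                     subject_id=rec.subject_id, channel=rec.channel)


def make_windows(rec: Recording, hyp: Hypnogram,
                 cfg: PreprocessConfig = PreprocessConfig()) -> list[ContextWindow]:
    """One context window per scored epoch of an already-preprocessed recording."""
    if abs(rec.fs - cfg.target_fs) > 1e-9:
        raise ConfigError(
            f"recording is at {rec.fs} Hz; preprocess to {cfg.target_fs} Hz first"
        )
    spe = cfg.samples_per_epoch
    n_epochs = int(math.floor(len(rec.samples) / spe + 1e-9))
    if n_epochs != len(hyp):
        raise AlignmentError(
            f"recording holds {n_epochs} whole epochs but hypnogram has {len(hyp)}"
        )
    if n_epochs == 0:
        return []
    x = rec.samples[: n_epochs * spe]
    half = (cfg.context_epochs - 1) // 2
    # replicate the edge epochs so boundary windows keep full context
    ext = np.concatenate([np.tile(x[:spe], half), x, np.tile(x[-spe:], half)])
    windows = []
    for k in range(n_epochs):
        start = k * spe
        windows.append(
            ContextWindow(
                signal=ext[start : start + cfg.window_len],
                label=int(hyp.labels[k]),
                center_epoch=k,
                source=ext,
                start=start,
            )
        )
    return windows


def windows_to_array(windows: list[ContextWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack window signals into (N, T) float32 plus the label vector."""
    X = np.stack([w.signal for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows], dtype=np.int64)
    return X, y
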