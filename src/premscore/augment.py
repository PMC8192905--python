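"""Stochastic training-time augmentation of context windows.

Four transforms, each with a strength in [0, 1], emulate nuisance
variability of EEG acquisition:

* **amplitude scaling** — ``s* = s * (1 + a_a * u)``, u ~ U[-1, 1): gain
  differences between amplifier settings;
* **sign flip** — ``s* = -s`` with probability ``a_s``: montage polarity;
* **window warping** — a temporary series of length ``T* = floor(T * (1 +
  a_f * u))`` sharing the original central sample is linearly resampled back
  to length T, shifting apparent frequencies by the factor ``T*/T``;
* **time shift** — the window is moved by ``dt = floor(T * a_t * u)``
  samples within its source recording, so stage boundaries stop aligning
  with window boundaries.

Transforms are applied in the order amplitude, sign flip, warp, shift, with
fresh uniform draws every time a window enters the network.  Samples needed
beyond the source recording are obtained by edge replication.  Each operator
takes its uniform draw ``u`` as an explicit argument so the formulas are
testable deterministically; only the composite consumes an RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .preprocess import ContextWindow

__all__ = [
    "AugmentationParams",
    "augment_amplitude",
    "augment_signflip",
    "augment_frequency",
    "augment_timeshift",
    "augment_with_draws",
    "augment",
]


@dataclass(frozen=True)
class AugmentationParams:
    """Strengths of the four transforms; 0 disables a transform."""

    a_a: float = 0.0
    a_f: float = 0.0
    a_s: float = 0.0
    a_t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_a", "a_f", "a_s", "a_t"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

    @property
    def any_active(self) -> bool:
        return any((self.a_a, self.a_f, self.a_s, self.a_t))


def augment_amplitude(s: np.ndarray, a_a: float, u: float) -> np.ndarray:
    """Scale the whole series by ``1 + a_a * u`` (u in [-1, 1))."""
    return np.asarray(s) * (1.0 + a_a * u)


def augment_signflip(s: np.ndarray, a_s: float, u: float) -> np.ndarray:
    """Negate the series iff ``u < a_s`` (u in [0, 1))."""
    s = np.asarray(s)
    return -s if u < a_s else s.copy()


def _warped_length(T: int, a_f: float, u: float) -> int:
    return int(math.floor(T * (1.0 + a_f * u)))


def _resample_to_length(temp: np.ndarray, T: int) -> np.ndarray:
    T_star = len(temp)
    if T_star == T:
        return temp.copy()
    grid = np.linspace(0.0, T_star - 1, T)
    return np.interp(grid, np.arange(T_star), temp)


def augment_frequency(w: ContextWindow, a_f: float, u: float) -> np.ndarray:
    """Window warping: resample a length-``T*`` series around the window center
    back to length T, shifting frequencies by ``T*/T``."""
    T = len(w.signal)
    T_star = _warped_length(T, a_f, u)
    if T_star == T:
        return w.signal.copy()
    offset = (T - T_star) // 2  # keeps the central sample (up to parity) shared
    temp = w.gather(w.start + offset + np.arange(T_star))
    return _resample_to_length(temp, T)


def augment_timeshift(w: ContextWindow, a_t: float, u: float) -> np.ndarray:
    """Shift the window by ``dt = floor(T * a_t * u)`` samples in its source."""
    T = len(w.signal)
    dt = int(math.floor(T * a_t * u))
    if dt == 0:
        return w.signal.copy()
    return w.gather(w.start + dt + np.arange(T))


def augment_with_draws(w: ContextWindow, p: AugmentationParams,
                       u_a: float, u_s: float, u_f: float, u_t: float) -> np.ndarray:
    """Apply the full composite for fixed uniform draws.

    Amplitude and sign flip are pointwise scalings, so they commute with the
    two resampling transforms; warp and shift are composed in source-position
    space (the shift moves the temporary series within the recording before
    it is warped back to length T), which keeps both operators exact.
    """
    T = len(w.signal)
    scale = (1.0 + p.a_a * u_a) * (-1.0 if u_s < p.a_s else 1.0)
    T_star = _warped_length(T, p.a_f, u_f)
    dt = int(math.floor(T * p.a_t * u_t))
    if T_star == T and dt == 0:
        sig = w.signal.copy()
    elif T_star == T:
        sig = w.gather(w.start + dt + np.arange(T))
    else:
        offset = (T - T_star) // 2
        temp = w.gather(w.start + offset + dt + np.arange(T_star))
        sig = _resample_to_length(temp, T)
    return scale * sig


def augment(w: ContextWindow, p: AugmentationParams,
            rng: np.random.Generator) -> np.ndarray:
    """Composite augmentation with fresh draws, in the order
    amplitude -> sign flip -> warp -> shift."""
    u_a = rng.uniform(-1.0, 1.0)
    u_s = rng.uniform(0.0, 1.0)
    u_f = rng.uniform(-1.0, 1.0)
    u_t = rng.uniform(-1.0, 1.0)
    return augment_with_draws(w, p, u_a, u_s, u_f, u_t)
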