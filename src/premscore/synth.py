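"""Synthetic stage-labeled EEG.

Real mouse polysomnography is rarely shareable, so this module generates
recordings whose epochs carry the spectral signatures a sleep-staging
classifier must exploit:

* **Wake** — low-amplitude broadband (pink-noise) activity,
* **NREM** — dominant slow waves in the 0.5-4 Hz delta band,
* **REM** — rhythmic 7-8 Hz theta activity,
* **pre-REM** — NREM-like delta background with an emerging theta component
  and short (<10 s) spindle-like high-amplitude bursts (10-15 Hz carrier
  under a smooth envelope),
* **artifact** — wake-like background plus at least one clipped
  high-amplitude spike transient.

Stage sequences come from a first-order Markov chain whose default
transition matrix enforces the physiological cycle (Wake <-> NREM,
NREM -> pre-REM -> REM -> Wake, near-zero direct NREM -> REM) and whose
stationary distribution approximates the class frequencies seen in mouse
datasets (Wake ~55 %, NREM ~38 %, REM ~5 %, pre-REM ~2 %, artifact ~0.3 %).
All numeric defaults are synthetic choices, not measured mouse statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .io import Hypnogram, Recording, write_hypnogram, write_recording
from .stages import ALL_STAGES, Stage

__all__ = [
    "StageSignalModel",
    "HypnogramModel",
    "DEFAULT_SIGNAL_MODELS",
    "DEFAULT_HYPNOGRAM_MODEL",
    "generate_hypnogram",
    "synthesize_epoch",
    "generate_recording",
    "generate_dataset",
]


@dataclass(frozen=True)
class StageSignalModel:
    """Spectral recipe for one stage.

    Amplitudes are microvolt RMS of the respective component; ``band_hz``
    is the oscillation band, ``burst_*`` parameters describe transient
    events (spindle-like bursts for pre-REM, spikes for artifact) and
    ``theta_amp`` adds the emerging-theta component of pre-REM.
    """

    band_hz: tuple[float, float] = (0.5, 4.0)
    osc_amp: float = 0.0
    noise_amp: float = 0.0
    burst_rate: float = 0.0  # expected events per epoch
    burst_len_s: float = 0.0
    burst_amp: float = 0.0
    theta_amp: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ConfigError(f"invalid band {self.band_hz}")
        for name in ("osc_amp", "noise_amp", "burst_rate", "burst_amp", "theta_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.burst_len_s < 10):
            raise ConfigError("burst_len_s must lie in [0, 10) seconds")


DEFAULT_SIGNAL_MODELS: dict[Stage, StageSignalModel] = {
    Stage.WAKE: StageSignalModel(band_hz=(0.5, 4.0), osc_amp=0.0, noise_amp=30.0),
    Stage.NREM: StageSignalModel(band_hz=(0.5, 4.0), osc_amp=120.0, noise_amp=20.0),
    Stage.REM: StageSignalModel(band_hz=(7.0, 8.0), osc_amp=70.0, noise_amp=15.0),
    Stage.PREREM: StageSignalModel(
        band_hz=(0.5, 4.0),
        osc_amp=60.0,
        noise_amp=20.0,
        theta_amp=40.0,
        burst_rate=2.0,
        burst_len_s=1.5,
        burst_amp=150.0,
    ),
    Stage.ARTIFACT: StageSignalModel(
        band_hz=(0.5, 4.0),
        osc_amp=0.0,
        noise_amp=30.0,
        burst_rate=1.5,
        burst_len_s=0.08,
        burst_amp=600.0,
    ),
}

#: fraction of the artifact spike amplitude at which the signal is clipped
_ARTIFACT_CLIP_FRACTION = 0.75


@dataclass(frozen=True)
class HypnogramModel:
    """First-order Markov model over the five stages (code order)."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=np.float64)
        p0 = np.asarray(self.initial_distribution, dtype=np.float64)
        k = len(ALL_STAGES)
        if P.shape != (k, k) or p0.shape != (k,):
            raise ConfigError(f"expected {k}x{k} matrix and length-{k} vector")
        if (P < 0).any() or (p0 < 0).any():
            raise ConfigError("probabilities must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("transition matrix rows must sum to 1")
        if not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ConfigError("initial distribution must sum to 1")
        object.__setattr__(self, "transition_matrix", P)
        object.__setattr__(self, "initial_distribution", p0)

    def stationary_distribution(self) -> np.ndarray:
        w, v = np.linalg.eig(self.transition_matrix.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        return pi / pi.sum()


# rows/columns in Stage code order: WAKE, NREM, PREREM, REM, ARTIFACT.
# Stationary distribution ~ (0.553, 0.376, 0.019, 0.050, 0.003).
_DEFAULT_TRANSITIONS = np.array(
    [
        [0.960, 0.037, 0.000, 0.000, 0.003],
        [0.037, 0.930, 0.030, 0.001, 0.002],
        [0.080, 0.220, 0.400, 0.300, 0.000],
        [0.100, 0.020, 0.000, 0.880, 0.000],
        [0.700, 0.280, 0.000, 0.000, 0.020],
    ]
)

DEFAULT_HYPNOGRAM_MODEL = HypnogramModel(
    transition_matrix=_DEFAULT_TRANSITIONS,
    initial_distribution=np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_hypnogram(model: HypnogramModel, n_epochs: int, seed) -> Hypnogram:
    """Sample a stage sequence of length ``n_epochs`` from the Markov model."""
    if n_epochs < 0:
        raise ConfigError("n_epochs must be >= 0")
    rng = _as_rng(seed)
    cum = np.cumsum(model.transition_matrix, axis=1)
    labels = np.empty(n_epochs, dtype=np.int64)
    if n_epochs == 0:
        return Hypnogram(labels=labels)
    u = rng.random(n_epochs)
    labels[0] = np.searchsorted(np.cumsum(model.initial_distribution), u[0], side="right")
    for t in range(1, n_epochs):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t], side="right")
    return Hypnogram(labels=np.minimum(labels, len(ALL_STAGES) - 1))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = np.inf  # kill DC
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _band_oscillation(n: int, band: tuple[float, float], fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise (4th-order Butterworth bandpass)."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synthesize_epoch(stage: Stage, model: StageSignalModel, fs: float,
                     duration_s: float = 10.0, seed=None) -> np.ndarray:
    """Synthesize one labeled epoch of EEG at rate ``fs``."""
    if fs <= 2 * model.band_hz[1]:
        raise ConfigError(
            f"fs={fs} violates Nyquist for band {model.band_hz}"
        )
    rng = _as_rng(seed)
    n = int(round(fs * duration_s))
    x = np.zeros(n)
    if model.noise_amp > 0:
        x += model.noise_amp * _pink_noise(n, rng)
    if model.osc_amp > 0:
        x += model.osc_amp * _band_oscillation(n, model.band_hz, fs, rng)
    if model.theta_amp > 0:
        x += model.theta_amp * _band_oscillation(n, (6.5, 8.5), fs, rng)

    if stage == Stage.PREREM and model.burst_amp > 0 and model.burst_rate > 0:
        n_bursts = max(1, rng.poisson(model.burst_rate))
        blen = max(2, int(round(model.burst_len_s * fs)))
        for _ in range(n_bursts):
            start = rng.integers(0, max(1, n - blen))
            t = np.arange(blen) / fs
            carrier = np.sin(2 * np.pi * rng.uniform(10.0, 15.0) * t + rng.uniform(0, 2 * np.pi))
            x[start : start + blen] += model.burst_amp * np.hanning(blen) * carrier

    if stage == Stage.ARTIFACT and model.burst_amp > 0 and model.burst_rate > 0:
        n_spikes = max(1, rng.poisson(model.burst_rate))
        blen = max(2, int(round(model.burst_len_s * fs)))
        for _ in range(n_spikes):
            start = rng.integers(0, max(1, n - blen))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            x[start : start + blen] += sign * model.burst_amp * np.hanning(blen)
        clip = _ARTIFACT_CLIP_FRACTION * model.burst_amp
        x = np.clip(x, -clip, clip)

    return x


def generate_recording(hyp: Hypnogram, sig_models: dict[Stage, StageSignalModel],
                       fs: float, seed, subject_id: str = "synth") -> Recording:
    """Concatenate per-epoch synthetic signals following a hypnogram."""
    rng = _as_rng(seed)
    epochs = [
        synthesize_epoch(Stage(code), sig_models[Stage(code)], fs,
                         hyp.epoch_len_s, seed=rng)
        for code in hyp.labels
    ]
    samples = np.concatenate(epochs) if epochs else np.zeros(0)
    return Recording(samples=samples, fs=fs, subject_id=subject_id)


def generate_dataset(out_dir, n_epochs: int, n_subjects: int, seed: int,
                     fs: float = 992.0,
                     hyp_model: HypnogramModel = DEFAULT_HYPNOGRAM_MODEL,
                     sig_models: dict[Stage, StageSignalModel] | None = None,
                     fmt: str = "raw") -> list[tuple[Path, Path]]:
    """Write one synthetic recording + aligned hypnogram per subject.

    Each subject gets an independent random stream derived from ``seed``,
    so outputs are byte-identical across runs with the same seed.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    if sig_models is None:
        sig_models = DEFAULT_SIGNAL_MODELS
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".edf" if fmt == "edf" else ".raw"
    paths = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subject = f"synth{i:02d}"
        hyp = generate_hypnogram(hyp_model, n_epochs, rng)
        rec = generate_recording(hyp, sig_models, fs, rng, subject_id=subject)
        rec_path = write_recording(out_dir / f"{subject}{suffix}", rec)
        hyp_path = write_hypnogram(out_dir / f"{subject}.csv", hyp)
        paths.append((rec_path, hyp_path))
    return paths
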