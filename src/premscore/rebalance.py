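"""Class rebalancing by per-epoch resampling with replacement.

Sleep stages are heavily imbalanced (Wake ~55 % vs pre-REM ~2 %), which
biases gradient training toward majority classes.  Before every training
epoch a fresh index multiset of (approximately) the original size N is drawn:
for each class ``c`` with target frequency ``f_c``, exactly
``round_half_away(f_c * N)`` indices are sampled with replacement from the
positions of class ``c``.

Two named profiles ship with the package: ``reb1`` for 5-class training
(Wake .30 / REM .18 / NREM .24 / pre-REM .14 / artifact .14) and ``reb2``
for 3-class training (Wake .41 / REM .25 / NREM .34).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ConfigError, DataError
from .stages import Stage

__all__ = [
    "RebalanceSpec",
    "REB1",
    "REB2",
    "PROFILES",
    "round_half_away",
    "rebalance_indices",
    "make_training_view",
]


def round_half_away(x: float) -> int:
    """Round to nearest with .5 away from zero (for non-negative x)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RebalanceSpec:
    """Target class frequencies; the total segment count is preserved."""

    target_freq: dict[Stage, float]
    preserve_total: bool = True

    def __post_init__(self) -> None:
        freqs = {Stage(k): float(v) for k, v in self.target_freq.items()}
        if any(v < 0 for v in freqs.values()):
            raise ConfigError("target frequencies must be >= 0")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ConfigError("target frequencies must sum to 1")
        object.__setattr__(self, "target_freq", freqs)

    @classmethod
    def from_empirical(cls, labels: np.ndarray) -> "RebalanceSpec":
        labels = np.asarray(labels)
        n = len(labels)
        freq = {Stage(c): int((labels == c).sum()) / n for c in np.unique(labels)}
        return cls(target_freq=freq)


REB1 = RebalanceSpec(
    target_freq={
        Stage.WAKE: 0.30,
        Stage.REM: 0.18,
        Stage.NREM: 0.24,
        Stage.PREREM: 0.14,
        Stage.ARTIFACT: 0.14,
    }
)

REB2 = RebalanceSpec(
    target_freq={Stage.WAKE: 0.41, Stage.REM: 0.25, Stage.NREM: 0.34}
)

PROFILES = {"reb1": REB1, "reb2": REB2}


def rebalance_indices(labels: np.ndarray, spec: RebalanceSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw one rebalanced index multiset over ``labels``.

    Returns a concatenation of per-class draws (unshuffled); the caller
    shuffles.  A class with positive target but no support raises.
    """
    labels = np.asarray(labels)
    n = len(labels)
    parts = []
    for stage in sorted(spec.target_freq, key=int):
        f = spec.target_freq[stage]
        if f == 0:
            continue
        positions = np.flatnonzero(labels == int(stage))
        if len(positions) == 0:
            raise DataError(
                f"class {stage.name} has target frequency {f} but no segments"
            )
        count = round_half_away(f * n)
        parts.append(rng.choice(positions, size=count, replace=True))
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def make_training_view(labels: np.ndarray, spec: RebalanceSpec | None,
                       rng: np.random.Generator) -> Iterator[np.ndarray]:
    """Yield a freshly resampled, shuffled index multiset per training epoch.

    With ``spec=None`` each epoch is a plain shuffle of all indices
    (no rebalancing baseline).
    """
    labels = np.asarray(labels)
    while True:
        if spec is None:
            idx = np.arange(len(labels))
        else:
            idx = rebalance_indices(labels, spec, rng)
        rng.shuffle(idx)
        yield idx
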