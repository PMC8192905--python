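"""Reduced-scale reference experiments on synthetic data.

The full-size study (hundreds of thousands of 10-s epochs, 50 training
epochs of a 96-kernel network) is far beyond a desk-scale CPU run, so this
module defines a scaled-down surrogate used by the test suite and the
reproduction script: a few thousand synthetic epochs from the default
generator, a narrower (32-kernel) network of otherwise identical
architecture, and a short training schedule.  The synthetic classes are
spectrally separable by construction, so the surrogate checks that the whole
pipeline — preprocessing, rebalancing, augmentation, training, evaluation —
learns, not that it reaches the accuracy attainable on real mouse data.
"""

from __future__ import annotations

from pathlib import Path

from .augment import AugmentationParams
from .nn.network import ModelConfig
from .nn.optim import TrainConfig
from .pipeline import RunConfig, run_experiment

__all__ = ["surrogate_config", "run_surrogate"]

#: epochs per synthetic subject; 4 train + 1 validation + 1 test subjects
N_EPOCHS_PER_SUBJECT = 600
SYNTH_FS = 128.0
N_KERNELS = 32


def surrogate_config(seed: int, out_dir, mode: str = "standard3",
                     rebalance_profile: str = "default",
                     max_epochs: int | None = None, min_epochs: int | None = None,
                     patience: int = 5,
                     augmentation: AugmentationParams | None = None) -> RunConfig:
    """Configuration of the scaled-down synthetic experiment.

    The 3-class surrogate trains without augmentation (the best-performing
    3-class configuration needs none); the 5-class surrogate defaults to
    time-shift augmentation ``a_t = 0.06``, the configuration that most
    helps the scarce pre-REM class, and a longer schedule — with only a few
    dozen unique pre-REM windows at this scale, minority-class learning
    starts only once the warm-up learning rate has ramped up.
    """
    five = mode == "extended5"
    if augmentation is None:
        augmentation = AugmentationParams(a_t=0.06 if five else 0.0)
    if max_epochs is None:
        max_epochs = 15 if five else 8
    if min_epochs is None:
        min_epochs = 6 if five else 3
    return RunConfig(
        seed=seed,
        out_dir=str(out_dir),
        mode=mode,
        data={"synthetic": {"n_epochs": N_EPOCHS_PER_SUBJECT, "fs": SYNTH_FS}},
        split={
            "train": ["s0", "s1", "s2", "s3"],
            "validation": ["s4"],
            "test": ["s5"],
        },
        rebalance_profile=rebalance_profile,
        augmentation=augmentation,
        model=ModelConfig(n_kernels=N_KERNELS),
        train=TrainConfig(min_epochs=min_epochs, max_epochs=max_epochs,
                          patience=patience),
    )


def run_surrogate(seed: int, out_dir, **kwargs) -> dict:
    """Run one surrogate experiment; returns ``run_experiment`` artifacts."""
    cfg = surrogate_config(seed, Path(out_dir), **kwargs)
    return run_experiment(cfg)
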