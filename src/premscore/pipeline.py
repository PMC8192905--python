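"""End-to-end orchestration: generate -> preprocess -> train -> predict -> evaluate.

A single :class:`RunConfig` (typically a YAML file) is the source of truth
for one experiment.  All randomness derives from its seed, so a run is
reproducible; the effective configuration is archived next to the outputs.

Two target-stage modes exist: ``extended5`` trains on all five stages with
the ``reb1`` rebalancing profile; ``standard3`` reinterprets pre-REM as
NREM, removes artifact epochs, trains 3 output neurons and uses ``reb2``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentationParams
from .errors import ConfigError
from .evaluation import confusion, markov_matrix
from .io import (
    DatasetSplit,
    Hypnogram,
    Recording,
    check_disjoint,
    read_hypnogram,
    read_recording,
    write_hypnogram,
)
from .nn.network import ModelConfig, SleepNet
from .nn.optim import TrainConfig
from .preprocess import PreprocessConfig, make_windows, preprocess_recording
from .rebalance import PROFILES, RebalanceSpec
from .stages import ALL_STAGES, STANDARD_STAGES, Stage
from .synth import generate_dataset
from .training import train

__all__ = ["RunConfig", "mode_switch", "run_experiment", "predict_recording"]

logger = logging.getLogger("premscore")

MODES = ("standard3", "extended5")


@dataclass
class RunConfig:
    """Everything one experiment needs.

    ``data`` either requests synthetic data (``{"synthetic": {"n_epochs":
    ..., "fs": ...}}``) or lists files per subject (``{"recordings":
    {subject: {"recording": path, "hypnogram": path}}}``).  ``split`` maps
    each subject to one of train/validation/test.
    """

    seed: int = 0
    out_dir: str = "premscore_run"
    mode: str = "extended5"
    data: dict = field(default_factory=lambda: {"synthetic": {"n_epochs": 200, "fs": 992.0}})
    split: dict = field(default_factory=dict)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    rebalance_profile: str = "default"
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.split:
            raise ConfigError("split must assign subjects to roles")
        # accept either {subject: role} or {role: [subjects]}
        if set(self.split) <= set(DatasetSplit.ROLES):
            splits = [DatasetSplit(role=r, subject_ids=list(subjects))
                      for r, subjects in self.split.items()]
            check_disjoint(splits)
            self.split = {s: sp.role for sp in splits for s in sp.subject_ids}
        roles = set(self.split.values())
        bad = roles - set(DatasetSplit.ROLES)
        if bad:
            raise ConfigError(f"unknown split roles: {sorted(bad)}")
        for role in DatasetSplit.ROLES:
            if role not in roles:
                raise ConfigError(f"split assigns no subject to {role!r}")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, typ in [("preprocess", PreprocessConfig),
                         ("augmentation", AugmentationParams),
                         ("model", ModelConfig),
                         ("train", TrainConfig)]:
            if key in kwargs and isinstance(kwargs[key], dict):
                section = dict(kwargs[key])
                if "stride_pattern" in section:
                    section["stride_pattern"] = tuple(section["stride_pattern"])
                kwargs[key] = typ(**section)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        d = asdict(self)
        d["model"]["stride_pattern"] = list(self.model.stride_pattern)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path


def mode_switch(cfg: RunConfig, mode: str) -> RunConfig:
    """Return a copy of ``cfg`` configured for 3- or 5-class training."""
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    num_classes = 3 if mode == "standard3" else 5
    return dataclasses.replace(
        cfg, mode=mode, model=dataclasses.replace(cfg.model, num_classes=num_classes)
    )


def _effective_rebalance(cfg: RunConfig) -> RebalanceSpec | None:
    name = cfg.rebalance_profile
    if name == "default":
        name = "reb2" if cfg.mode == "standard3" else "reb1"
    if name in (None, "none"):
        return None
    if name not in PROFILES:
        raise ConfigError(f"unknown rebalance profile {name!r}")
    return PROFILES[name]


def _load_subject_windows(cfg: RunConfig, run_dir: Path):
    """Generate/read all subjects, preprocess, and window them."""
    if "synthetic" in cfg.data:
        synth = cfg.data["synthetic"]
        subjects = sorted(cfg.split)
        paths = generate_dataset(
            run_dir / "data",
            n_epochs=int(synth.get("n_epochs", 200)),
            n_subjects=len(subjects),
            seed=cfg.seed,
            fs=float(synth.get("fs", 992.0)),
        )
        files = {}
        for sid, (rec_path, hyp_path) in zip(subjects, paths):
            files[sid] = {"recording": rec_path, "hypnogram": hyp_path}
    elif "recordings" in cfg.data:
        files = cfg.data["recordings"]
        missing = set(cfg.split) - set(files)
        if missing:
            raise ConfigError(f"split subjects without data files: {sorted(missing)}")
    else:
        raise ConfigError("data section must contain 'synthetic' or 'recordings'")

    per_subject = {}
    for sid in sorted(cfg.split):
        rec = read_recording(files[sid]["recording"])
        pre = preprocess_recording(rec, cfg.preprocess)
        n_epochs = pre.n_epochs(cfg.preprocess.epoch_len_s)
        hyp = read_hypnogram(files[sid]["hypnogram"], n_epochs=n_epochs,
                             epoch_len_s=cfg.preprocess.epoch_len_s)
        per_subject[sid] = make_windows(pre, hyp, cfg.preprocess)
    return per_subject


def _apply_mode(windows, mode: str):
    """Relabel/drop windows for the requested stage set."""
    if mode == "extended5":
        return list(windows)
    out = []
    for w in windows:
        if w.label == int(Stage.ARTIFACT):
            continue
        if w.label == int(Stage.PREREM):
            w = dataclasses.replace(w, label=int(Stage.NREM))
        out.append(w)
    return out


def run_experiment(cfg: RunConfig) -> dict:
    """Run one full experiment; returns paths and the test-set report."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")

    per_subject = _load_subject_windows(cfg, run_dir)
    by_role = {role: [] for role in DatasetSplit.ROLES}
    for sid, windows in per_subject.items():
        by_role[cfg.split[sid]].append((sid, _apply_mode(windows, cfg.mode)))

    train_windows = [w for _, ws in by_role["train"] for w in ws]
    val_windows = [w for _, ws in by_role["validation"] for w in ws]

    classes = np.array(
        [int(s) for s in (STANDARD_STAGES if cfg.mode == "standard3" else ALL_STAGES)]
    )
    model_cfg = dataclasses.replace(
        cfg.model,
        num_classes=len(classes),
        input_len=cfg.preprocess.window_len,
    )
    rng_init = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    model = SleepNet(model_cfg, rng=rng_init, classes=classes)

    X_val = np.stack([w.signal for w in val_windows]).astype(np.float32)
    y_val = np.array([w.label for w in val_windows])
    train_cfg = dataclasses.replace(cfg.train, seed=cfg.seed)
    logger.info("training on %d windows, validating on %d",
                len(train_windows), len(val_windows))
    model, history = train(
        model, train_windows, X_val, y_val, train_cfg,
        rebalance_spec=_effective_rebalance(cfg),
        augment_params=cfg.augmentation if cfg.augmentation.any_active else None,
        log=lambda row: logger.info(
            "epoch %(epoch)d lr=%(lr).3g loss=%(train_loss).4f "
            "val_macro_f1=%(val_macro_f1).4f", row
        ),
    )
    ckpt = model.save(run_dir / "model.npz")
    history.to_csv(run_dir / "history.csv", index=False)

    # test-set evaluation
    y_true, y_pred, true_seqs, pred_seqs = [], [], [], []
    for sid, ws in by_role["test"]:
        X, yt = np.stack([w.signal for w in ws]).astype(np.float32), \
            np.array([w.label for w in ws])
        _, yp = model.predict(X)
        y_true.append(yt)
        y_pred.append(yp)
        true_seqs.append(yt)
        pred_seqs.append(yp)
    report = confusion(np.concatenate(y_true), np.concatenate(y_pred),
                       classes=classes)
    report_dir = run_dir / "report"
    report.save(report_dir)
    for name, seqs in [("transition_true", true_seqs), ("transition_pred", pred_seqs)]:
        _, norm = markov_matrix(seqs, classes=classes)
        pd.DataFrame(norm, index=[Stage(c).name for c in classes],
                     columns=[Stage(c).name for c in classes]).to_csv(
            report_dir / f"{name}.csv")

    return {
        "checkpoint": ckpt,
        "history": history,
        "report": report,
        "run_dir": run_dir,
    }


def predict_recording(model: SleepNet, rec: Recording,
                      pre_cfg: PreprocessConfig = PreprocessConfig()) -> pd.DataFrame:
    """Score every epoch of a raw recording.

    Returns a table with epoch_index, the predicted label, and the full
    probability vector (one ``p_<STAGE>`` column per output class).
    """
    pre = preprocess_recording(rec, pre_cfg)
    n_epochs = pre.n_epochs(pre_cfg.epoch_len_s)
    dummy = Hypnogram(labels=np.zeros(n_epochs, dtype=np.int64),
                      epoch_len_s=pre_cfg.epoch_len_s)
    windows = make_windows(pre, dummy, pre_cfg)
    X = np.stack([w.signal for w in windows]).astype(np.float32)
    probs, pred = model.predict(X)
    df = pd.DataFrame({
        "epoch_index": np.arange(n_epochs),
        "label": [Stage(c).name for c in pred],
    })
    for j, c in enumerate(model.classes_):
        df[f"p_{Stage(c).name}"] = probs[:, j]
    return df
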