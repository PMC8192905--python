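"""Train a small 3-class network end to end on synthetic data.

Uses a deliberately small network (8 kernels) and short schedule so the
example finishes in about a minute; see scripts/acceptance.py for the
larger reference run.  Prints the per-epoch log, the test-set confusion
report, and the stage-transition matrices.
"""

import pandas as pd

import premscore as pm
from premscore.pipeline import RunConfig, run_experiment

cfg = RunConfig(
    seed=11,
    out_dir="example_output/run3",
    mode="standard3",  # pre-REM -> NREM, artifact epochs dropped
    data={"synthetic": {"n_epochs": 240, "fs": 128.0}},
    split={"train": ["a", "b", "c"], "validation": ["d"], "test": ["e"]},
    rebalance_profile="default",  # reb2 (.41/.25/.34) in 3-class mode
    model=pm.ModelConfig(n_kernels=8),
    train=pm.TrainConfig(min_epochs=2, max_epochs=6, patience=3),
)
artifacts = run_experiment(cfg)

print("per-epoch training log:")
log = artifacts["history"][["epoch", "lr", "train_loss", "val_macro_f1"]]
print(log.to_string(index=False, formatters={
    "lr": "{:.2e}".format, "train_loss": "{:.4f}".format,
    "val_macro_f1": "{:.4f}".format}))

report = artifacts["report"]
print(f"\ntest-set macro F1: {report.f1_mean:.3f}")
print("\nper-class precision/recall/F1:")
print(report.per_class().round(3).to_string())

print("\nrow-normalised confusion (rows = true stage, diagonal = recall):")
names = [pm.Stage(c).name for c in report.classes]
print(pd.DataFrame(report.cm_recall_norm, index=names, columns=names)
      .round(3).to_string())
print(f"\nartifacts written to {artifacts['run_dir']}/")
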