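"""Score a new recording with a trained checkpoint.

Loads the checkpoint written by 04_train_and_evaluate.py (trains it first if
missing), scores an unseen synthetic recording epoch by epoch, and prints
the per-epoch score-probability table — the same output as
``premscore predict``.
"""

import pathlib
import runpy

import premscore as pm
from premscore.pipeline import predict_recording

ckpt = pathlib.Path("example_output/run3/model.npz")
if not ckpt.exists():
    print("no checkpoint yet - running 04_train_and_evaluate.py first\n")
    runpy.run_path(pathlib.Path(__file__).with_name("04_train_and_evaluate.py"))

model = pm.SleepNet.load(ckpt)

hyp = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, n_epochs=30, seed=99)
rec = pm.generate_recording(hyp, pm.DEFAULT_SIGNAL_MODELS, fs=128.0, seed=100,
                            subject_id="unseen")
table = predict_recording(model, rec)

print("predicted scores and probabilities (first 10 epochs):")
print(table.head(10).round(3).to_string(index=False))

truth = [pm.Stage(c).name for c in hyp.labels]
# the checkpoint is 3-class: pre-REM counts as NREM, artifacts are unscored
reduced = ["NREM" if t == "PREREM" else t for t in truth]
agree = sum(p == t for p, t in zip(table["label"], reduced) if t != "ARTIFACT")
n = sum(t != "ARTIFACT" for t in reduced)
print(f"\nagreement with the generating hypnogram: {agree}/{n} epochs")
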