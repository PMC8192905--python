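"""Preprocess a recording and build the network's context windows.

The raw signal is low-pass filtered (4th-order Butterworth at 25.6 Hz,
forward+backward so there is no phase shift), downsampled to 64 Hz by linear
interpolation, and cut into 10-s epochs; each classifier input is three
consecutive epochs (1920 samples) labeled with the middle epoch's stage.
"""

import numpy as np

import premscore as pm

hyp = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, n_epochs=60, seed=3)
rec = pm.generate_recording(hyp, pm.DEFAULT_SIGNAL_MODELS, fs=992.0, seed=4,
                            subject_id="demo")
print(f"raw: {len(rec.samples)} samples at {rec.fs} Hz")

pre = pm.preprocess_recording(rec)
print(f"preprocessed: {len(pre.samples)} samples at {pre.fs} Hz")

# the filter halves a 25.6 Hz component's amplitude (|H|^2 = 1/2 at f_c)
t = np.arange(int(992 * 20)) / 992.0
sine = np.sin(2 * np.pi * 25.6 * t)
filtered = pm.antialias_filter(sine, fs=992.0)
mid = slice(len(t) // 4, 3 * len(t) // 4)
print(f"attenuation at 25.6 Hz: {np.max(np.abs(filtered[mid])):.3f} (expect 0.5)")

windows = pm.make_windows(pre, hyp)
X, y = pm.windows_to_array(windows)
print(f"{len(windows)} context windows of {X.shape[1]} samples "
      f"({X.shape[1] // 3} per epoch); labels from {sorted(set(y))}")
print("window 0 repeats the first epoch in place of the missing left",
      "neighbour, so every scored epoch gets a prediction.")
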