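"""The four training-time augmentations on one context window.

Each transform has a strength in [0, 1] and a fresh uniform draw per
presentation: amplitude scaling, sign flip (montage polarity), window
warping (frequency shift by T*/T), and time shift within the recording.
"""

import numpy as np

import premscore as pm
from premscore.augment import augment_with_draws

fs, spe = 64.0, 640
t = np.arange(9 * spe) / fs
source = 100 * np.sin(2 * np.pi * 4.0 * t)  # 4 Hz, 100 uV
start = 3 * spe
w = pm.ContextWindow(signal=source[start : start + 3 * spe], label=0,
                     center_epoch=4, source=source, start=start)
T = len(w.signal)

amp = pm.augment_amplitude(w.signal, a_a=0.5, u=0.5)
print(f"amplitude a_a=0.5, u=0.5: scale 1.25 -> peak {amp.max():.1f} uV")

flip = pm.augment_signflip(w.signal, a_s=1.0, u=0.3)
print(f"sign flip: first samples {w.signal[:2].round(1)} -> {flip[:2].round(1)}")

warped = pm.augment_frequency(w, a_f=0.2, u=1.0)
spec = np.abs(np.fft.rfft(warped * np.hanning(T)))
freqs = np.fft.rfftfreq(T, d=1 / fs)
t_star = int(np.floor(1.2 * T))
print(f"warp T*={t_star}: 4 Hz sine now peaks at {freqs[spec.argmax()]:.2f} Hz "
      f"(expect {4 * t_star / T:.2f})")

shifted = pm.augment_timeshift(w, a_t=0.06, u=1.0)
dt = int(np.floor(T * 0.06 * 1.0))
print(f"time shift dt={dt} samples ({dt / fs:.2f} s within the recording)")

composite = augment_with_draws(w, pm.AugmentationParams(a_a=0.5, a_f=0.1,
                                                        a_s=0.5, a_t=0.06),
                               u_a=-0.4, u_s=0.2, u_f=0.5, u_t=-1.0)
print(f"composite (order: amplitude, flip, warp, shift) keeps length {len(composite)}")
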