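# premscore

Automated scoring of mouse sleep stages — **Wake, NREM, pre-REM, REM, and
artifact** — from a single EEG channel, with a small 1-D convolutional
network.

Sleep studies in rodents rest on hypnograms: one stage label per 10-s epoch
of EEG, traditionally assigned by a human expert watching the traces. The
three classical stages (Wake, NREM, REM) are routinely automated; the
transitional **pre-REM** stage (also called intermediate stage or transition
sleep) — short bouts of spindle-like high-amplitude activity over an
emerging theta rhythm between NREM and REM — is rare (~2 % of epochs) and
much harder, for experts and machines alike. This package implements an
end-to-end scoring pipeline that targets pre-REM alongside the classical
stages, and a synthetic stage-labeled EEG generator so that every part of
the pipeline is testable without access to animal recordings.

It is aimed at sleep researchers and methods developers who want a
transparent, dependency-light reference implementation: the entire network
and training loop are plain numpy, every formula is a unit-testable
function, and all randomness is seeded.

## The pipeline

1. **Preprocessing.** The raw EEG (e.g. 992.06 Hz) is low-pass filtered with
   a 4th-order Butterworth at 25.6 Hz, applied forward and backward
   (zero-phase; effective magnitude |H(f)|² = 1/(1+(f/f_c)⁸)), then
   downsampled to 64 Hz by linear interpolation. Each classifier input is
   three consecutive 10-s epochs — T = 3·640 = 1920 samples — labeled with
   the middle epoch's stage, mimicking what a human scorer sees.
2. **Augmentation** (training only; strengths a_a, a_f, a_s, a_t ∈ [0, 1],
   fresh draws u per presentation, applied in this order):
   amplitude scaling s* = s·(1 + a_a·u); sign flip s* = −s with probability
   a_s (montage polarity); window warping — a temporary series of length
   T* = ⌊T(1 + a_f·u)⌋ is resampled back to T, shifting frequencies by
   T*/T; time shift by Δt = ⌊T·a_t·u⌋ samples within the recording.
3. **Class rebalancing.** Before every training epoch the training set is
   resampled with replacement to target class frequencies while keeping its
   size N: class c contributes round(f_c·N) windows. Two shipped profiles:
   `reb1` (.30/.18/.24/.14/.14 over Wake/REM/NREM/pre-REM/artifact, 5-class)
   and `reb2` (.41/.25/.34, 3-class).
4. **Network.** Input batchnorm → 8 convolutional layers (96 kernels of
   width 5, valid convolutions, strides 1,2,1,2,1,2,1,2; conv → ReLU →
   batchnorm, dropout p = 0.2 on every second block) → flatten
   (113·96 = 10848 features) → FC(80, ReLU) → FC(3 or 5) → softmax score
   probabilities p⃗; the predicted stage is argmax p⃗.
5. **Training.** Loss 𝓛 = −(1/N_b)Σ log p_{k,c_k} + (λ/2N_b)Σ w² (λ = 10⁻⁴,
   biases excluded); Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on gradients
   clipped to global norm θ = 0.1; learning rate warmed up linearly from
   10⁻⁷·N_b to 10⁻⁶·N_b over 12 epochs, then decayed as
   η_i = 10⁻⁶·N_b·e^(−0.06(i−12)); early stopping when the validation macro
   F1 has not improved for 5 epochs (min 12, max 50), returning the
   best-epoch weights.
6. **Evaluation.** Confusion matrices raw and under both normalisations
   (row-normalised diagonal = recall, column-normalised diagonal =
   precision), per-class F1 = 2pr/(p+r), macro F̄1 over classes present in
   the true labels, and Markov transition matrices of stage sequences.

In **standard3** mode pre-REM is reinterpreted as NREM and artifact epochs
are removed; **extended5** keeps all five stages.

## Worked example

```python
>>> import premscore as pm
>>> hyp = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, n_epochs=60, seed=3)
>>> rec = pm.generate_recording(hyp, pm.DEFAULT_SIGNAL_MODELS, fs=992.0, seed=4)
>>> pre = pm.preprocess_recording(rec)       # 595200 samples @992 Hz -> 38400 @64 Hz
>>> windows = pm.make_windows(pre, hyp)      # 60 windows of 1920 samples
>>> pm.DEFAULT_HYPNOGRAM_MODEL.stationary_distribution().round(4)
array([0.5532, 0.3755, 0.0188, 0.0501, 0.0025])
```

The stationary distribution above is the generator's class mix
(Wake/NREM/pre-REM/REM/artifact) — the class imbalance the rebalancing
profiles exist to counter. The filter halves a 25.6 Hz component
(`examples/02` prints `attenuation at 25.6 Hz: 0.500`), and warping a 4 Hz
sine with a_f = 0.2, u = 1 moves its spectral peak to 4.80 Hz
(`examples/03`), the T*/T = 2304/1920 shift.

The scripts in `examples/` walk through every capability (generation,
preprocessing, augmentation, a small end-to-end training run, scoring a new
recording); each prints the numbers it computes and what they mean. A
command-line interface mirrors the pipeline:

```sh
premscore generate --out data --subjects 3 --epochs 360 --seed 1
premscore run --config run.yaml
premscore predict --model run/model.npz --in data/synth00.raw --out scores.csv
```

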