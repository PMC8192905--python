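# Methods

This note documents the models, numerical choices, and open design
decisions behind premscore, and what the synthetic-data experiments do and
do not demonstrate.

## Problem setting

Mouse polysomnography is scored in non-overlapping 10-s epochs over five
stages: Wake, NREM, pre-REM, REM, artifact. The scorer sees three
consecutive epochs and labels the middle one. The package reproduces that
setting end to end from a single EEG channel: the classifier consumes
three consecutive preprocessed epochs (1920 samples at 64 Hz) and outputs
score probabilities for the middle epoch. Epoch k of a recording covers
samples [k·10·fs, (k+1)·10·fs), 0-based and half-open; a trailing partial
epoch is dropped.

## Preprocessing

* **Anti-alias filter**: 4th-order Butterworth low-pass, critical frequency
  25.6 Hz, applied forward and backward (scipy `filtfilt`). The net phase
  response is zero and the effective magnitude response is the squared
  single-pass response, so a 25.6 Hz component is attenuated to exactly 1/2.
  Edge transients are controlled with odd-reflection padding of length
  3·(order+1) = 15; the magnitude contract is asserted on interior samples
  only. Signals must exceed the pad length.
* **Resampling**: linear interpolation onto the grid t_k = k/64 anchored at
  t = 0; output length ⌊(n−1)·fs_out/fs_in⌋ + 1, so every output time lies
  inside the input's support. Filtering precedes resampling (the reverse
  would alias); epoching happens after resampling, which sidesteps the
  non-integer 9920.6 samples/epoch of a 992.06 Hz native rate.
* **Context windows**: the window for epoch k spans epochs (k−1, k, k+1).
  At recording boundaries the missing neighbour is a copy of the edge
  epoch. Rationale: dropping boundary epochs would desynchronise predicted
  and manual hypnograms; replication keeps one prediction per scored epoch.
  This choice is ours — how the original scoring setup presented the first
  and last epochs is not documented.

## Augmentation

Four stochastic transforms emulate nuisance variability (gain settings,
montage polarity, frequency jitter, stage boundaries not aligned to epoch
boundaries). Strengths live in [0, 1]; a fresh uniform draw is taken each
time a window enters the network; the application order is amplitude, sign
flip, warp, shift. Implementation choices:

* Every operator takes its uniform draw `u` as an explicit argument, so each
  formula is deterministic and unit-testable; only the composite consumes an
  RNG.
* Window warping builds a temporary series of length T* = ⌊T(1+a_f u)⌋
  sharing the original centre (up to one sample when T and T* differ in
  parity) and resamples it to T by linear interpolation.
* Warping and shifting may address samples outside the window; they are
  gathered from the source recording, with edge-sample replication beyond
  its ends (replication avoids the spectral artifacts of zero padding).
* In the composite, the time shift is applied to the temporary series'
  source positions before warping back, and the two pointwise scalings
  (amplitude, sign) multiply the result; this is algebraically identical to
  scaling the recording first and keeps both resampling operators exact.
* The uniform draws use the half-open interval [−1, 1) throughout; one of
  the transforms is sometimes written with a closed interval, a
  probability-zero distinction.
* Augmentation applies to training windows only, never at validation/test.

## Class rebalancing

Before each training epoch, a fresh index multiset of (approximately) the
original size N is drawn: class c contributes round-half-away(f_c · N)
indices sampled with replacement from its positions. With the 5-class
profile (.30/.18/.24/.14/.14) at N = 366,720 this yields 110,016 / 66,010 /
88,013 / 51,341 / 51,341 — the published worked example prints 110,017 for
the first cell, which no standard rounding rule reproduces (every other cell
matches); we document the one-off discrepancy rather than special-case it.

## Network

Input batchnorm (learnable scale/shift of the single channel) → 8 × [valid
conv (96 kernels, width 5) → ReLU → batchnorm], strides (1,2,1,2,1,2,1,2),
dropout p = 0.2 after blocks 2, 4, 6, 8 → flatten → dropout → FC 80 (ReLU,
dropout) → FC num_classes → softmax. Ties in the argmax go to the lowest
class index.

Valid (unpadded) convolution is load-bearing: it is the only padding mode
under which the stride pattern maps 1920 input samples to the 113 positions
whose flattening gives 10848 classifier features ("same" padding would give
120). The per-layer lengths follow L_out = ⌊(L_in − 5)/stride⌋ + 1:
1916, 956, 952, 474, 470, 233, 229, 113. Dropout placement "every second
conv block" and the learnable input normalisation are our reading of an
architecture description that does not pin them down.

The implementation is plain numpy (float32), with explicit forward/backward
passes per layer. Convolutions use a shift-and-sum formulation (one GEMM
per kernel tap on a strided view) rather than im2col, which avoids
materialising large column matrices on CPU. Activations are channels-last.
Backpropagation is verified against central-difference numerical gradients
in float64 to a relative error of 1e-5.

## Training protocol

* Loss: mean negative log-likelihood of the true classes plus
  λ/(2N_b)·Σw² over non-bias weights; λ = 10⁻⁴; probabilities are clamped
  at 1e−12 inside the log. Batchnorm scale/shift parameters are excluded
  from the penalty along with biases (our extension; they act as
  per-channel gains, not capacity).
* Gradients are clipped by rescaling when the global norm across all
  parameters exceeds θ = 0.1, before the Adam moment updates.
* Adam with bias-corrected moments; β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸;
  verified against an independent textbook recurrence to 1e−10.
* Learning rate is per training epoch (1-based): linear warm-up over the
  first 12 epochs from 10⁻⁷·N_b (epoch 1) to 10⁻⁶·N_b (epoch 12), then
  exponential cool-down with rate α = 0.06. N_b = 256. Whether the original
  warm-up was per-step or per-epoch is unstated; we chose per-epoch, which
  matches a protocol described in epochs.
* Early stopping: "no improvement" means no strict increase of the
  validation macro F1 over the running best; after `patience` (5)
  consecutive non-improving epochs training stops, never before
  `min_epochs` (12) nor beyond `max_epochs` (50), and the best-epoch
  weights are restored. Patience counts from the best epoch.
* Validation macro F1 averages over the classes present in the validation
  labels (all five in 5-class mode when all occur).
* All randomness (rebalancing draws, batch shuffling, augmentation draws,
  dropout masks) derives from the single training seed via independent
  spawned streams; a fixed seed reproduces the run bit for bit on the same
  platform.

## Synthetic data generator

The generator exists so the pipeline is buildable and testable without
animal recordings, which are typically not depositable. It emulates the
features the classifier must exploit:

* **Hypnogram**: first-order Markov chain over the five stages. The default
  transition matrix encodes the physiological cycle — Wake ↔ NREM,
  NREM → pre-REM → REM → Wake, direct NREM → REM probability 0.001 — and
  was chosen (once, by a coarse search over self-transition probabilities)
  so that its stationary distribution approximates the class frequencies of
  real mouse datasets: (0.553, 0.376, 0.019, 0.050, 0.0025) for
  Wake/NREM/pre-REM/REM/artifact. All numbers are synthetic choices, not
  measured transition statistics.
* **Signals**: pink (1/f) background noise for every stage, plus per-stage
  components — NREM: 0.5–4 Hz band-limited oscillation (120 µV RMS);
  REM: 7–8 Hz (70 µV); pre-REM: attenuated delta (60 µV), emerging theta
  (40 µV), and ≥1 spindle-like burst per epoch (10–15 Hz carrier under a
  Hann envelope, 1.5 s, 150 µV); Wake: 30 µV broadband noise only;
  artifact: ≥1 large spike transient with the whole epoch clipped at 75 %
  of the spike amplitude, guaranteeing a flat-topped excursion above 5× the
  epoch RMS. Band-limited components are Butterworth-bandpass-filtered
  white noise normalised to the target RMS.
* What it does **not** emulate: EMG, real EEG nonstationarity within a
  stage, scorer label noise, inter-subject spectral variability, electrode
  drift. Consequently, passing tests show the pipeline can learn and score
  *separable* stage signatures — they say nothing about accuracy on real
  mouse data, where pre-REM is hard precisely because it is not cleanly
  separable.

A guard test verifies the fixture is learnable before any network test: a
linear discriminant on log bandpowers separates the three main stages with
≥90 % accuracy.

## Reduced-scale surrogate experiments

The reference experiments (tests and `scripts/acceptance.py`) run on 6
synthetic subjects × 600 epochs (3,600 epochs ≈ 10 h of signal) generated
at 128 Hz, split 4/1/1 by subject, with a 32-kernel variant of the
architecture — chosen so a full run fits in minutes of single-core CPU
time; all other hyperparameters keep their defaults.

* The 3-class run (reb2 rebalancing, no augmentation, ≤8 training epochs)
  reaches test-subject macro F1 ≈ 0.9.
* The 5-class run uses reb1 rebalancing, time-shift augmentation
  a_t = 0.06 and ≤15 epochs. At this scale the training set holds only a
  few dozen unique pre-REM windows; without augmentation the network
  memorises them and validation pre-REM F1 stays at 0. Time shift — the
  augmentation that most helps pre-REM at full scale too — restores
  generalisation (best validation pre-REM F1 ≈ 0.25–0.45 by epochs 12–15,
  versus ~0 after one epoch of unbalanced training).
* A 1-epoch no-rebalancing baseline provides the comparison value.

## Degenerate inputs and numerical conventions

* Probabilities: softmax is computed with max subtraction; the loss clamps
  p at 1e−12; batchnorm uses ε = 1e−5 and momentum 0.1 running statistics.
* Confusion-matrix normalisations divide by zero-safe row/column sums; a
  class absent from the true labels has undefined recall — its F1 is NaN
  and it is excluded from the macro average.
* F1 is defined as 0 when precision + recall = 0.
* Markov transition matrices are computed per recording and summed; a
  sequence shorter than 2 contributes no transitions.
* EDF stores 16-bit integers with physical scaling, so EDF round trips are
  exact only to quantisation; the raw float32 + JSON sidecar dialect is
  bit-exact and carries non-integer rates. EDF record duration is chosen as
  the smallest integer making fs·duration integral (50 s for 992.06 Hz);
  a final partial record is padded by repeating the last sample.

## Known limitations

* No EMG channel: stages whose definitions lean on muscle tone (Wake) are
  identified from EEG alone, as in the single-channel design the package
  implements.
* The numpy network is CPU-bound: a 256-window forward pass of the default
  96-kernel architecture takes on the order of seconds, fine for scoring
  recordings, slow for large hyperparameter searches.
* Full-scale F1 values on real mouse data cannot be reproduced or asserted
  here; they require the original (request-only) recordings.
* The hyperparameter search the full study performed is out of scope; every
  searched quantity is exposed in the run configuration instead.
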