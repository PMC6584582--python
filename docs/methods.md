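# Methods

## Problem and model

Agonal breathing — the sporadic, gasping respiration of severe hypoxia — is
an audible biomarker of cardiac arrest that typically recurs at 3–6 gasps per
minute. `agonalert` implements a contactless detector for it: a smart
speaker or phone listens to a bedroom, scores every 2.5 s audio segment for
the presence of a gasp, and raises an alarm only when detections recur at the
physiologic rate.

The per-segment classifier is a conventional audio-event pipeline:

1. **Front end** (`audio`): mono waveform, peak-normalized to [−1, 1],
   band-limited polyphase resampling to 16 kHz, non-overlapping 2.5 s
   segmentation (hop defaults to the segment length; overlap is a config
   option). Timestamps are seconds from stream start, half-open intervals
   `[t, t + 2.5)`.
2. **Featurization** (`features`): Hann-windowed STFT (25 ms window, 10 ms
   hop, 512-point FFT, no centering/padding), a 64-band triangular mel
   filterbank between 125 and 7500 Hz applied to the power spectrum,
   `log(x + 0.01)` compression, then projection of the flattened 248 × 64
   log-mel matrix onto a 256-component PCA basis fitted on training segments
   only. One matrix per 2.5 s segment is flattened and embedded whole; a
   patch-wise embedding with pooling would be an alternative but the
   per-segment reading is the minimal one. No whitening by default — it
   would change the geometry the SVM's `gamma` is calibrated against
   (`whiten=True` is a flag).
3. **Classifier** (`detector`): RBF-kernel SVM with C = 10 and the scale
   heuristic `gamma = 1/(256 · var(X))`. Probabilities come from Platt
   scaling — a sigmoid fitted on decision values of an inner 80/20 split,
   after which the SVM is refitted on all training data. The operating
   threshold defaults to probability 0.5 and is config-exposed.
4. **Alarm filter** (`agonal_filter`): positives within 5 s of the previous
   positive merge into one breath event (a gasp can straddle a segment
   boundary); a breath event chains to the previous one when the onset gap
   lies in [10, 20] s inclusive (3–6 breaths/min); a chain of
   `breaths_required` events (default 3) alarms and resets. A gap outside
   the window — whether too long *or* implausibly short — reseeds the chain
   at the new event; this is the minimal-state choice for the unstated
   too-fast case and keeps the filter memoryless beyond one pending chain.

### Real-time approximation

For real-time scoring the kernel machine can be replaced by a linear model in
`D` random Fourier features (`detector.approximate`): rows of the projection
drawn N(0, 2γI), phases uniform on [0, 2π), features
`z_i(x) = sqrt(2/D)·cos(ω_i·x + b_i)`, so `z(x)·z(y) → exp(−γ‖x−y‖²)` with
Monte-Carlo error O(1/√D). The linear weights are refitted on the retained
training embeddings with logistic loss rather than mapped from the dual
coefficients — simpler, and directly checkable against the exact machine.

### Cross-validation and leakage

`detector.crossvalidate` runs grouped k-fold (k = 10) where the grouping key
is the source recording: every augmented variant (distance, interference,
device) of a source stays on one side of each fold's split, and sources of
each class are dealt round-robin into folds so both classes always appear in
training. The PCA featurizer and the SVM are refitted per fold on training
rows only; the deterministic log-mel transform is computed once per corpus
and shared across folds.

## Self-playback cancellation

`cancel` implements Sign-Data LMS with 100 weights and step size μ = 0.05:
`e[k] = d[k] − wᵀx[k]`, `w ← w + μ·e[k]·sign(x[k])`, with `sign(0) = 0` so a
silent reference is a strict no-op. Two implementation constants:

- The reference window is normalized by its running peak, so μ has the same
  meaning regardless of playback level.
- An additional `1/sqrt(n_weights)` factor on the input keeps the sign-data
  loop gain `μ·‖x‖₁` below its stability bound of 2 in the worst case
  (`μ·√n_weights = 0.5` at the defaults). Without it, bursty references
  (speech, music peaks) drive the update unstable at exactly these
  parameter values.

The filter models echo delays up to `n_weights` samples (6.25 ms at 16 kHz);
coarse alignment of the reference is the caller's job (`chirpsync`, or a
known offset).

## Chirp synchronization

`chirpsync` prepends a linear FMCW sweep (default 500 → 4000 Hz over 100 ms,
Hann-tapered edges — inside telephony bandwidth so 8 kHz material can be
synchronized) and recovers clip onsets by normalized cross-correlation: the
correlation is divided by the local signal energy under the template window,
making the detection threshold level-independent. Peaks are picked greedily
(highest first) with a minimum separation defaulting to chirp + clip length.

## Synthetic acoustic scenes

The original training audio (9-1-1 call extracts, polysomnography streams)
is not publicly distributable, so `synthgen` generates surrogate scenes with
the same statistical structure. Templates are engineering surrogates, not
physiological models:

- **Agonal gasp**: band-passed (200–3000 Hz) noise burst plus an 80–150 Hz
  harmonic, sharp ~50 ms attack and ~400 ms exponential decay, unit peak.
- **Negative classes**: periodic respiratory cycles (6–30 per minute) —
  snoring (low-frequency buzz-modulated noise), normal breathing (soft
  turbulent airflow), hypopnea (cycles at 30% amplitude), central apnea
  (≥10 s silent gap, no effort), obstructive apnea (gap with weak residual
  struggle bursts).
- **Interference**: speech-like (formant-band noise, 3–7 Hz syllabic AM),
  traffic-like (low-pass rumble with transients), white, and narrowband
  soundscape noise.

Scenes mix events at 1/r amplitude relative to 1 m (no reverberation — the
attenuation is what the augmentation stresses, and a room impulse response
would add unvalidated complexity), interference at a stated RMS dBFS, and a
Gaussian noise floor. If a mix would clip, the whole waveform is scaled
down, never clipped, so mixing stays linear. All randomness flows from one
scene seed through counter-based `SeedSequence` splits (separate roles for
noise floor, interference, and each event), making scenes bit-reproducible
and single-event scenes exactly the sum of the event and the noise-only
scene.

A segment is labeled positive iff it overlaps at least 50% of some gasp's
support — unambiguous and testable, consistent with labeling whole 2.5 s
clips cut from gasp onsets.

### Study-condition corpus

`build_clip_corpus` emulates the training-data structure: each positive
source is one gasp (0.4–1.2 s, position jittered inside the 2.5 s clip, since
streamed segments are not aligned to gasp onsets); each negative source is a
slice of a sleep track (the five negative kinds cycled) or an
interference-only clip. Every source is rendered under six recording
conditions (distances 1/3/6 m × {clean, −25 dBFS interference}), all sharing
the source id for grouped CV. Class balance is 1:1 with no class weighting.

## Evaluation conventions

- AUC is the trapezoid over the empirical ROC (equivalently the Mann–Whitney
  statistic, ties counted half).
- Confidence intervals are 95% Wald (`p ± 1.96·√(p(1−p)/n)`, clipped to
  [0, 1]); Wilson intervals are available behind a flag but the normal
  approximation is the reported form.
- Percentages print half-up at 2 dp for operating-point metrics and 5 dp for
  streaming false-positive rates.
- Streaming FP rate = 100 × false-positive segments / truly-negative
  segments.
- Benchmark "detection accuracy" is the fraction of played 2.5 s clips
  classified with their true label per condition cell.

## Problem sizes

The experiment helpers default to the sizes the whole analysis is run at:
100 sources per class (1200 clips) for grouped 10-fold CV; 100 simulated 1 h
all-negative prediction streams (positives i.i.d. at 0.00144 per segment,
the order of magnitude of a raw classifier FP rate on sleep audio) for the
false-positive cascade; 20 paired scenes for the cancellation comparison; 40
sources per class for the reference training bundle behind the cancellation
and distance benchmarks.

## What passing tests do and do not show

The synthetic corpus is acoustically much easier than real bedroom audio:
surrogate gasps share one spectral template family, negatives are stationary
surrogates, and there is no reverberation, codec distortion, or device
nonlinearity. High cross-validated AUC on this corpus demonstrates that the
pipeline is correctly wired and that its inductive structure (log-mel + PCA
+ RBF-SVM + rate filter) separates the intended event classes under
distance, interference and playback stress — it does not certify real-world
sensitivity or specificity, which can only be measured on clinical audio.

Known limitations:

- A gasp straddling a 2.5 s boundary is split across two segments that may
  each fall below the classifier's evidence threshold; the merge window in
  the filter mitigates double counting but not missed detections.
- The 1/r distance model ignores reverberant energy, which in real rooms
  flattens the attenuation curve.
- The agonal acoustic template cannot be validated against real 9-1-1 audio;
  its realism is an assumption of every synthetic result.
- The LMS canceller assumes the echo path is shorter than 100 taps and
  time-invariant; double-talk (gasp during loud playback) transiently
  perturbs the weights.
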