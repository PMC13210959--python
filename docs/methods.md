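# Methods

This note documents the models, numerical choices and limitations behind
`emgintent`, in the order data flows through the pipeline.

## Synthetic signal model

Surface EMG is the superposition of many motor-unit action potentials; at
the whole-signal level it is well approximated by an amplitude-modulated,
band-limited stochastic process.  Each channel of a simulated trial is

    x_c(t) = g_c · e(t) · s_c(t) + d(t) + l(t) + n(t)

- `s_c(t)` — unit-variance carrier: white Gaussian noise band-pass
  filtered to 20–240 Hz (4th-order Butterworth, forward–backward) and
  standardised.  The physiological sEMG band is usually quoted as
  20–450 Hz, but at the 500 Hz sampling rate of the emulated hardware
  only content below the 250 Hz Nyquist frequency exists; 240 Hz keeps
  the carrier inside the realisable band.  Each channel draws an
  independent carrier per trial.
- `e(t)` — activation envelope (trapezoid by default, raised-cosine
  optional).  The rise (0.4 s) is placed in the *preparation* phase and
  the fall (0.4 s) in the *return* phase, reflecting that neuromuscular
  activation precedes and outlasts the cued movement.  Consequently the
  execution phase is a steady plateau, and the trial annotation
  `[t_s, t_e)` (0-based, half-open sample indices) marks exactly that
  execution interval — the "steady contraction" segment downstream stages
  consume.
- `g_c` — per-channel plateau gain in mV.  The four default profiles give
  each active class a distinct support pattern over the eight-muscle
  montage (biceps/anterior-deltoid/pectoralis for drinking,
  biceps/triceps for flexion–extension, lateral/posterior
  deltoid/trapezius for abduction); rest keeps a 0.05 mV tonic gain on
  every channel, since a static holding posture still produces low-level
  tone.  An `overlap ∈ [0, 1]` parameter blends all gain vectors toward
  their mean: 0 is the default clearly-separated regime, 1 collapses all
  classes onto one distribution (chance-level separability).
- contaminants, present in *all* phases: sinusoidal baseline drift
  (0.2 mV at 0.5 Hz), 50 Hz line interference (0.2 mV), white sensor
  noise (0.1 mV std), each with independent random phase per channel, and
  an optional hard saturation rail.  The magnitudes are package choices
  on the scale of real surface recordings (activation ~1 mV, SNR ≈ 10);
  real noise environments vary widely, so all of them are config-exposed.

Sessions follow a cue-driven block protocol: trials of all classes are
shuffled within each block, blocks are separated by rest gaps that contain
contaminants only.  The default offline protocol is 4 blocks × 5
trials/class (20 trials per class) with 2.5 s preparation + 5 s execution
+ 2.5 s return per trial; `online_protocol()` reproduces the interactive
validation layout of 15 repetitions of each motion in one round, each a
5 s motion cycle framed by 5 s of preparation/return.  Everything is
driven by one `numpy` generator per session, so a fixed seed reproduces a
session bit-exactly.

What the generator does *not* emulate: motor-unit recruitment and firing
statistics, fatigue-induced spectral compression, electrode displacement,
cross-talk between channels, or movement-phase-dependent activation
shapes beyond the trapezoid.  Passing tests on this generator therefore
demonstrates the pipeline's correctness and its behaviour under the
stated amplitude/noise structure — not performance on real recordings.

## Preprocessing

Order: inspect → interpolate → wavelet denoise → band-pass → notch,
identical parameters for every retained channel.

- **Quality inspection.**  A channel is excluded iff its saturation
  fraction (samples at or beyond a ±5 mV rail) exceeds 5 % or its mean
  offset exceeds 1 mV.  Transient artifacts are flagged as intervals
  where |x − median| exceeds 50× a robust scale, and repaired by linear
  interpolation between the interval's boundary samples (hold-value at
  recording edges).  The scale is `max(1.4826·MAD, std/3)`: sEMG is
  burst-like, most samples sit near baseline, and a pure MAD scale would
  label ordinary voluntary bursts as artifacts; the std floor restricts
  flagging to electrode-pop-scale spikes an order of magnitude above the
  physiological range.
- **Denoising.**  Multi-level db4 decomposition (4 levels), soft
  thresholding `T(w) = sign(w)·max(|w| − λ, 0)` of the detail bands only,
  with the Donoho–Johnstone universal threshold λ = σ̂√(2 ln N) and
  σ̂ = median(|finest detail|)/0.6745.  On a mixed recording the median is
  dominated by low-activity samples, so λ sits at the noise floor and
  voluntary bursts pass nearly intact while rest-period noise is strongly
  shrunk.  Two corollaries worth knowing: (i) the rest class is encoded
  as a near-zero residue, and (ii) the estimator is *not* meaningful for
  stationary narrowband signals (a pure sine's finest-detail MAD is the
  signal itself and the threshold erases it) — the denoiser is built for
  burst-structured biosignals.  Signals shorter than 2^levels samples are
  rejected with the minimum length in the message.
- **Filtering.**  4th-order Butterworth band-pass (second-order-sections)
  plus an IIR notch at 50 Hz with Q = 30 — field-standard sEMG choices;
  the filter family and order are not dictated by the problem.  The
  requested 20–450 Hz band is auto-clamped to `0.9·fs/2` (225 Hz at
  500 Hz) with a logged warning, because the printed band exceeds Nyquist
  at this sampling rate.  Offline filtering is zero-phase
  (forward–backward) so activation onsets are not shifted; a causal
  single-pass variant (`CausalFilterBank`, stateful across chunks) exists
  for latency-critical streaming and diagnostics.

Applying the full chain twice changes in-band power of activity-carrying
channels by ≲3 % (soft thresholding is a shrinkage operator, so exact
idempotence is impossible; channels with no activity keep shrinking
relative to their own noise floor).

## Windowing

`N = fs·Δt` must be an exact integer (no silent rounding); defaults
Δt = 200 ms, step 100 ms → N = 100, 50 % overlap.  Only annotated
execution segments are windowed; a segment of length L yields
`⌊(L−N)/S⌋ + 1` windows, the trailing remainder is dropped (uniform
window shape), and a segment shorter than one window yields zero windows
with a warning.  All intervals are 0-based half-open `[start, end)`.
Because windows are cut per segment, no window ever spans two trials —
the structural guarantee behind leak-free trial-level splits.

## Features

Verbal definitions fixed as standard formulas: VAR uses the unbiased
(N−1) denominator; skewness and kurtosis use population moments with
Pearson (non-excess) kurtosis; WF = RMS/MAV, IF = peak/MAV,
CF = peak/RMS.  The quantity named "clearance factor" here is numerically
the conventional *crest* factor (peak/RMS); the conventional clearance
factor (peak over squared mean square-root) is a different statistic, and
the naming follows the feature set this package implements.  Windows with
zero MAV or zero variance (possible only for pathological input) are
dropped from the assembled matrix with a logged count — imputation would
distort class geometry.

The default layout concatenates per-channel values (channel-major,
feature-minor columns named `<channel>_<feature>`), preserving the
spatial information an eight-electrode montage exists to provide; a
`channel_mean` layout is available for comparison.  No normalization is
applied by default.  `TimeDomainFeatures` exposes the same computation as
a scikit-learn transformer over `(n_windows, N, m)` stacks.

## Modeling

- **Splits.**  Trials are atomic.  Stratified per class, test count
  `max(1, round((1−f)·n))` so every class appears in the test set;
  f = 0.9 by default.
- **Classifiers.**  SVC (RBF), LDA, QDA, GradientBoosting, RandomForest
  with library defaults beyond the tuned pair; the concrete parameter set
  is recorded verbatim in every report.  QDA gets a tiny covariance ridge
  (`reg_param = 1e-6`, rank tolerance 1e-12) because the near-constant
  rest class otherwise yields a singular class covariance.  The "single
  classifier" used for single-feature and fusion screening defaults to a
  seeded random forest (the pipeline's eventual model), configurable.
- **Per-class accuracy** is recall (diagonal / row sum of the confusion
  matrix); tables carry a `Mean Value` column equal to the arithmetic
  mean of the four class accuracies, and multi-subject tables are
  aggregated by column means.
- **Grid search.**  K = 5 trial-level folds (class-stratified,
  round-robin after a seeded shuffle) — K is a package choice, kept
  configurable.  The default grid `n_estimators ∈ {11, 51, 101, 151,
  181, 201} × max_depth ∈ {31, 71, 131, ∞}` spans the regime where forest
  performance saturates and includes the configuration (181, 131) used by
  the tuned model.  Ties break toward the smaller (n_estimators,
  max_depth) pair, unbounded depth ordered last.

## Online loop

The recognizer consumes raw chunks, classifies once per 100 ms step
(first classification when the first full window is buffered; a stream of
L samples yields exactly `⌊(L−N)/S⌋+1` classifications), and gates
commands: an event fires only when the last `k` (default 2 — the minimal
multi-window constraint) predictions agree *and* differ from the active
command; otherwise the previous command is held, biasing the system
against unintended activation.  Rest maps to a hold command; the
class→command table is bijective and fixed.

Causal preprocessing is implemented as *buffered zero-phase* processing:
the recognizer keeps the trailing `N + 0.4 s` of raw samples and applies
the offline chain — wavelet shrinkage with fixed per-channel thresholds
estimated once from the training recording, then zero-phase band-pass and
notch — to that buffer alone, using the trailing N samples for features.
Forward–backward filtering over past samples is still strictly causal
with respect to the stream (verified by a mutation test) while keeping
the online feature distribution aligned with training; the newest buffer
edge necessarily carries filter edge effects, which is the honest causal
limitation.  Earlier single-pass causal IIR filtering was measurably
inconsistent with zero-phase training features (stop-band leakage differs
by the squared-vs-single magnitude response, which distorts the near-zero
rest residues), so the buffered design was adopted.  Without training
thresholds the shrinkage threshold is re-estimated per buffer.

Scoring: a prediction is scored iff its window lies entirely inside one
annotated execution interval; transition and rest windows carry no ground
truth and are excluded from the confusion matrix.

## Problem sizes

Defaults were chosen so a full study is desk-scale: the default offline
session is 80 trials (~830 s of 8-channel signal at 500 Hz, ~3 900
windows), the interactive replay 60 trials (~600 s), and the complete
grid search 24 cells × 5 folds.  The acceptance script runs the whole
study in a few minutes on one CPU.

## Known limitations

- Synthetic-data realism as listed above; results do not certify
  real-electrode performance, cross-subject transfer (out of scope), or
  robustness to electrode shift and fatigue.
- The universal-threshold denoiser assumes burst-structured broadband
  signals; it is destructive on stationary narrowband input.
- The online recognizer re-filters its full buffer at every step —
  simple and exactly consistent, but not the cheapest real-time
  implementation.
- Channel-exclusion thresholds are qualitative defaults, config-exposed;
  no adaptive line-frequency tracking, ICA artifact removal, or
  event-triggered segmentation is provided.
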