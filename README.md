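# emgintent

Surface-electromyography (sEMG) motion-intention recognition for upper-limb
assistance.  The package implements a complete, reproducible decoding
pipeline — synthetic multi-channel signal generation, standardized
preprocessing, sliding-window segmentation, time-domain feature fusion,
supervised classifier benchmarking with K-fold tuning, and a simulated
real-time command loop with a temporal consistency gate — for researchers
and engineers building myoelectric human–machine interfaces.

## The problem and the method

Voluntary muscle activation precedes visible limb motion, so sEMG recorded
over upper-limb muscles can decode a user's *intended* movement with lower
latency than kinematic or force sensing.  The pipeline decodes four motion
classes `Y = {y1, y2, y3, y4}` (seated rest, drinking-style lifting,
forearm flexion–extension, shoulder abduction) from an eight-channel
bipolar montage `x(t) = [x_1(t), …, x_8(t)]ᵀ` sampled at `f_s = 500 Hz`:

1. **Preprocessing.** Channel-quality inspection (saturation, baseline
   offset, transient artifacts repaired by local interpolation), wavelet
   soft-threshold denoising `x_w(t) = W⁻¹(T(W(x(t))))` with a db4 mother
   wavelet, 4 levels and the universal threshold
   `λ = σ̂ √(2 ln N)`, `σ̂ = median(|d₁|)/0.6745`, then zero-phase
   band-pass filtering `x_f(t) = x_w(t) ∗ h(t)` (Butterworth, 20 Hz to the
   highest realisable edge below Nyquist) and a 50 Hz notch.
2. **Windowing.** Only the steady execution interval `[t_s, t_e]` of each
   movement repetition is kept and cut into `N = f_s·Δt = 100`-sample
   windows (Δt = 200 ms) with a 100 ms step (50 % overlap).
3. **Features.** Eight time-domain descriptors per window per channel —
   MAV, VAR, RMS, waveform factor (RMS/MAV), skewness, kurtosis, impulse
   factor (peak/MAV) and clearance factor (peak/RMS) — screened singly and
   in fusions; the compact `RMS + IF + CF` triplet is the default fused
   representation.
4. **Modeling.** SVM (RBF), LDA, QDA, gradient boosting and random forest
   benchmarked under one protocol with **trial-level** 90/10 splitting
   (windows of one repetition never straddle train and test), accuracy
   `= N_correct / N_total`; the random forest is tuned by trial-level
   K-fold grid search over `n_estimators × max_depth`.
5. **Online loop.** A causal streaming recognizer classifies every 100 ms
   and maps labels to discrete device commands; a command is issued only
   when `k` consecutive predictions agree, suppressing transient
   misclassifications.

The study data behind this design are not public, so the package ships a
first-class synthetic-session generator: band-limited Gaussian carriers
(20–240 Hz) amplitude-modulated by class-specific per-channel activation
envelopes, plus baseline drift, 50 Hz line interference and broadband
noise, organised into the block/trial timing of a cue-driven protocol.

## Worked example

```python
import emgintent as ei
from emgintent.modeling import ClassifierSpec, SplitSpec, fit_and_evaluate, split_trials

# 1. simulate a labelled acquisition session (2 blocks x 5 trials/class)
protocol = ei.ProtocolSpec(n_blocks=2, trials_per_class_per_block=5)
rec, anns = ei.generate_session(
    protocol, ei.default_profiles(), ei.ContaminantSpec(), seed=7
)
print(f"session: {rec.duration:.0f} s, {rec.n_channels} channels, {len(anns)} trials")

# 2. condition the signals and window the execution segments
clean, report = ei.preprocess_recording(rec)
batch = ei.slide_session(ei.extract_effective(clean, anns), ei.WindowSpec(fs=rec.fs))
print(f"windows: {len(batch)} x {batch.spec.n_samples} samples x {batch.n_channels} channels")

# 3. fused time-domain features and a trial-level 90/10 evaluation
fm = ei.extract_features(batch, ["RMS", "IF", "CF"])
train_ids, test_ids = split_trials(anns, SplitSpec(0.9, seed=7))
result = fit_and_evaluate(
    fm, train_ids, test_ids,
    ClassifierSpec("RandomForest", {"n_estimators": 181, "max_depth": 131}, seed=7),
)
print(result.render())
```

Output:

```
session: 410 s, 8 channels, 40 trials
windows: 1960 x 100 samples x 8 channels
overall accuracy: 1.0000
confusion matrix (rows = true, cols = predicted):
    y1  y2  y3  y4
y1  49   0   0   0
y2   0  49   0   0
y3   0   0  49   0
y4   0   0   0  49
per-class accuracy: y1=1.0000, y2=1.0000, y3=1.0000, y4=1.0000
```

With the default, clearly separated activation profiles the four classes
are recoverable essentially perfectly; the generator's `overlap` parameter
blends the class gain vectors toward each other to make the task as hard
(down to chance level at `overlap=1`) as desired.

Feature transforms also compose with scikit-learn directly:

```python
from sklearn.pipeline import make_pipeline
from sklearn.ensemble import RandomForestClassifier
from emgintent import TimeDomainFeatures

pipe = make_pipeline(TimeDomainFeatures(subset=("RMS", "IF", "CF")),
                     RandomForestClassifier(n_estimators=181, random_state=0))
pipe.fit(batch.data, batch.labels)
```

## Command line

```bash
emg-intent simulate --seed 3 --out session/       # synthetic session (TSV + YAML)
emg-intent preprocess --in session/ --out clean/  # conditioning chain
emg-intent features --session session/ --subset RMS,IF,CF --out features.tsv
emg-intent evaluate --features features.tsv --out benchmark.tsv
emg-intent tune --features features.tsv --k 5 --out tuned/
emg-intent online-sim --model run/model.joblib --session session/ --k 2 --out online/
emg-intent run --seed 1 --out runs/full           # everything, one manifest
```

Every run directory contains the echoed configuration, per-stage seeds and
a manifest, so any artifact can be regenerated from its config + seed.

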