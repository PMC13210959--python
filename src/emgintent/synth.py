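"""Synthetic multi-channel surface-EMG session generator.

The signal model: each channel carries a band-limited, unit-variance
stochastic process (the superposition of many motor-unit action potentials
is well approximated by filtered Gaussian noise) that is amplitude-modulated
by a class-specific activation envelope, then contaminated by low-frequency
baseline drift, power-line interference and broadband sensor noise:

    x_c(t) = g_c * e(t) * s_c(t) + d(t) + l(t) + n(t)

where ``g_c`` is the channel gain of the active motion class, ``e(t)`` a
trapezoidal (or raised-cosine) envelope, ``s_c`` the carrier, ``d`` a slow
sinusoidal drift, ``l`` a 50 Hz line tone and ``n`` white Gaussian noise.

A trial consists of preparation, execution and return phases.  The envelope
rises during the tail of the preparation phase and decays during the return
phase, so the execution phase is a steady activation plateau; the trial
annotation marks exactly that execution interval.

Sessions are organised into blocks of randomised trials separated by rest
gaps, mirroring a cue-driven acquisition protocol.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .datatypes import (
    CHANNEL_NAMES,
    MOTION_CLASSES,
    Recording,
    TrialAnnotation,
)

__all__ = [
    "ActivationProfile",
    "ContaminantSpec",
    "ProtocolSpec",
    "make_carrier",
    "generate_trial",
    "generate_session",
    "default_profiles",
    "xor_profiles",
    "online_protocol",
]


@dataclass(frozen=True)
class ActivationProfile:
    """Class-specific per-channel activation pattern.

    ``per_channel_gain`` is the plateau amplitude multiplier (mV) applied to
    the unit-variance carrier on each channel.  The rest class keeps a small
    tonic gain on every channel: a static holding posture still produces
    low-level muscle tone.
    """

    class_id: str
    per_channel_gain: tuple[float, ...]
    envelope_shape: str = "trapezoid"
    rise_time: float = 0.4
    fall_time: float = 0.4

    def __post_init__(self) -> None:
        if self.class_id not in MOTION_CLASSES:
            raise ValueError(f"unknown class {self.class_id!r}")
        object.__setattr__(
            self, "per_channel_gain", tuple(float(g) for g in self.per_channel_gain)
        )
        if any(g < 0 for g in self.per_channel_gain):
            raise ValueError("channel gains must be non-negative")
        if self.envelope_shape not in ("trapezoid", "raised-cosine"):
            raise ValueError(f"unknown envelope shape {self.envelope_shape!r}")
        if self.rise_time < 0 or self.fall_time < 0:
            raise ValueError("rise/fall times must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.per_channel_gain)


@dataclass(frozen=True)
class ContaminantSpec:
    """Additive contaminants present in every phase of every trial."""

    drift_amplitude: float = 0.2   # mV
    drift_frequency: float = 0.5   # Hz, < 5
    line_amplitude: float = 0.2    # mV
    line_frequency: float = 50.0   # Hz
    noise_std: float = 0.1         # mV
    saturation_rail: float | None = None  # mV; clip if set

    def __post_init__(self) -> None:
        if min(self.drift_amplitude, self.line_amplitude, self.noise_std) < 0:
            raise ValueError("contaminant amplitudes must be non-negative")
        if self.line_frequency <= 0:
            raise ValueError("line frequency must be positive")
        if not 0 <= self.drift_frequency < 5:
            raise ValueError("drift frequency must lie in [0, 5) Hz")


@dataclass(frozen=True)
class ProtocolSpec:
    """Block/trial timing of an acquisition session.

    Defaults emulate a cue-driven protocol at 500 Hz: each movement cycle is
    5 s of execution framed by 2.5 s preparation and 2.5 s return, repeated
    in blocks separated by rest.  Four blocks of five repetitions give 20
    trials per motion class.
    """

    n_blocks: int = 4
    trials_per_class_per_block: int = 5
    prep_duration: float = 2.5
    execution_duration: float = 5.0
    return_duration: float = 2.5
    inter_block_rest: float = 10.0
    fs: float = 500.0
    carrier_band: tuple[float, float] = (20.0, 240.0)

    def __post_init__(self) -> None:
        for name in ("prep_duration", "execution_duration", "return_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inter_block_rest < 0:
            raise ValueError("inter_block_rest must be non-negative")
        if self.n_blocks < 1 or self.trials_per_class_per_block < 1:
            raise ValueError("need at least one block and one trial per class")
        if self.carrier_band[1] >= self.fs / 2:
            raise ValueError(
                f"carrier band edge {self.carrier_band[1]} Hz is not below the "
                f"Nyquist frequency {self.fs / 2} Hz"
            )

    @property
    def trial_duration(self) -> float:
        return self.prep_duration + self.execution_duration + self.return_duration

    @property
    def trials_per_class(self) -> int:
        return self.n_blocks * self.trials_per_class_per_block

    def trial_samples(self) -> tuple[int, int, int]:
        """(prep, execution, return) phase lengths in samples."""
        prep = int(round(self.prep_duration * self.fs))
        execu = int(round(self.execution_duration * self.fs))
        ret = int(round(self.return_duration * self.fs))
        return prep, execu, ret

    def total_samples(self, n_classes: int = len(MOTION_CLASSES)) -> int:
        prep, execu, ret = self.trial_samples()
        per_trial = prep + execu + ret
        n_trials = self.n_blocks * self.trials_per_class_per_block * n_classes
        rest = int(round(self.inter_block_rest * self.fs))
        return n_trials * per_trial + (self.n_blocks - 1) * rest


def online_protocol() -> ProtocolSpec:
    """Interactive-validation protocol: 15 repetitions of each of the four
    motions in one round, 5 s motion cycles separated by 5 s of return/rest
    (modelled as 2.5 s preparation + 2.5 s return around each execution)."""
    return ProtocolSpec(
        n_blocks=1,
        trials_per_class_per_block=15,
        prep_duration=2.5,
        execution_duration=5.0,
        return_duration=2.5,
        inter_block_rest=10.0,
    )


def make_carrier(
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance stochastic carrier band-limited to ``band``.

    White Gaussian noise is band-pass filtered (4th-order Butterworth,
    forward-backward) and standardised.  A fixed integer seed yields a
    bit-identical array.
    """
    if n_samples < 64:
        raise ValueError("need at least 64 samples for a stable carrier")
    low, high = band
    nyq = fs / 2
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if high >= nyq:
        raise ValueError(
            f"band edge {high} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x = x - x.mean()
    return x / x.std()


def _envelope(profile: ActivationProfile, protocol: ProtocolSpec) -> np.ndarray:
    """Activation envelope over one trial: ramps up at the end of the
    preparation phase, holds a plateau across execution, ramps down at the
    start of the return phase."""
    fs = protocol.fs
    prep, execu, ret = protocol.trial_samples()
    n = prep + execu + ret
    rise = min(int(round(profile.rise_time * fs)), prep)
    fall = min(int(round(profile.fall_time * fs)), ret)
    env = np.zeros(n)
    env[prep : prep + execu] = 1.0
    if rise > 0:
        ramp = np.linspace(0.0, 1.0, rise, endpoint=False)
        if profile.envelope_shape == "raised-cosine":
            ramp = 0.5 * (1 - np.cos(np.pi * ramp))
        env[prep - rise : prep] = ramp
    if fall > 0:
        ramp = np.linspace(1.0, 0.0, fall + 1)[1:]
        if profile.envelope_shape == "raised-cosine":
            ramp = 0.5 * (1 - np.cos(np.pi * ramp))
        env[prep + execu : prep + execu + fall] = ramp
    return env


def _contaminate(
    clean: np.ndarray,
    contaminants: ContaminantSpec,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add drift, line interference and noise (independent phase/noise per
    channel), then clip at the saturation rail if one is set."""
    n, m = clean.shape
    t = np.arange(n) / fs
    out = clean.copy()
    c = contaminants
    for ch in range(m):
        if c.drift_amplitude > 0 and c.drift_frequency > 0:
            out[:, ch] += c.drift_amplitude * np.sin(
                2 * np.pi * c.drift_frequency * t + rng.uniform(0, 2 * np.pi)
            )
        if c.line_amplitude > 0:
            out[:, ch] += c.line_amplitude * np.sin(
                2 * np.pi * c.line_frequency * t + rng.uniform(0, 2 * np.pi)
            )
        if c.noise_std > 0:
            out[:, ch] += rng.normal(0.0, c.noise_std, size=n)
    if c.saturation_rail is not None:
        np.clip(out, -c.saturation_rail, c.saturation_rail, out=out)
    return out


def generate_trial(
    profile: ActivationProfile,
    contaminants: ContaminantSpec,
    protocol: ProtocolSpec,
    seed: int | np.random.Generator,
    trial_id: int = 0,
) -> tuple[np.ndarray, TrialAnnotation]:
    """One trial's signal matrix plus its execution-interval annotation.

    Returns ``(data, annotation)`` with ``data`` of shape
    (trial samples, n_channels) and the annotation covering exactly the
    execution phase (sample offsets local to the trial).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prep, execu, ret = protocol.trial_samples()
    n = prep + execu + ret
    m = profile.n_channels
    env = _envelope(profile, protocol)
    clean = np.empty((n, m))
    for ch in range(m):
        carrier = make_carrier(n, protocol.fs, protocol.carrier_band, rng)
        clean[:, ch] = profile.per_channel_gain[ch] * env * carrier
    data = _contaminate(clean, contaminants, protocol.fs, rng)
    ann = TrialAnnotation(trial_id, profile.class_id, prep, prep + execu)
    return data, ann


ProfileSet = Mapping[str, "ActivationProfile | Sequence[ActivationProfile]"]


def _as_profile_lists(profiles: ProfileSet) -> dict[str, list[ActivationProfile]]:
    out: dict[str, list[ActivationProfile]] = {}
    for cid in MOTION_CLASSES:
        if cid not in profiles:
            raise ValueError(f"missing activation profile for class {cid}")
        p = profiles[cid]
        plist = [p] if isinstance(p, ActivationProfile) else list(p)
        if not plist:
            raise ValueError(f"empty profile list for class {cid}")
        for q in plist:
            if q.class_id != cid:
                raise ValueError(
                    f"profile labelled {q.class_id} registered under class {cid}"
                )
        out[cid] = plist
    return out


def generate_session(
    protocol: ProtocolSpec,
    profiles: ProfileSet,
    contaminants: ContaminantSpec,
    seed: int,
) -> tuple[Recording, list[TrialAnnotation]]:
    """A full multi-block session: randomised trial order within each block,
    rest gaps between blocks, deterministic for a fixed seed.

    ``profiles`` maps each class id to one profile or to several
    alternatives; with several, each trial draws one at random, modelling
    within-class execution variability.
    """
    rng = np.random.default_rng(seed)
    plists = _as_profile_lists(profiles)
    m = plists[MOTION_CLASSES[0]][0].n_channels
    for cid, plist in plists.items():
        for p in plist:
            if p.n_channels != m:
                raise ValueError("all profiles must share one channel count")
    channel_names = CHANNEL_NAMES if m == len(CHANNEL_NAMES) else tuple(
        f"ch{i}" for i in range(m)
    )

    rest_samples = int(round(protocol.inter_block_rest * protocol.fs))
    chunks: list[np.ndarray] = []
    annotations: list[TrialAnnotation] = []
    offset = 0
    trial_counter = itertools.count()
    for block in range(protocol.n_blocks):
        if block > 0 and rest_samples > 0:
            gap = _contaminate(
                np.zeros((rest_samples, m)), contaminants, protocol.fs, rng
            )
            chunks.append(gap)
            offset += rest_samples
        order = [
            cid
            for cid in MOTION_CLASSES
            for _ in range(protocol.trials_per_class_per_block)
        ]
        order = [order[i] for i in rng.permutation(len(order))]
        for cid in order:
            plist = plists[cid]
            profile = plist[rng.integers(len(plist))] if len(plist) > 1 else plist[0]
            data, ann = generate_trial(
                profile, contaminants, protocol, rng, trial_id=next(trial_counter)
            )
            chunks.append(data)
            annotations.append(
                replace(
                    ann,
                    start_sample=ann.start_sample + offset,
                    end_sample=ann.end_sample + offset,
                )
            )
            offset += data.shape[0]
    data = np.concatenate(chunks, axis=0)
    rec = Recording(
        data,
        protocol.fs,
        channel_names,
        meta={"seed": int(seed), "units": "mV", "generator": "emgintent.synth"},
    )
    return rec, annotations


# ---------------------------------------------------------------------------
# Default class activation patterns


def default_profiles(
    overlap: float = 0.0,
    n_channels: int = 8,
    active_gain: float = 1.0,
    tone_gain: float = 0.05,
) -> dict[str, ActivationProfile]:
    """Distinct per-class channel support patterns over the eight-muscle
    montage.  ``overlap`` in [0, 1] blends every class's gain vector toward
    the across-class mean: 0 keeps the patterns fully distinct, 1 makes all
    classes identical (chance-level separability)."""
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    base = {
        # channel order: BB, TB, AD, PM, LD, PD, TR, LAT
        "y1": np.full(n_channels, tone_gain),
        "y2": np.array([1.0, 0.1, 0.8, 0.6, 0.1, 0.1, 0.1, 0.1]),
        "y3": np.array([0.9, 1.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]),
        "y4": np.array([0.1, 0.1, 0.1, 0.1, 1.0, 0.7, 0.8, 0.1]),
    }
    if n_channels != 8:
        rng = np.random.default_rng(0)  # fixed pattern, not a noise source
        for cid in ("y2", "y3", "y4"):
            pattern = np.full(n_channels, 0.1)
            idx = rng.permutation(n_channels)[: max(1, n_channels // 3)]
            pattern[idx] = 1.0
            base[cid] = pattern
    for cid in ("y2", "y3", "y4"):
        base[cid] = base[cid] * active_gain
    mean = np.mean([base[c] for c in MOTION_CLASSES], axis=0)
    return {
        cid: ActivationProfile(
            cid, tuple((1 - overlap) * base[cid] + overlap * mean)
        )
        for cid in MOTION_CLASSES
    }


def xor_profiles(
    n_channels: int = 8,
    high: float = 2.0,
    low: float = 0.2,
    tone_gain: float = 0.05,
) -> dict[str, list[ActivationProfile]]:
    """Per-class profile *pairs* with equal class-mean gain vectors.

    Classes y1/y2 differ only in the joint pattern over channels 0-1
    (anti-correlated vs correlated activation) and y3/y4 likewise over
    channels 2-3, so no linear boundary in amplitude-feature space separates
    the pairs while a nonlinear classifier can.
    """

    def pattern(pairs: dict[int, float]) -> tuple[float, ...]:
        g = np.full(n_channels, tone_gain)
        for ch, v in pairs.items():
            g[ch] = v
        return tuple(g)

    return {
        "y1": [
            ActivationProfile("y1", pattern({0: high, 1: low})),
            ActivationProfile("y1", pattern({0: low, 1: high})),
        ],
        "y2": [
            ActivationProfile("y2", pattern({0: high, 1: high})),
            ActivationProfile("y2", pattern({0: low, 1: low})),
        ],
        "y3": [
            ActivationProfile("y3", pattern({2: high, 3: low})),
            ActivationProfile("y3", pattern({2: low, 3: high})),
        ],
        "y4": [
            ActivationProfile("y4", pattern({2: high, 3: high})),
            ActivationProfile("y4", pattern({2: low, 3: low})),
        ],
    }
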