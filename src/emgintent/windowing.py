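"""Execution-segment extraction and sliding-window segmentation.

Only the steady execution interval of each trial is analysed; preparation
and return samples are discarded.  Each retained segment is cut into
fixed-length windows of N = fs * dt samples advanced by a fixed step, the
standard quasi-stationary representation for myoelectric pattern
recognition (defaults: 200 ms windows, 100 ms step = 50% overlap).
Windows never span trial boundaries, so a trial-level train/test split can
never leak windows across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import Recording, TrialAnnotation, validate_annotations

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "Segment",
    "WindowBatch",
    "samples_per_window",
    "extract_effective",
    "slide_windows",
    "slide_session",
]


def samples_per_window(fs: float, dt: float) -> int:
    """N = fs * dt, required to be a positive integer (no silent rounding)."""
    if fs <= 0 or dt <= 0:
        raise ValueError("fs and window duration must be positive")
    n = fs * dt
    nearest = round(n)
    if nearest < 1 or abs(n - nearest) > 1e-6 * max(1.0, nearest):
        raise ValueError(
            f"fs * dt = {n} is not a positive integer sample count"
        )
    return int(nearest)


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-length sliding-window parameters."""

    window_duration: float = 0.2  # seconds
    step_duration: float = 0.1    # seconds
    fs: float = 500.0

    def __post_init__(self) -> None:
        n = samples_per_window(self.fs, self.window_duration)
        s = samples_per_window(self.fs, self.step_duration)
        if not 0 < s <= n:
            raise ValueError("step must satisfy 0 < step <= window length")

    @property
    def n_samples(self) -> int:
        return samples_per_window(self.fs, self.window_duration)

    @property
    def step_samples(self) -> int:
        return samples_per_window(self.fs, self.step_duration)

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.step_samples / self.n_samples


@dataclass(frozen=True)
class Segment:
    """The retained execution-phase signal of one trial."""

    trial_id: int
    label: str
    start_sample: int  # absolute offset of the segment in its recording
    data: np.ndarray   # (n_samples, n_channels)
    channel_names: tuple[str, ...] = ()


@dataclass
class WindowBatch:
    """Stack of fixed-length windows with per-window provenance."""

    data: np.ndarray        # (n_windows, N, n_channels)
    labels: np.ndarray      # (n_windows,) motion-class ids
    trial_ids: np.ndarray   # (n_windows,)
    start_samples: np.ndarray  # (n_windows,) absolute start index
    channel_names: tuple[str, ...] = ()
    spec: WindowSpec | None = None

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.trial_ids) == len(self.start_samples) == n):
            raise ValueError("provenance arrays must match the window count")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


def extract_effective(
    rec: Recording, annotations: Sequence[TrialAnnotation]
) -> list[Segment]:
    """One segment per annotation, exactly the samples [start, end)."""
    anns = validate_annotations(annotations, rec.n_samples)
    return [
        Segment(
            a.trial_id,
            a.label,
            a.start_sample,
            rec.data[a.start_sample : a.end_sample],
            rec.channel_names,
        )
        for a in anns
    ]


def slide_windows(segment: Segment, spec: WindowSpec) -> WindowBatch:
    """Cut one segment into overlapping fixed-length windows.

    Emits floor((L - N) / S) + 1 windows for a segment of length L >= N;
    the trailing remainder shorter than N is dropped.  A segment shorter
    than one window yields an empty batch with a logged warning.
    """
    n, s = spec.n_samples, spec.step_samples
    data = np.atleast_2d(segment.data)
    length = data.shape[0]
    m = data.shape[1]
    if length < n:
        logger.warning(
            "trial %s segment of %d samples shorter than the %d-sample window; "
            "no windows emitted",
            segment.trial_id,
            length,
            n,
        )
        return WindowBatch(
            np.empty((0, n, m)),
            np.empty(0, dtype=object),
            np.empty(0, dtype=int),
            np.empty(0, dtype=int),
            segment.channel_names,
            spec,
        )
    count = (length - n) // s + 1
    starts = np.arange(count) * s
    windows = np.stack([data[st : st + n] for st in starts])
    return WindowBatch(
        windows,
        np.array([segment.label] * count, dtype=object),
        np.full(count, segment.trial_id, dtype=int),
        segment.start_sample + starts,
        segment.channel_names,
        spec,
    )


def slide_session(
    segments: Sequence[Segment], spec: WindowSpec
) -> WindowBatch:
    """Window every segment with identical parameters and concatenate."""
    batches = [slide_windows(seg, spec) for seg in segments]
    batches = [b for b in batches if len(b) > 0]
    if not batches:
        m = segments[0].data.shape[1] if segments else 0
        names = segments[0].channel_names if segments else ()
        return WindowBatch(
            np.empty((0, spec.n_samples, m)),
            np.empty(0, dtype=object),
            np.empty(0, dtype=int),
            np.empty(0, dtype=int),
            names,
            spec,
        )
    return WindowBatch(
        np.concatenate([b.data for b in batches]),
        np.concatenate([b.labels for b in batches]),
        np.concatenate([b.trial_ids for b in batches]),
        np.concatenate([b.start_samples for b in batches]),
        batches[0].channel_names,
        spec,
    )
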