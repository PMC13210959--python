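"""Core containers shared across the pipeline.

A session is a continuous multi-channel surface-EMG recording plus a table
of trial annotations.  Each annotation marks the steady execution interval
of one movement repetition as a half-open, 0-based sample interval
``[start_sample, end_sample)``; everything downstream (segment extraction,
windowing, trial-level splitting) consumes these intervals verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The four motion classes: rest, drinking, forearm flexion-extension,
#: shoulder abduction.
MOTION_CLASSES: tuple[str, ...] = ("y1", "y2", "y3", "y4")

MOTION_DESCRIPTIONS: dict[str, str] = {
    "y1": "seated rest (static holding posture)",
    "y2": "composite lifting motion simulating drinking assistance",
    "y3": "forearm flexion-extension",
    "y4": "shoulder abduction",
}

#: Default eight-channel bipolar montage over the upper-limb muscles.
CHANNEL_NAMES: tuple[str, ...] = (
    "biceps_brachii",
    "triceps_brachii",
    "anterior_deltoid",
    "pectoralis_major",
    "lateral_deltoid",
    "posterior_deltoid",
    "trapezius",
    "latissimus_dorsi",
)


@dataclass
class Recording:
    """Synchronized multi-channel signal matrix.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in millivolts, one column per channel.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        One name per column.
    meta : dict
        Free-form provenance (seed, units, processing history).
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} data columns"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class TrialAnnotation:
    """One movement repetition: label plus its steady execution interval."""

    trial_id: int
    label: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.label not in MOTION_CLASSES:
            raise ValueError(
                f"unknown motion label {self.label!r}; expected one of {MOTION_CLASSES}"
            )
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError(
                f"trial {self.trial_id}: invalid interval "
                f"[{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


def validate_annotations(
    annotations: Sequence[TrialAnnotation], n_samples: int | None = None
) -> list[TrialAnnotation]:
    """Check that annotations are in-bounds, sorted and non-overlapping.

    Returns the annotations sorted by start sample.  Raises ``ValueError``
    naming the offending trial otherwise.
    """
    anns = sorted(annotations, key=lambda a: a.start_sample)
    for a in anns:
        if n_samples is not None and a.end_sample > n_samples:
            raise ValueError(
                f"trial {a.trial_id} extends to sample {a.end_sample}, "
                f"beyond the {n_samples}-sample recording"
            )
    for prev, cur in zip(anns, anns[1:]):
        if cur.start_sample < prev.end_sample:
            raise ValueError(
                f"trials {prev.trial_id} and {cur.trial_id} overlap"
            )
    return anns
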