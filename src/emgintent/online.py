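"""Streaming recognition with a temporal consistency gate.

The online loop ingests raw samples chunk-by-chunk, classifies the most
recent window once per step interval, and converts predictions into device
commands through a deterministic class-to-command table.  A command is
emitted only when the last ``k`` consecutive predictions agree and differ
from the currently active command; otherwise the previous command is held.
This suppresses transient misclassifications at the cost of k-1 steps of
switching latency.

Preprocessing is strictly causal: the recognizer keeps a short raw context
buffer (the current window plus a trailing context of past samples) and
applies the offline conditioning chain — wavelet soft-threshold shrinkage
with a fixed, training-derived threshold, then zero-phase band-pass and
notch filtering — to that buffer alone.  Filtering forward-backward inside
a buffer of past samples shifts no onsets yet never touches future input;
the trailing edge of the buffer (the newest samples) still carries edge
effects, which is the genuine causal limitation.  When no training
thresholds are supplied the shrinkage threshold is re-estimated from each
buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import MOTION_CLASSES, Recording, TrialAnnotation, validate_annotations
from .features import normalize_subset, _batch_features
from .modeling import EvaluationReport, confusion_and_per_class
from .preprocess import DenoiseSpec, FilterSpec, bandpass_notch, wavelet_denoise
from .windowing import WindowSpec

__all__ = [
    "DEFAULT_COMMAND_MAP",
    "ConsistencySpec",
    "CommandEvent",
    "ConsistencyGate",
    "StreamState",
    "OnlineRecognizer",
    "map_label_to_command",
    "step",
    "simulate_online_session",
]

#: Rest maps to a hold (no-motion) command; each active motion to its
#: assistance command.
DEFAULT_COMMAND_MAP: dict[str, str] = {
    "y1": "CMD_HOLD",
    "y2": "CMD_DRINK",
    "y3": "CMD_FLEX_EXTEND",
    "y4": "CMD_ABDUCT",
}


@dataclass(frozen=True)
class ConsistencySpec:
    """Gate parameters: required agreement length and the command table."""

    k: int = 2
    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COMMAND_MAP))

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if set(self.mapping) != set(MOTION_CLASSES):
            raise ValueError("command mapping must cover exactly the four classes")
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("command mapping must be bijective")


@dataclass(frozen=True)
class CommandEvent:
    """A command emission: when (sample index of the window end), what."""

    time: int
    command: str
    source_label: str


def map_label_to_command(label: str, spec: ConsistencySpec) -> str:
    """Deterministic class-to-command lookup."""
    try:
        return spec.mapping[label]
    except KeyError:
        raise ValueError(f"label {label!r} not in the command mapping") from None


class ConsistencyGate:
    """Emit a command only after k consecutive identical predictions that
    differ from the active command; hold the previous command otherwise."""

    def __init__(self, spec: ConsistencySpec) -> None:
        self.spec = spec
        self.history: list[str] = []
        self.active_command: str | None = None

    def update(self, label: str, time: int) -> CommandEvent | None:
        self.history.append(label)
        if len(self.history) > self.spec.k:
            self.history.pop(0)
        if len(self.history) < self.spec.k or len(set(self.history)) != 1:
            return None
        command = map_label_to_command(label, self.spec)
        if command == self.active_command:
            return None
        self.active_command = command
        return CommandEvent(time, command, label)


@dataclass
class StreamState:
    """Introspectable state of an online run."""

    buffer: np.ndarray            # most recent <= N filtered samples
    samples_seen: int = 0
    windows_processed: int = 0
    history: list[str] = field(default_factory=list)
    active_command: str | None = None


class OnlineRecognizer:
    """Causal streaming wrapper around a trained window classifier.

    Parameters
    ----------
    model : fitted classifier
        Predicts a motion label from one feature row.
    feature_subset : sequence of str
        Features the model was trained on (channel-major layout).
    window_spec : WindowSpec
        Window/step geometry; a classification happens each time the stream
        advances by one step interval once the first full window is seen.
    filter_spec : FilterSpec
        Band-pass/notch design, applied zero-phase inside the causal buffer.
    denoise_spec : DenoiseSpec
        Wavelet shrinkage applied to the buffer before filtering.
    denoise_thresholds : array of shape (n_channels,), optional
        Per-channel shrinkage thresholds estimated from the training
        recording; without them each buffer estimates its own.
    consistency : ConsistencySpec
        Command gate.
    context_duration : float
        Seconds of past samples retained behind the current window to
        absorb wavelet/filter boundary effects.
    """

    def __init__(
        self,
        model,
        feature_subset: Sequence[str],
        window_spec: WindowSpec,
        filter_spec: FilterSpec | None = None,
        consistency: ConsistencySpec | None = None,
        n_channels: int = 8,
        denoise_spec: DenoiseSpec | None = None,
        denoise_thresholds: np.ndarray | None = None,
        context_duration: float = 0.4,
    ) -> None:
        self.model = model
        self.feature_subset = normalize_subset(feature_subset)
        self.window_spec = window_spec
        self.consistency = consistency or ConsistencySpec()
        self.n_channels = n_channels
        self.filter_spec = filter_spec or FilterSpec()
        self.denoise_spec = denoise_spec or DenoiseSpec()
        if denoise_thresholds is not None:
            denoise_thresholds = np.asarray(denoise_thresholds, dtype=float)
            if denoise_thresholds.shape != (n_channels,):
                raise ValueError(
                    f"need one denoise threshold per channel ({n_channels})"
                )
        self.denoise_thresholds = denoise_thresholds
        self._context = int(round(context_duration * window_spec.fs))
        self._gate = ConsistencyGate(self.consistency)
        self._buffer = np.empty((0, n_channels))
        self._samples_seen = 0
        self._next_window_end = window_spec.n_samples
        self.predictions: list[tuple[int, str]] = []  # (window end, label)
        self.events: list[CommandEvent] = []

    @property
    def state(self) -> StreamState:
        return StreamState(
            buffer=self._buffer.copy(),
            samples_seen=self._samples_seen,
            windows_processed=len(self.predictions),
            history=list(self._gate.history),
            active_command=self._gate.active_command,
        )

    def _condition_buffer(self, raw: np.ndarray) -> np.ndarray:
        """Offline-equivalent conditioning of the buffered past samples:
        wavelet shrinkage (fixed training threshold when available) then
        zero-phase band-pass + notch, per channel."""
        out = np.empty_like(raw)
        for ch in range(raw.shape[1]):
            lam = (
                float(self.denoise_thresholds[ch])
                if self.denoise_thresholds is not None
                else None
            )
            x = wavelet_denoise(raw[:, ch], self.denoise_spec, lam=lam)
            out[:, ch] = bandpass_notch(x, self.filter_spec, self.window_spec.fs)
        return out

    def _classify_window(self, window: np.ndarray) -> str:
        feats = _batch_features(window[None, :, :], self.feature_subset)
        row = feats.reshape(1, -1)
        n_expected = getattr(self.model, "n_features_in_", row.shape[1])
        if row.shape[1] != n_expected:
            raise ValueError(
                f"model expects {n_expected} features but the stream produced "
                f"{row.shape[1]}; feature subset or channel count mismatch"
            )
        return str(self.model.predict(row)[0])

    def step(self, chunk: np.ndarray) -> list[CommandEvent]:
        """Ingest new samples; classify at each due step boundary.

        Returns the command events emitted while consuming this chunk.
        Strictly causal: only samples received so far influence any output.
        """
        chunk = np.atleast_2d(np.asarray(chunk, dtype=float))
        if chunk.shape[1] != self.n_channels:
            raise ValueError(
                f"chunk has {chunk.shape[1]} channels, expected {self.n_channels}"
            )
        n = self.window_spec.n_samples
        s = self.window_spec.step_samples
        # Append first, trim after draining pending windows, so arbitrary
        # chunk sizes are supported without losing window samples.
        self._buffer = np.vstack([self._buffer, chunk])
        self._samples_seen += chunk.shape[0]
        emitted: list[CommandEvent] = []
        while self._samples_seen >= self._next_window_end:
            offset = self._samples_seen - self._next_window_end
            conditioned = self._condition_buffer(self._buffer)
            window = (
                conditioned[-n:]
                if offset == 0
                else conditioned[-(n + offset) : -offset]
            )
            label = self._classify_window(window)
            self.predictions.append((self._next_window_end, label))
            event = self._gate.update(label, self._next_window_end)
            if event is not None:
                emitted.append(event)
                self.events.append(event)
            self._next_window_end += s
        self._buffer = self._buffer[-(n + self._context) :]
        return emitted


def step(recognizer: OnlineRecognizer, chunk: np.ndarray) -> list[CommandEvent]:
    """Functional alias for :meth:`OnlineRecognizer.step`."""
    return recognizer.step(chunk)


def simulate_online_session(
    rec: Recording,
    annotations: Sequence[TrialAnnotation],
    model,
    consistency: ConsistencySpec | None = None,
    window_spec: WindowSpec | None = None,
    filter_spec: FilterSpec | None = None,
    feature_subset: Sequence[str] = ("RMS", "IF", "CF"),
    denoise_spec: DenoiseSpec | None = None,
    denoise_thresholds: np.ndarray | None = None,
) -> tuple[list[CommandEvent], EvaluationReport]:
    """Replay a recorded session through the online loop.

    The raw recording is streamed in step-sized chunks through the causal
    recognizer.  Every prediction whose window lies entirely inside a trial's
    execution interval is scored against that trial's label; windows spanning
    rest or transition periods carry no ground truth and are not scored.
    """
    window_spec = window_spec or WindowSpec(fs=rec.fs)
    anns = validate_annotations(annotations, rec.n_samples)
    recognizer = OnlineRecognizer(
        model,
        feature_subset,
        window_spec,
        filter_spec,
        consistency,
        n_channels=rec.n_channels,
        denoise_spec=denoise_spec,
        denoise_thresholds=denoise_thresholds,
    )
    s = window_spec.step_samples
    for start in range(0, rec.n_samples, s):
        recognizer.step(rec.data[start : start + s])

    n = window_spec.n_samples
    bounds = [(a.start_sample, a.end_sample, a.label) for a in anns]
    y_true: list[str] = []
    y_pred: list[str] = []
    for end, label in recognizer.predictions:
        w_start = end - n
        for a_start, a_end, a_label in bounds:
            if w_start >= a_start and end <= a_end:
                y_true.append(a_label)
                y_pred.append(label)
                break
    if not y_true:
        raise ValueError("no prediction window fell inside an annotated trial")
    report = confusion_and_per_class(y_pred, y_true)
    report.provenance = {
        "mode": "online",
        "k": (consistency or ConsistencySpec()).k,
        "n_trials": len(anns),
        "n_scored_windows": len(y_true),
        "n_predictions": len(recognizer.predictions),
        "n_command_events": len(recognizer.events),
        "feature_subset": list(feature_subset),
    }
    return recognizer.events, report
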