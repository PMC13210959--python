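"""Time-domain window descriptors and feature-matrix assembly.

Eight descriptors per channel per window:

========  ==========================================================
MAV       mean absolute value, (1/N) sum |x_i|
VAR       unbiased sample variance (N-1 denominator)
RMS       root mean square, sqrt((1/N) sum x_i^2)
WF        waveform factor, RMS / MAV  (>= 1 by Cauchy-Schwarz)
SK        skewness, population third standardised moment
KU        kurtosis, population fourth standardised moment (Pearson,
          non-excess; Gaussian -> 3)
IF        impulse factor, max|x| / MAV  (>= 1)
CF        clearance factor as used here: max|x| / RMS — numerically the
          conventional crest factor; the name follows the convention of
          the peak-statistics feature set this package implements
========  ==========================================================

Amplitude features (MAV, VAR, RMS) carry contraction intensity; the ratio
features (WF, IF, CF) and shape moments (SK, KU) are scale-invariant.
Windows on which a ratio is undefined (zero MAV or zero variance) are
dropped from the assembled matrix with a logged count rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .windowing import WindowBatch

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = ("MAV", "VAR", "RMS", "WF", "SK", "KU", "IF", "CF")

__all__ = [
    "FEATURE_NAMES",
    "mav",
    "var",
    "rms",
    "wf",
    "sk",
    "ku",
    "impulse_factor",
    "clearance_factor",
    "FeatureMatrix",
    "extract_features",
    "TimeDomainFeatures",
]


def _check(x: np.ndarray, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D window")
    if x.size < min_len:
        raise ValueError(f"window needs at least {min_len} samples, got {x.size}")
    return x


def mav(x: np.ndarray) -> float:
    """Mean absolute value."""
    x = _check(x)
    return float(np.mean(np.abs(x)))


def var(x: np.ndarray) -> float:
    """Unbiased sample variance."""
    x = _check(x, min_len=2)
    return float(np.var(x, ddof=1))


def rms(x: np.ndarray) -> float:
    """Root mean square."""
    x = _check(x)
    return float(np.sqrt(np.mean(x**2)))


def wf(x: np.ndarray) -> float:
    """Waveform factor RMS/MAV; NaN when MAV is zero."""
    x = _check(x)
    m = mav(x)
    return float(rms(x) / m) if m > 0 else float("nan")


def _std_moment(x: np.ndarray, order: int) -> float:
    x = _check(x, min_len=2)
    centred = x - x.mean()
    m2 = np.mean(centred**2)
    if m2 == 0:
        return float("nan")
    return float(np.mean(centred**order) / m2 ** (order / 2))


def sk(x: np.ndarray) -> float:
    """Skewness (population moments); NaN for a constant window."""
    return _std_moment(x, 3)


def ku(x: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis; NaN for a constant window."""
    return _std_moment(x, 4)


def impulse_factor(x: np.ndarray) -> float:
    """Peak absolute amplitude over MAV; NaN when MAV is zero."""
    x = _check(x)
    m = mav(x)
    return float(np.max(np.abs(x)) / m) if m > 0 else float("nan")


def clearance_factor(x: np.ndarray) -> float:
    """Peak absolute amplitude over RMS; NaN when RMS is zero."""
    x = _check(x)
    r = rms(x)
    return float(np.max(np.abs(x)) / r) if r > 0 else float("nan")


FEATURE_FUNCS = {
    "MAV": mav,
    "VAR": var,
    "RMS": rms,
    "WF": wf,
    "SK": sk,
    "KU": ku,
    "IF": impulse_factor,
    "CF": clearance_factor,
}


def _batch_features(data: np.ndarray, subset: Sequence[str]) -> np.ndarray:
    """Vectorised per-channel descriptors for a (n, N, m) window stack.

    Returns an array of shape (n, m, len(subset)).
    """
    n, _, m = data.shape
    absx = np.abs(data)
    mav_ = absx.mean(axis=1)
    rms_ = np.sqrt((data**2).mean(axis=1))
    peak = absx.max(axis=1)
    centred = data - data.mean(axis=1, keepdims=True)
    m2 = (centred**2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = {
            "MAV": mav_,
            "VAR": (centred**2).sum(axis=1) / (data.shape[1] - 1),
            "RMS": rms_,
            "WF": np.where(mav_ > 0, rms_ / mav_, np.nan),
            "SK": np.where(m2 > 0, (centred**3).mean(axis=1) / m2**1.5, np.nan),
            "KU": np.where(m2 > 0, (centred**4).mean(axis=1) / m2**2, np.nan),
            "IF": np.where(mav_ > 0, peak / mav_, np.nan),
            "CF": np.where(rms_ > 0, peak / rms_, np.nan),
        }
    return np.stack([values[f] for f in subset], axis=2)


def normalize_subset(subset: Sequence[str]) -> list[str]:
    """Validate names; deduplicate preserving order (with a warning)."""
    if not subset:
        raise ValueError("feature subset must be non-empty")
    seen: list[str] = []
    for f in subset:
        if f not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {f!r}; choose from {FEATURE_NAMES}")
        if f in seen:
            logger.warning("duplicate feature %s in subset; deduplicated", f)
        else:
            seen.append(f)
    return seen


@dataclass
class FeatureMatrix:
    """Windows x (channels x features) values with per-window provenance.

    ``X`` columns are channel-major, feature-minor: for each channel in
    recording order, the selected features in subset order, named
    ``<channel>_<feature>``.
    """

    X: pd.DataFrame
    labels: np.ndarray
    trial_ids: np.ndarray
    feature_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.labels) == len(self.trial_ids)):
            raise ValueError("rows, labels and trial ids must align")
        if self.X.isna().any().any():
            raise ValueError("assembled feature matrix must not contain NaN")

    def __len__(self) -> int:
        return len(self.X)

    def to_frame(self) -> pd.DataFrame:
        frame = self.X.copy()
        frame.insert(0, "trial_id", self.trial_ids)
        frame.insert(1, "label", self.labels)
        return frame


def extract_features(
    batch: WindowBatch,
    subset: Sequence[str] = ("RMS", "IF", "CF"),
    layout: str = "per_channel",
) -> FeatureMatrix:
    """Assemble the fused feature matrix for a window batch.

    ``layout='per_channel'`` concatenates per-channel values (m x |subset|
    columns, preserving the spatial pattern across electrodes);
    ``layout='channel_mean'`` averages each feature over channels.
    Windows with any undefined value are dropped with a logged count.
    """
    subset = normalize_subset(subset)
    if layout not in ("per_channel", "channel_mean"):
        raise ValueError(f"unknown layout {layout!r}")
    n, _, m = batch.data.shape
    names = batch.channel_names or tuple(f"ch{i}" for i in range(m))
    if n == 0:
        cols = (
            [f"{ch}_{f}" for ch in names for f in subset]
            if layout == "per_channel"
            else list(subset)
        )
        return FeatureMatrix(
            pd.DataFrame(np.empty((0, len(cols))), columns=cols),
            batch.labels,
            batch.trial_ids,
            tuple(subset),
        )
    feats = _batch_features(batch.data, subset)  # (n, m, f)
    if layout == "per_channel":
        flat = feats.reshape(n, m * len(subset))  # channel-major, feature-minor
        cols = [f"{ch}_{f}" for ch in names for f in subset]
    else:
        flat = feats.mean(axis=1)
        cols = list(subset)
    ok = np.isfinite(flat).all(axis=1)
    dropped = int(n - ok.sum())
    if dropped:
        logger.warning(
            "dropped %d window(s) with undefined feature values", dropped
        )
    return FeatureMatrix(
        pd.DataFrame(flat[ok], columns=cols),
        batch.labels[ok],
        batch.trial_ids[ok],
        tuple(subset),
    )


class TimeDomainFeatures(BaseEstimator, TransformerMixin):
    """sklearn transformer mapping a window stack to time-domain features.

    Accepts ``X`` of shape (n_windows, N, n_channels) and returns a 2-D
    array of shape (n_windows, n_channels * len(subset)) in channel-major,
    feature-minor order.  Stateless; ``fit`` only records the input shape.
    """

    def __init__(
        self, subset: Sequence[str] = ("RMS", "IF", "CF"), layout: str = "per_channel"
    ) -> None:
        self.subset = subset
        self.layout = layout

    def fit(self, X, y=None):  # noqa: N803 - sklearn API
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a (n_windows, N, n_channels) stack")
        normalize_subset(self.subset)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        self.n_channels_ = X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:  # noqa: N803
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a (n_windows, N, n_channels) stack")
        subset = normalize_subset(self.subset)
        feats = _batch_features(X, subset)
        if self.layout == "channel_mean":
            return feats.mean(axis=1)
        if self.layout != "per_channel":
            raise ValueError(f"unknown layout {self.layout!r}")
        return feats.reshape(X.shape[0], X.shape[2] * len(subset))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        subset = normalize_subset(self.subset)
        m = getattr(self, "n_channels_", None)
        if m is None:
            raise ValueError("call fit before get_feature_names_out")
        if self.layout == "channel_mean":
            return np.asarray(subset, dtype=object)
        return np.asarray(
            [f"ch{i}_{f}" for i in range(m) for f in subset], dtype=object
        )
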