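"""Plain-text I/O for recordings and annotation tables.

A recording is stored as ``<stem>.tsv`` (one row per sample, one numeric
column per channel, header = channel names) with a YAML sidecar
``<stem>.yaml`` carrying the sampling rate, channel names, units and any
provenance metadata.  Annotations are a four-column TSV
(trial_id, label, start_sample, end_sample), 0-based half-open intervals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .datatypes import Recording, TrialAnnotation


def write_recording(rec: Recording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` + ``<stem>.yaml``; returns both paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tsv = stem.with_suffix(".tsv")
    sidecar = stem.with_suffix(".yaml")
    pd.DataFrame(rec.data, columns=list(rec.channel_names)).to_csv(
        tsv, sep="\t", index=False, float_format="%.6g"
    )
    header = {
        "fs": float(rec.fs),
        "channels": list(rec.channel_names),
        "units": rec.meta.get("units", "mV"),
        **{k: v for k, v in rec.meta.items() if k != "units"},
    }
    sidecar.write_text(yaml.safe_dump(header, sort_keys=False))
    return tsv, sidecar


def read_recording(stem: str | Path) -> Recording:
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    sidecar = stem.with_suffix(".yaml")
    header = yaml.safe_load(sidecar.read_text())
    frame = pd.read_csv(tsv, sep="\t")
    channels = tuple(header.pop("channels"))
    fs = float(header.pop("fs"))
    return Recording(frame[list(channels)].to_numpy(), fs, channels, meta=header)


def write_annotations(
    annotations: Iterable[TrialAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        (a.trial_id, a.label, a.start_sample, a.end_sample) for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["trial_id", "label", "start_sample", "end_sample"]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_annotations(path: str | Path) -> list[TrialAnnotation]:
    frame = pd.read_csv(path, sep="\t")
    return [
        TrialAnnotation(int(r.trial_id), str(r.label), int(r.start_sample), int(r.end_sample))
        for r in frame.itertuples()
    ]


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write any report table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
    return path
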