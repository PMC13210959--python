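"""Run configuration, seed derivation and the end-to-end pipeline driver.

A run is fully determined by one YAML config and one global seed; each stage
draws its own seed deterministically from the global one (stage-name
hashing), so stages can be re-run in isolation and a finished run directory
can be reconstructed exactly from its logged config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .features import extract_features
from .modeling import (
    ClassifierSpec,
    CVSpec,
    SplitSpec,
    benchmark_classifiers,
    default_benchmark_specs,
    fit_and_evaluate,
    grid_search_rf,
    split_trial_ids,
)
from .online import ConsistencySpec, simulate_online_session
from .preprocess import (
    DenoiseSpec,
    FilterSpec,
    estimate_channel_thresholds,
    preprocess_recording,
)
from .synth import (
    ContaminantSpec,
    ProtocolSpec,
    default_profiles,
    generate_session,
    online_protocol,
)
from .windowing import WindowSpec, extract_effective, slide_session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "derive_seed", "run_pipeline", "load_config"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class SynthConfig:
    n_blocks: int = 4
    trials_per_class_per_block: int = 5
    prep_duration: float = 2.5
    execution_duration: float = 5.0
    return_duration: float = 2.5
    inter_block_rest: float = 10.0
    fs: float = 500.0
    overlap: float = 0.0
    drift_amplitude: float = 0.2
    drift_frequency: float = 0.5
    line_amplitude: float = 0.2
    noise_std: float = 0.1

    def protocol(self) -> ProtocolSpec:
        return ProtocolSpec(
            n_blocks=self.n_blocks,
            trials_per_class_per_block=self.trials_per_class_per_block,
            prep_duration=self.prep_duration,
            execution_duration=self.execution_duration,
            return_duration=self.return_duration,
            inter_block_rest=self.inter_block_rest,
            fs=self.fs,
        )

    def contaminants(self) -> ContaminantSpec:
        return ContaminantSpec(
            drift_amplitude=self.drift_amplitude,
            drift_frequency=self.drift_frequency,
            line_amplitude=self.line_amplitude,
            noise_std=self.noise_std,
        )


@dataclass
class PreprocessConfig:
    wavelet: str = "db4"
    levels: int = 4
    band_low: float = 20.0
    band_high: float = 450.0
    filter_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0

    def denoise_spec(self) -> DenoiseSpec:
        return DenoiseSpec(self.wavelet, self.levels)

    def filter_spec(self, phase_mode: str = "zero-phase") -> FilterSpec:
        return FilterSpec(
            band_low=self.band_low,
            band_high=self.band_high,
            order=self.filter_order,
            notch_freq=self.notch_freq,
            notch_q=self.notch_q,
            phase_mode=phase_mode,
        )


@dataclass
class WindowingConfig:
    window_duration: float = 0.2
    step_duration: float = 0.1

    def spec(self, fs: float) -> WindowSpec:
        return WindowSpec(self.window_duration, self.step_duration, fs)


@dataclass
class FeaturesConfig:
    subset: list[str] = field(default_factory=lambda: ["RMS", "IF", "CF"])
    layout: str = "per_channel"


@dataclass
class ModelingConfig:
    train_fraction: float = 0.9
    k_folds: int = 5
    n_estimators_grid: list[int] = field(
        default_factory=lambda: [11, 51, 101, 151, 181, 201]
    )
    max_depth_grid: list[int | None] = field(
        default_factory=lambda: [31, 71, 131, None]
    )

    def cv_spec(self) -> CVSpec:
        return CVSpec(
            self.k_folds, tuple(self.n_estimators_grid), tuple(self.max_depth_grid)
        )


@dataclass
class OnlineConfig:
    enabled: bool = True
    k: int = 2
    trials_per_class: int = 15


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    online: OnlineConfig = field(default_factory=OnlineConfig)
    seed: int = 0
    out_dir: str = "runs/run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _from_mapping(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)} in section '{path}'"
        )
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_mapping(f.type, value, f"{path}.{f.name}")
        kwargs[f.name] = value
    return cls(**kwargs)


_SECTIONS = {
    "synth": SynthConfig,
    "preprocess": PreprocessConfig,
    "windowing": WindowingConfig,
    "features": FeaturesConfig,
    "modeling": ModelingConfig,
    "online": OnlineConfig,
}


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Build a RunConfig from YAML (or a pre-parsed mapping), rejecting any
    unknown key by name."""
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) if path else {}
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown configuration key(s) {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _from_mapping(cls, dict(data[name] or {}), name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> Path:
    """Offline model construction, then (optionally) an online replay.

    Writes feature tables, the classifier benchmark table, the tuned
    random-forest report, the online confusion matrix and command log, a
    serialized model and a manifest into the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("emgintent")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("run config (all defaults echoed): %s", json.dumps(config.to_dict(), default=str))
        # --- offline stage -------------------------------------------------
        synth_seed = derive_seed(config.seed, "synth")
        protocol = config.synth.protocol()
        profiles = default_profiles(overlap=config.synth.overlap)
        rec, anns = generate_session(
            protocol, profiles, config.synth.contaminants(), synth_seed
        )
        eio.write_recording(rec, out / "session_offline")
        eio.write_annotations(anns, out / "session_offline_annotations.tsv")

        clean, quality = preprocess_recording(
            rec, config.preprocess.denoise_spec(), config.preprocess.filter_spec()
        )
        denoise_thresholds = estimate_channel_thresholds(
            rec, config.preprocess.denoise_spec()
        )
        wspec = config.windowing.spec(rec.fs)
        batch = slide_session(extract_effective(clean, anns), wspec)
        fm = extract_features(batch, config.features.subset, config.features.layout)
        eio.write_table(fm.to_frame(), out / "features.tsv", index=False)

        split = SplitSpec(
            config.modeling.train_fraction, seed=derive_seed(config.seed, "split")
        )
        bench_seed = derive_seed(config.seed, "benchmark")
        reports = benchmark_classifiers(fm, default_benchmark_specs(bench_seed), split)
        bench = {
            r.provenance["classifier"]: r.overall_accuracy for r in reports
        }
        eio.write_table(
            pd.DataFrame(
                sorted(bench.items(), key=lambda kv: -kv[1]),
                columns=["classifier", "accuracy"],
            ),
            out / "benchmark.tsv",
            index=False,
        )

        train_ids, test_ids = split_trial_ids(fm.trial_ids, fm.labels, split)
        cv_seed = derive_seed(config.seed, "cv")
        train_fm = dataclasses.replace(
            fm,
            X=fm.X[np.isin(fm.trial_ids, train_ids)].reset_index(drop=True),
            labels=fm.labels[np.isin(fm.trial_ids, train_ids)],
            trial_ids=fm.trial_ids[np.isin(fm.trial_ids, train_ids)],
        )
        best_n, best_depth, surface = grid_search_rf(
            train_fm, config.modeling.cv_spec(), cv_seed
        )
        eio.write_table(surface, out / "cv_surface.tsv")
        tuned_spec = ClassifierSpec(
            "RandomForest",
            {"n_estimators": best_n, "max_depth": best_depth},
            seed=bench_seed,
        )
        tuned_report = fit_and_evaluate(fm, train_ids, test_ids, tuned_spec)
        (out / "tuned_rf_report.json").write_text(tuned_report.to_json())
        (out / "tuned_rf_confusion.txt").write_text(tuned_report.render())

        from .modeling import make_classifier

        final_model = make_classifier(tuned_spec)
        final_model.fit(fm.X.to_numpy(), fm.labels)
        joblib.dump(
            {"schema_version": 1, "model": final_model,
             "feature_subset": list(fm.feature_subset),
             "denoise_thresholds": denoise_thresholds.tolist()},
            out / "model.joblib",
        )

        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": {
                s: derive_seed(config.seed, s)
                for s in ("synth", "split", "benchmark", "cv", "online")
            },
            "n_trials": len(anns),
            "n_windows": len(fm),
            "excluded_channels": quality.excluded,
            "benchmark": bench,
            "tuned": {
                "n_estimators": best_n,
                "max_depth": best_depth,
                "test_accuracy": tuned_report.overall_accuracy,
            },
        }

        # --- online stage --------------------------------------------------
        if config.online.enabled:
            online_seed = derive_seed(config.seed, "online")
            oproto = dataclasses.replace(
                online_protocol(), fs=config.synth.fs,
                trials_per_class_per_block=config.online.trials_per_class,
            )
            orec, oanns = generate_session(
                oproto, profiles, config.synth.contaminants(), online_seed
            )
            events, oreport = simulate_online_session(
                orec,
                oanns,
                final_model,
                ConsistencySpec(k=config.online.k),
                config.windowing.spec(orec.fs),
                config.preprocess.filter_spec(),
                config.features.subset,
                config.preprocess.denoise_spec(),
                denoise_thresholds,
            )
            eio.write_table(
                pd.DataFrame(
                    [(e.time, e.command, e.source_label) for e in events],
                    columns=["time", "command", "label"],
                ),
                out / "command_log.tsv",
                index=False,
            )
            (out / "online_report.json").write_text(oreport.to_json())
            (out / "online_confusion.txt").write_text(oreport.render())
            manifest["online"] = {
                "accuracy": oreport.overall_accuracy,
                "n_command_events": len(events),
                "n_trials": len(oanns),
            }

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
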