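"""End-to-end study pipeline: configuration, simulation, analysis, report.

This module ties the stages together for the command-line interface and
the numbered analysis scripts: simulate a cohort of recordings to disk,
run preprocessing -> difference waves -> MMN features -> group statistics,
and render a human-readable summary.  Every artifact embeds the run seed
and a hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evoked as _evoked
from . import group_stats, mmn_features, preprocess
from .paradigm import (DEVIANT_KINDS, DeviantKind, ParadigmConfig,
                       generate_paradigm, schedule_events)
from .synthetic_eeg import (NoiseModel, RawRecording, read_recording,
                            sample_cohort, simulate_subject, write_recording)

__all__ = ["PreprocessParams", "RunConfig", "process_recording",
           "simulate_study", "analyze_study", "report"]


@dataclass(frozen=True)
class PreprocessParams:
    low_hz: float = 1.0
    high_hz: float = 20.0
    reject_threshold_uV: float = 50.0
    ocular_method: str = "ica"  # "ica" | "regression" | "none"
    tmin_ms: float = -50.0
    tmax_ms: float = 900.0
    feature_window_ms: tuple[float, float] = (100.0, 250.0)


@dataclass(frozen=True)
class RunConfig:
    """Study-level configuration: paradigm, cohort, noise, preprocessing."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    params: PreprocessParams = field(default_factory=PreprocessParams)
    n_per_group: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["paradigm"]["tone"]["frequencies_hz"] = list(
            self.paradigm.tone.frequencies_hz)
        d["params"]["feature_window_ms"] = list(self.params.feature_window_ms)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        from .paradigm import ToneComplexSpec

        tone = d.get("paradigm", {}).pop("tone", {})
        if "frequencies_hz" in tone:
            tone["frequencies_hz"] = tuple(tone["frequencies_hz"])
        par = ParadigmConfig(tone=ToneComplexSpec(**tone),
                             **d.get("paradigm", {}))
        params = d.get("params", {})
        if "feature_window_ms" in params:
            params["feature_window_ms"] = tuple(params["feature_window_ms"])
        return cls(paradigm=par, noise=NoiseModel(**d.get("noise", {})),
                   params=PreprocessParams(**params),
                   n_per_group=d.get("n_per_group", 20),
                   seed=d.get("seed", 0))


def process_recording(rec: RawRecording, subject_id: str, group: str,
                      params: PreprocessParams = PreprocessParams(),
                      ) -> tuple[mmn_features.MMNFeatureSet, dict]:
    """Run one subject's recording through the full analysis chain.

    Returns the feature set and a log dict (rejection counts, trial counts
    per condition).
    """
    rec = preprocess.bandpass(rec, params.low_hz, params.high_hz)
    if params.ocular_method != "none":
        rec = preprocess.remove_ocular(rec, method=params.ocular_method)
    epochs = preprocess.extract_epochs(rec, params.tmin_ms, params.tmax_ms)
    epochs = preprocess.reject_epochs(epochs, params.reject_threshold_uV)
    epochs = preprocess.drop_warmup_standards(epochs)

    evoked_map = _evoked.average_by_condition(epochs)
    standard = evoked_map[DeviantKind.STANDARD]
    diffs = {k: _evoked.difference_wave(evoked_map[k], standard)
             for k in DEVIANT_KINDS if k in evoked_map}
    features = mmn_features.extract_features(
        subject_id, group, diffs, rec.layout, params.feature_window_ms)
    log = {
        "subject_id": subject_id,
        "n_trials": epochs.n_trials,
        "n_kept": int(epochs.keep.sum()),
        "n_rejected_amplitude": sum(r == "amplitude" for r in epochs.reason),
        "n_rejected_warmup": sum(r == "warmup" for r in epochs.reason),
        "trials_per_condition": {k.value: v.n_trials
                                 for k, v in evoked_map.items()},
    }
    return features, log


def simulate_study(config: RunConfig, out_dir: str | Path,
                   overwrite: bool = False) -> pd.DataFrame:
    """Simulate one recording per subject; write FIF files and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")

    events = schedule_events(generate_paradigm(config.paradigm),
                             config.paradigm)
    cohort = sample_cohort(config.n_per_group, seed=config.seed,
                           noise=config.noise)
    rows = []
    for profile in cohort:
        rec = simulate_subject(profile, events, noise=config.noise)
        fif, _ = write_recording(rec, out / f"{profile.subject_id}_raw.fif")
        rows.append({"subject_id": profile.subject_id, "group": profile.group,
                     "seed": profile.seed, "file": fif.name,
                     "config_hash": config.config_hash(),
                     "root_seed": config.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    config.to_yaml(out / "run_config.yaml")
    return manifest


def analyze_study(config: RunConfig, rec_dir: str | Path,
                  out_dir: str | Path, overwrite: bool = False
                  ) -> tuple[pd.DataFrame, group_stats.StudyResults]:
    """Analyze every recording in a manifest; write features + stats bundle."""
    rec_dir = Path(rec_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features_path = out / "features.csv"
    if features_path.exists() and not overwrite:
        raise FileExistsError(f"{features_path} exists; pass overwrite=True")
    manifest_path = rec_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path)

    feature_sets, logs = [], []
    for row in manifest.itertuples(index=False):
        path = rec_dir / row.file
        if not path.exists():
            raise FileNotFoundError(f"missing recording: {path}")
        rec = read_recording(path)
        try:
            fs, log = process_recording(rec, row.subject_id, row.group,
                                        config.params)
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for {row.subject_id}: {exc}") from exc
        feature_sets.append(fs)
        logs.append(log)

    table = mmn_features.features_to_table(feature_sets)
    table.to_csv(features_path, index=False)
    results = group_stats.run_study(table)
    results.to_json(out / "stats.json")
    results.to_flat_frame().to_csv(out / "stats_flat.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"config": config.to_dict(),
                   "config_hash": config.config_hash(),
                   "seed": config.seed, "subjects": logs}, fh, indent=2)
    return table, results


def report(results: group_stats.StudyResults) -> str:
    """Deterministic human-readable summary of a stats bundle."""
    flat = results.to_flat_frame()
    if flat.empty:
        return "no tests in bundle"
    lines = [f"{'test':<14} {'context':<52} {'statistic':>10} "
             f"{'df1':>6} {'df2':>6} {'p':>8}"]
    for r in flat.itertuples(index=False):
        df1 = "" if pd.isna(r.df1) else f"{r.df1:g}"
        df2 = "" if pd.isna(r.df2) else f"{r.df2:g}"
        lines.append(f"{r.test:<14} {r.context:<52} {r.statistic:>10.3f} "
                     f"{df1:>6} {df2:>6} {r.p:>8.4f}")
    return "\n".join(lines)
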