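"""Pipeline configuration and the end-to-end driver.

``run_pipeline`` chains the stages — simulate/read trials, QC, gains,
saccade detection, normative classification, association statistics — and
writes a deterministic report bundle: identical config and seed give
byte-identical JSON (timestamps are deliberately omitted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from vhitkit import classify as _classify
from vhitkit import gain as _gain
from vhitkit import io as _io
from vhitkit import qc as _qc
from vhitkit import saccades as _sacc
from vhitkit import stats as _stats
from vhitkit import synthetic as _syn
from vhitkit.errors import ConfigError

logger = logging.getLogger("vhitkit")


@dataclass
class PipelineConfig:
    """All thresholds, seeds, and paths of a pipeline run."""

    seed: int = 0
    out_dir: str = "vhit_out"
    # trial-level stage
    trials_dir: Optional[str] = None  # read trials from here if set
    n_signal_patients: int = 2  # simulated trial-level subjects otherwise
    n_trials_per_direction: int = 15
    # 250 deg/s at sigma 0.04 s gives ~3790 deg/s^2 peak acceleration,
    # comfortably above the 2500 deg/s^2 horizontal-canal threshold
    peak_head_velocity: float = 250.0
    pulse_width: float = 0.04
    true_gain: float = 1.0
    noise_sd: float = 4.0
    accel_thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(_qc.DEFAULT_ACCEL_THRESHOLDS)
    )
    blink_cutoff: float = _qc.DEFAULT_BLINK_CUTOFF
    saccade_threshold: float = _sacc.DEFAULT_SACCADE_THRESHOLD
    ms_v_max: float = 500.0
    ms_c: float = 5.0
    ms_tolerance: float = _sacc.DEFAULT_MS_TOLERANCE
    # cohort stage
    cohort_csv: Optional[str] = None  # read cohort from here if set
    n_patients: int = 151
    copy_intercept: float = 2.0
    copy_slope_hc_gain: float = -4.0
    normative_ranges: Dict[str, list] = field(
        default_factory=lambda: {
            k: [v.low, v.high] for k, v in _classify.DEFAULT_NORMATIVE_RANGES.items()
        }
    )
    rcft_threshold: float = _classify.DEFAULT_RCFT_THRESHOLD
    alpha_remove: float = _stats.DEFAULT_ALPHA_REMOVE
    model: str = "plain_mle"

    def validate(self) -> "PipelineConfig":
        positives = {
            "n_signal_patients": self.n_signal_patients,
            "n_trials_per_direction": self.n_trials_per_direction,
            "peak_head_velocity": self.peak_head_velocity,
            "pulse_width": self.pulse_width,
            "blink_cutoff": self.blink_cutoff,
            "saccade_threshold": self.saccade_threshold,
            "ms_v_max": self.ms_v_max,
            "ms_c": self.ms_c,
            "n_patients": self.n_patients,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for canal, thr in self.accel_thresholds.items():
            if thr <= 0:
                raise ConfigError(
                    f"acceleration threshold for {canal} must be positive"
                )
        for canal, (low, high) in self.normative_ranges.items():
            if not 0 < low < high:
                raise ConfigError(
                    f"normative range for {canal} must satisfy 0 < low < high"
                )
        if self.model not in ("plain_mle", "firth"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        return self

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**data).validate()

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data.pop("out_dir")  # where the bundle lands must not change its content
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def ranges(self) -> Dict[str, _classify.NormativeRange]:
        return {
            canal: _classify.NormativeRange(canal, low, high, "fixed_published")
            for canal, (low, high) in self.normative_ranges.items()
        }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _association_to_dict(res: _stats.AssociationResult) -> dict:
    return {
        "outcome": res.outcome,
        "model": res.model,
        "converged": res.converged,
        "intercept": res.intercept,
        "terms": [dataclasses.asdict(t) for t in res.terms],
        "elimination_trace": [[v, p] for v, p in res.elimination_trace],
    }


def _run_signal_stage(config: PipelineConfig, out: Path) -> None:
    """QC, gain, and saccade tables for trial-level recordings."""
    ms_model = _sacc.MainSequenceModel(config.ms_v_max, config.ms_c)
    qc_report = {}
    gain_rows = []
    saccade_rows = []

    if config.trials_dir is not None:
        groups: Dict[tuple, list] = {}
        for trial in _io.read_trials(config.trials_dir):
            groups.setdefault(("subject", trial.canal, trial.side), []).append(trial)
    else:
        groups = {}
        rng_root = np.random.SeedSequence(config.seed)
        subjects = [f"S{i + 1:03d}" for i in range(config.n_signal_patients)]
        children = rng_root.spawn(
            config.n_signal_patients * len(_classify.CANAL_CLASSES) * 2
        )
        k = 0
        for subject in subjects:
            for canal in _classify.CANAL_CLASSES:
                for side in ("right", "left"):
                    params = _syn.ImpulseParams(
                        peak_head_velocity=config.peak_head_velocity,
                        pulse_width=config.pulse_width,
                        true_gain=config.true_gain,
                        noise_sd=config.noise_sd,
                    )
                    child_seed = int(children[k].generate_state(1)[0])
                    k += 1
                    groups[(subject, canal, side)] = _syn.simulate_trial_set(
                        params,
                        config.n_trials_per_direction,
                        rng_seed=child_seed,
                        canal=canal,
                        side=side,
                    )

    for (subject, canal, side), trials in sorted(groups.items()):
        accepted, report = _qc.select_valid_trials(
            trials,
            thresholds=config.accel_thresholds,
            blink_cutoff=config.blink_cutoff,
        )
        qc_report[f"{subject}/{canal}/{side}"] = report.to_dict()
        window_gains, auc_gains = [], []
        for i, trial in enumerate(accepted):
            _, _, peak_index = _qc.head_acceleration(trial)
            tg = _gain.trial_gain(trial, peak_index)
            window_gains.append(tg.gain_window)
            auc_gains.append(tg.gain_auc)
            saccade_rows.extend(
                _sacc.saccade_table_rows(
                    f"{subject}/{canal}/{side}/{i}",
                    trial,
                    _sacc.detect_trial_saccades(
                        trial, threshold=config.saccade_threshold
                    ),
                    ms_model,
                )
            )
        summary = _gain.summarize_canal(window_gains, canal, side)
        auc_mean = float(np.mean(auc_gains)) if auc_gains else float("nan")
        gain_rows.append(_gain.gain_table_row(subject, summary, auc_mean))

    _write_json(out / "qc_report.json", qc_report)
    pd.DataFrame(gain_rows).to_csv(out / "gain_table.csv", index=False)
    pd.DataFrame(
        saccade_rows,
        columns=[
            "trial_id",
            "canal",
            "side",
            "onset_s",
            "peak_vel_dps",
            "amplitude_deg",
            "direction",
            "reversed",
        ],
    ).to_csv(out / "saccade_table.csv", index=False)


def _run_cohort_stage(config: PipelineConfig, out: Path) -> None:
    """Classification counts and association statistics on a cohort table."""
    if config.cohort_csv is not None:
        cohort = _io.read_cohort(config.cohort_csv)
    else:
        cohort_params = _syn.CohortParams(
            n_patients=config.n_patients,
            seed=config.seed,
            copy_intercept=config.copy_intercept,
            copy_slope_hc_gain=config.copy_slope_hc_gain,
        )
        records = _syn.simulate_cohort(cohort_params)
        cohort = _io.records_to_frame(records)
        _io.write_cohort(cohort, out / "cohort.csv")

    counts = _classify.cohort_counts(
        cohort, ranges=config.ranges(), rcft_threshold=config.rcft_threshold
    )
    _write_json(out / "classification_counts.json", counts)
    (out / "classification_report.txt").write_text(_classify.counts_report(counts))

    analysis = _stats.run_primary_analysis(
        cohort,
        _stats.AnalysisConfig(
            rcft_threshold=config.rcft_threshold,
            alpha_remove=config.alpha_remove,
            model=config.model,
        ),
    )
    results = {
        "copy_model": _association_to_dict(analysis.copy_model),
        "recall_model": _association_to_dict(analysis.recall_model),
        "correlations": analysis.correlations.to_dict(orient="records"),
        "sensitivity": {
            k: _association_to_dict(v) for k, v in analysis.sensitivity.items()
        },
    }
    _write_json(out / "association_results.json", results)
    report = "\n\n".join(
        [_stats.association_report(analysis.copy_model)]
        + [_stats.association_report(analysis.recall_model)]
        + [_stats.association_report(v) for v in analysis.sensitivity.values()]
    )
    (out / "association_report.txt").write_text(report)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report bundle; returns the output dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed}
    logger.info("pipeline start (hash %s)", manifest["config_hash"])
    try:
        _run_signal_stage(config, out)
    except Exception as exc:
        raise RuntimeError(f"signal stage failed: {exc}") from exc
    try:
        _run_cohort_stage(config, out)
    except Exception as exc:
        raise RuntimeError(f"cohort stage failed: {exc}") from exc
    _write_json(out / "manifest.json", manifest)
    logger.info("pipeline done: %s", out)
    return out
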