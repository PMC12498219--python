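"""File formats: trial CSVs with JSON sidecars, cohort tables.

Trials are written as one CSV per trial (columns ``time_s``,
``head_vel_dps``, ``eye_vel_dps``) with a JSON sidecar carrying the canal,
side, sample rate, and seed. Cohorts are a single CSV, one row per patient.
All files are comma-separated UTF-8 with '.' decimals and a mandatory
header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from vhitkit.errors import FormatError
from vhitkit.types import (
    CANAL_CLASSES,
    SIDES,
    TIME_GRID_TOL,
    ImpulseTrial,
    PatientRecord,
)

TRIAL_COLUMNS = ("time_s", "head_vel_dps", "eye_vel_dps")

#: Column dictionary of the cohort CSV (field name -> description).
COHORT_COLUMN_DICTIONARY = {
    "patient_id": "patient identifier",
    "age": "age, years",
    "sex": "male | female",
    "gain_rhc": "mean VOR gain, right horizontal canal",
    "gain_lhc": "mean VOR gain, left horizontal canal",
    "gain_rac": "mean VOR gain, right anterior canal",
    "gain_lac": "mean VOR gain, left anterior canal",
    "gain_rpc": "mean VOR gain, right posterior canal",
    "gain_lpc": "mean VOR gain, left posterior canal",
    "rcft_copy_z": "RCFT-copying z-score",
    "rcft_recall_z": "RCFT-delayed-recall z-score",
    "rcft_copy_t": "RCFT-copying t-score (descriptive)",
    "rcft_recall_t": "RCFT-delayed-recall t-score (descriptive)",
    "mmse": "MMSE, points (0-30)",
    "schooling": "schooling, years",
    "disease_duration": "disease duration, months",
    "mds_updrs_iii": "MDS-UPDRS part III, points",
    "kinetic_tremor": "MDS-UPDRS kinetic tremor subscore, dominant hand",
    "hy": "Hoehn & Yahr stage",
    "scopa_pc": "SCOPA-PC, points",
    "orthostatic_hypotension": "0/1 flag",
    "rbd": "0/1 flag, REM sleep behavior disorder",
    "rls": "0/1 flag, restless legs syndrome",
    "dm": "0/1 flag, diabetes mellitus",
    "htn": "0/1 flag, hypertension",
    "dyslipidemia": "0/1 flag",
    "cva": "0/1 flag, cerebrovascular accident/TIA",
    "caod": "0/1 flag, coronary artery occlusive disease",
    "depression": "0/1 flag",
    "anxiety": "0/1 flag",
    "sedatives": "0/1 flag, sedative use",
    "cadence": "cadence, steps/min (gait covariate)",
    "walking_velocity": "walking velocity, cm/s (gait covariate)",
    "step_length_difference": "step length difference, cm (gait covariate)",
}


def write_trial(
    trial: ImpulseTrial, csv_path: Union[str, Path], seed: Optional[int] = None
) -> Path:
    """Write one trial CSV plus its JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "time_s": trial.time,
            "head_vel_dps": trial.head_velocity,
            "eye_vel_dps": trial.eye_velocity,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "canal": trial.canal,
        "side": trial.side,
        "sample_rate_hz": trial.sample_rate,
        "seed": seed,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))
    return csv_path


def read_trial(csv_path: Union[str, Path]) -> ImpulseTrial:
    """Read one trial CSV + sidecar, validating format and time grid."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in ("canal", "side", "sample_rate_hz"):
        if key not in sidecar:
            raise FormatError(f"sidecar {sidecar_path} is missing key {key!r}")
    if sidecar["canal"] not in CANAL_CLASSES:
        raise FormatError(
            f"sidecar canal {sidecar['canal']!r} not one of {list(CANAL_CLASSES)}"
        )
    if sidecar["side"] not in SIDES:
        raise FormatError(
            f"sidecar side {sidecar['side']!r} not one of {list(SIDES)}"
        )

    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise FormatError(f"cannot parse {csv_path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path} is missing columns: {missing}")
    for col in TRIAL_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"{csv_path}: non-numeric value in column {col!r} at line "
                f"{int(bad[0]) + 2}"
            )
    time = df["time_s"].to_numpy(dtype=float)
    fs = float(sidecar["sample_rate_hz"])
    if time.size >= 2 and np.max(np.abs(np.diff(time) - 1.0 / fs)) > max(
        TIME_GRID_TOL, 1e-9
    ):
        raise FormatError(f"{csv_path}: time grid is not uniform at {fs} Hz")
    trial = ImpulseTrial(
        time=time,
        head_velocity=df["head_vel_dps"].to_numpy(dtype=float),
        eye_velocity=df["eye_vel_dps"].to_numpy(dtype=float),
        canal=sidecar["canal"],
        side=sidecar["side"],
        sample_rate=fs,
    )
    return trial.validate()


def write_trials(
    trials: Sequence[ImpulseTrial], directory: Union[str, Path], prefix: str = "trial"
) -> List[Path]:
    """Write a trial set into a directory, one CSV+sidecar per trial."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trial in enumerate(trials):
        paths.append(write_trial(trial, directory / f"{prefix}_{i:04d}.csv"))
    return paths


def read_trials(path: Union[str, Path]) -> List[ImpulseTrial]:
    """Read all trial CSVs under a directory (or a single trial CSV)."""
    path = Path(path)
    if path.is_file():
        return [read_trial(path)]
    if not path.is_dir():
        raise FormatError(f"no such file or directory: {path}")
    csvs = sorted(path.glob("*.csv"))
    if not csvs:
        raise FormatError(f"no trial CSV files found under {path}")
    return [read_trial(p) for p in csvs]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> List[PatientRecord]:
    fields = {f.name for f in dataclasses.fields(PatientRecord)}
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in fields}
        out.append(PatientRecord(**kwargs))
    return out


def write_cohort(
    cohort: Union[Sequence[PatientRecord], pd.DataFrame], path: Union[str, Path]
) -> Path:
    """Write a cohort table CSV (one row per patient)."""
    path = Path(path)
    df = cohort if isinstance(cohort, pd.DataFrame) else records_to_frame(cohort)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort table CSV, checking the mandatory columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    required = ["patient_id", "age", "sex"] + [
        c for c in COHORT_COLUMN_DICTIONARY if c.startswith("gain_")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing columns: {missing}")
    return df
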