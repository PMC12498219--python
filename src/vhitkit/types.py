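"""Core domain types shared by the analysis stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from vhitkit.errors import InputError

#: Semicircular canal classes: horizontal, anterior, posterior.
CANAL_CLASSES = ("HC", "AC", "PC")

#: Rotation sides.
SIDES = ("left", "right")

#: Per-side gain column keys in cohort tables, ordered right/left per class.
GAIN_COLUMNS = (
    "gain_rhc",
    "gain_lhc",
    "gain_rac",
    "gain_lac",
    "gain_rpc",
    "gain_lpc",
)

#: Maps (canal_class, side) to the cohort gain column.
CANAL_SIDE_TO_COLUMN = {
    ("HC", "right"): "gain_rhc",
    ("HC", "left"): "gain_lhc",
    ("AC", "right"): "gain_rac",
    ("AC", "left"): "gain_lac",
    ("PC", "right"): "gain_rpc",
    ("PC", "left"): "gain_lpc",
}

#: Grid-uniformity tolerance for trial time vectors, seconds.
TIME_GRID_TOL = 1e-9

#: Minimum trial length in samples (200 ms at 120 Hz).
MIN_TRIAL_SAMPLES = 24


@dataclass
class ImpulseTrial:
    """One head-impulse recording: synchronized head and eye velocity.

    Velocities are in deg/s on a uniform time grid in seconds. ``canal``
    is one of HC/AC/PC and ``side`` the rotation side being tested.
    """

    time: np.ndarray
    head_velocity: np.ndarray
    eye_velocity: np.ndarray
    canal: str
    side: str
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.head_velocity = np.asarray(self.head_velocity, dtype=float)
        self.eye_velocity = np.asarray(self.eye_velocity, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def validate(self) -> "ImpulseTrial":
        """Check structural invariants; raise :class:`InputError` on failure."""
        if self.canal not in CANAL_CLASSES:
            raise InputError(
                f"unknown canal {self.canal!r}; expected one of {CANAL_CLASSES}"
            )
        if self.side not in SIDES:
            raise InputError(f"unknown side {self.side!r}; expected one of {SIDES}")
        n = self.time.size
        if self.head_velocity.size != n or self.eye_velocity.size != n:
            raise InputError("time, head and eye traces must have equal length")
        if n < MIN_TRIAL_SAMPLES:
            raise InputError(
                f"trial has {n} samples; at least {MIN_TRIAL_SAMPLES} required"
            )
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise InputError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sample_rate)) > TIME_GRID_TOL:
            raise InputError("time grid is not uniform at the stated sample rate")
        return self


@dataclass
class QCResult:
    """Outcome of quality control for a single trial."""

    accepted: bool
    peak_head_acceleration: float
    peak_acceleration_index: int
    rejection_reason: str = "none"  # none | low_acceleration | blink | outlier

    def __post_init__(self) -> None:
        if self.accepted and self.rejection_reason != "none":
            raise ValueError("accepted trials must have rejection_reason 'none'")


@dataclass
class TrialGain:
    """Per-trial VOR gain by the two estimators."""

    gain_window: float
    gain_auc: float
    window_start_index: int
    window_end_index: int


@dataclass
class CanalGainSummary:
    """Per-canal mean gain at patient level."""

    canal: str
    side: str  # left | right | both
    mean_gain: float
    n_trials: int
    available: bool = True


@dataclass
class DetectedSaccade:
    """A detected catch-up saccade in an eye-velocity trace."""

    onset_index: int
    offset_index: int
    peak_velocity: float
    amplitude: float
    direction: str  # with_head | against_head
    latency: float = math.nan


@dataclass
class NormativeRange:
    """Acceptance interval for a canal class, from mean +/- 2 SD of controls."""

    canal_class: str
    low: float
    high: float
    source: str = "fixed_published"  # fixed_published | derived_from_controls


@dataclass
class CanalStatus:
    """Classification of one canal/side gain against its normative range."""

    canal: str
    side: str
    status: str  # normal | decreased | overestimated | unavailable


@dataclass
class RCFTStatus:
    """Abnormality call for one RCFT domain at a z-score threshold."""

    domain: str  # copying | delayed_recall
    abnormal: Optional[bool]
    threshold: float


@dataclass
class PatientRecord:
    """One cohort row: per-canal gains, cognitive scores, covariates."""

    patient_id: str
    age: float
    sex: str  # male | female
    gain_rhc: float
    gain_lhc: float
    gain_rac: float
    gain_lac: float
    gain_rpc: float
    gain_lpc: float
    rcft_copy_z: float
    rcft_recall_z: float
    rcft_copy_t: float
    rcft_recall_t: float
    mmse: float
    schooling: float
    disease_duration: float
    mds_updrs_iii: float
    kinetic_tremor: float
    hy: float
    scopa_pc: float
    orthostatic_hypotension: int = 0
    rbd: int = 0
    rls: int = 0
    dm: int = 0
    htn: int = 0
    dyslipidemia: int = 0
    cva: int = 0
    caod: int = 0
    depression: int = 0
    anxiety: int = 0
    sedatives: int = 0
    cadence: float = math.nan
    walking_velocity: float = math.nan
    step_length_difference: float = math.nan

    def gain(self, canal: str, side: str) -> float:
        return getattr(self, CANAL_SIDE_TO_COLUMN[(canal, side)])


@dataclass
class TestResult:
    """A hypothesis-test outcome."""

    statistic: float
    p_value: float
    method: str  # spearman | mann_whitney | chi_square | fisher_exact
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class AssociationTerm:
    """One retained covariate of a fitted logistic model."""

    name: str
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class AssociationResult:
    """Backward-selected logistic model with its elimination trace."""

    outcome: str
    terms: list  # list[AssociationTerm], intercept excluded
    intercept: float
    elimination_trace: list  # list[(variable, p_at_removal)]
    model: str  # plain_mle | firth
    converged: bool = True

    def term(self, name: str) -> Optional[AssociationTerm]:
        for t in self.terms:
            if t.name == name:
                return t
        return None

    @property
    def retained(self) -> list:
        return [t.name for t in self.terms]
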