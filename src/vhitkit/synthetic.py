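"""Synthetic vHIT trials and patient cohorts.

Head impulses are modeled as Gaussian velocity pulses — chosen because the
peak acceleration then has the closed form ``V / (sigma * sqrt(e))``, which
serves as an analytic oracle for the QC derivative. Eye responses are the
negated, gain-scaled head trace plus optional saccade lobes, blink
artifacts, and Gaussian noise. Cohorts are drawn with programmable
gain-to-cognition associations so the statistical layer can be validated by
parameter recovery.

Sign convention: positive head velocity is rotation toward the tested side;
the compensatory eye response is negative; a "reversed" (with-head) saccade
is therefore a positive-going lobe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.stats import truncnorm

from vhitkit.errors import ParameterError
from vhitkit.saccades import MainSequenceModel, DEFAULT_MS_TOLERANCE
from vhitkit.types import ImpulseTrial, PatientRecord

RngLike = Union[int, np.random.Generator]

#: Acquisition sample rate, Hz.
DEFAULT_SAMPLE_RATE = 120.0

#: Tail appended after the pulse support, seconds.
TRACE_TAIL_S = 0.150

#: Half-support of the Gaussian pulse in units of sigma.
PULSE_SUPPORT_SIGMAS = 4.0

#: Blink artifact: biphasic transient, +/- this amplitude over this duration.
BLINK_AMPLITUDE = 400.0
BLINK_DURATION_S = 0.080

#: Saccade lobe support in units of its own sigma (each side).
SACCADE_SUPPORT_SIGMAS = 3.5


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SaccadeSpec:
    """A saccade to inject into an eye trace.

    ``onset`` is the lobe start in seconds from trace start. ``direction``
    is relative to head rotation: ``with_head`` lobes share the head's sign
    (the reversed-saccade geometry), ``against_head`` lobes oppose it.
    By default the (amplitude, peak_velocity) pair must lie on the main
    sequence; set ``allow_off_main_sequence`` for artifact fixtures.
    """

    onset: float
    amplitude: float
    direction: str
    peak_velocity: float
    allow_off_main_sequence: bool = False

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ParameterError("saccade amplitude must be positive")
        if self.peak_velocity <= 0:
            raise ParameterError("saccade peak_velocity must be positive")
        if self.direction not in ("with_head", "against_head"):
            raise ParameterError(
                f"saccade direction {self.direction!r} not in "
                "('with_head', 'against_head')"
            )

    @property
    def sigma(self) -> float:
        """Width of the Gaussian velocity lobe implied by amplitude and peak."""
        return self.amplitude / (self.peak_velocity * math.sqrt(2.0 * math.pi))

    @property
    def duration(self) -> float:
        return 2.0 * SACCADE_SUPPORT_SIGMAS * self.sigma

    def on_main_sequence(
        self,
        model: Optional[MainSequenceModel] = None,
        tolerance: float = DEFAULT_MS_TOLERANCE,
    ) -> bool:
        model = model or MainSequenceModel()
        predicted = model.predict(self.amplitude)
        return (
            predicted * (1.0 - tolerance)
            <= self.peak_velocity
            <= predicted * (1.0 + tolerance)
        )


def main_sequence_saccade(
    onset: float,
    amplitude: float,
    direction: str,
    model: Optional[MainSequenceModel] = None,
) -> SaccadeSpec:
    """A saccade whose peak velocity sits exactly on the main sequence."""
    model = model or MainSequenceModel()
    return SaccadeSpec(
        onset=onset,
        amplitude=amplitude,
        direction=direction,
        peak_velocity=model.predict(amplitude),
    )


@dataclass
class ImpulseParams:
    """Parameters of one simulated head impulse."""

    peak_head_velocity: float
    pulse_width: float  # sigma of the Gaussian velocity pulse, seconds
    direction: str = "positive"  # rotation sign of the head pulse
    true_gain: float = 1.0
    saccades: List[SaccadeSpec] = field(default_factory=list)
    noise_sd: float = 0.0
    blink: bool = False
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def validate(self) -> "ImpulseParams":
        if self.peak_head_velocity <= 0:
            raise ParameterError("peak_head_velocity must be > 0")
        if self.pulse_width <= 0:
            raise ParameterError("pulse_width must be > 0")
        if self.true_gain < 0:
            raise ParameterError("true_gain must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")
        if self.direction not in ("positive", "negative"):
            raise ParameterError(
                f"direction {self.direction!r} not in ('positive', 'negative')"
            )
        for s in self.saccades:
            if not s.allow_off_main_sequence and not s.on_main_sequence():
                raise ParameterError(
                    f"saccade (A={s.amplitude} deg, Vp={s.peak_velocity} deg/s) "
                    "violates the main sequence; set allow_off_main_sequence "
                    "for artifact fixtures"
                )
        return self

    @property
    def head_sign(self) -> float:
        return 1.0 if self.direction == "positive" else -1.0


def peak_head_acceleration(params: ImpulseParams) -> float:
    """Closed-form peak |acceleration| of the Gaussian pulse: V/(sigma*sqrt(e))."""
    return params.peak_head_velocity / (params.pulse_width * math.sqrt(math.e))


def simulate_head_velocity(params: ImpulseParams):
    """Deterministic Gaussian head-velocity pulse.

    The pulse center is snapped to the sample grid so the sampled maximum
    equals ``peak_head_velocity`` exactly. The trace spans the pulse support
    (+/- 4 sigma) plus a 150-ms tail.

    Returns ``(time, velocity)`` arrays.
    """
    params.validate()
    fs = params.sample_rate
    sigma = params.pulse_width
    t0 = math.ceil(PULSE_SUPPORT_SIGMAS * sigma * fs - 1e-9) / fs
    duration = t0 + PULSE_SUPPORT_SIGMAS * sigma + TRACE_TAIL_S
    n = math.ceil(duration * fs - 1e-9) + 1
    time = np.arange(n) / fs
    v = params.head_sign * params.peak_head_velocity * np.exp(
        -((time - t0) ** 2) / (2.0 * sigma**2)
    )
    return time, v


def _saccade_lobe(
    time: np.ndarray, spec: SaccadeSpec, sign: float, sample_rate: float
) -> np.ndarray:
    # center snapped to the grid so the sampled peak equals peak_velocity
    center = spec.onset + SACCADE_SUPPORT_SIGMAS * spec.sigma
    center = round(center * sample_rate) / sample_rate
    lobe = spec.peak_velocity * np.exp(
        -((time - center) ** 2) / (2.0 * spec.sigma**2)
    )
    lobe[np.abs(time - center) > SACCADE_SUPPORT_SIGMAS * spec.sigma] = 0.0
    return sign * lobe


def _blink_artifact(time: np.ndarray, onset: float) -> np.ndarray:
    """Biphasic +/-400 deg/s transient of 80 ms (one full sine cycle)."""
    out = np.zeros_like(time)
    mask = (time >= onset) & (time <= onset + BLINK_DURATION_S)
    out[mask] = BLINK_AMPLITUDE * np.sin(
        2.0 * math.pi * (time[mask] - onset) / BLINK_DURATION_S
    )
    return out


def simulate_eye_velocity(
    time: np.ndarray,
    head_velocity: np.ndarray,
    params: ImpulseParams,
    rng_seed: RngLike = 0,
    blink_onset: Optional[float] = None,
) -> np.ndarray:
    """Eye-velocity response to a simulated head impulse.

    The slow-phase component is ``-true_gain * head``; saccade lobes are
    added with the sign implied by their direction relative to head
    rotation; an optional biphasic blink artifact and Gaussian noise follow.
    Reproducible for a fixed seed.
    """
    params.validate()
    rng = _rng(rng_seed)
    eye = -params.true_gain * head_velocity
    t_end = float(time[-1])
    for spec in params.saccades:
        if spec.onset < 0 or spec.onset + spec.duration > t_end:
            raise ParameterError(
                f"saccade onset {spec.onset:.3f}s (duration {spec.duration:.3f}s) "
                f"falls outside the 0-{t_end:.3f}s trace"
            )
        sign = params.head_sign if spec.direction == "with_head" else -params.head_sign
        eye = eye + _saccade_lobe(time, spec, sign, params.sample_rate)
    if params.blink:
        if blink_onset is None:
            blink_onset = float(time[int(np.argmax(np.abs(head_velocity)))])
        eye = eye + _blink_artifact(time, blink_onset)
    if params.noise_sd > 0:
        eye = eye + rng.normal(0.0, params.noise_sd, size=time.size)
    return eye


def simulate_trial(
    params: ImpulseParams,
    canal: str = "HC",
    side: str = "left",
    rng_seed: RngLike = 0,
) -> ImpulseTrial:
    """One complete simulated trial."""
    time, head = simulate_head_velocity(params)
    eye = simulate_eye_velocity(time, head, params, rng_seed)
    return ImpulseTrial(
        time=time,
        head_velocity=head,
        eye_velocity=eye,
        canal=canal,
        side=side,
        sample_rate=params.sample_rate,
        meta={"true_gain": params.true_gain, "blink": params.blink},
    ).validate()


#: Per-trial multiplicative jitter SD on peak velocity and pulse width.
TRIAL_JITTER_FRAC = 0.05


def simulate_trial_set(
    params: ImpulseParams,
    n_trials: int,
    rng_seed: int = 0,
    canal: str = "HC",
    side: str = "left",
    blink_prob: float = 0.0,
    jitter_frac: float = TRIAL_JITTER_FRAC,
) -> List[ImpulseTrial]:
    """A set of same-direction trials with per-trial jitter.

    Each trial draws, in order, from its own child stream spawned from
    ``rng_seed``: a peak-velocity jitter factor, a width jitter factor, a
    blink uniform (compared against ``blink_prob``), then the eye noise.
    This fixed draw order makes the set reproducible and lets tests
    recompute e.g. the Bernoulli blink draws independently.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if not 0.0 <= blink_prob <= 1.0:
        raise ParameterError("blink_prob must be in [0, 1]")
    params.validate()
    children = np.random.SeedSequence(rng_seed).spawn(n_trials)
    trials = []
    for child in children:
        rng = np.random.default_rng(child)
        jv = max(0.1, 1.0 + rng.normal(0.0, jitter_frac))
        jw = max(0.1, 1.0 + rng.normal(0.0, jitter_frac))
        blink = bool(rng.random() < blink_prob) or params.blink
        trial_params = ImpulseParams(
            peak_head_velocity=params.peak_head_velocity * jv,
            pulse_width=params.pulse_width * jw,
            direction=params.direction,
            true_gain=params.true_gain,
            saccades=list(params.saccades),
            noise_sd=params.noise_sd,
            blink=blink,
            sample_rate=params.sample_rate,
        )
        trials.append(simulate_trial(trial_params, canal=canal, side=side, rng_seed=rng))
    return trials


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Central cohort values echoing the study population: age 68 +/- 9 years,
#: ~49% female, per-canal gain medians near 1.0-1.1.
DEFAULT_GAIN_LOCATION: Dict[str, float] = {
    "gain_rhc": 1.07,
    "gain_lhc": 1.01,
    "gain_rac": 1.08,
    "gain_lac": 1.09,
    "gain_rpc": 1.04,
    "gain_lpc": 1.03,
}

DEFAULT_COMORBIDITY_PREVALENCE: Dict[str, float] = {
    "orthostatic_hypotension": 54 / 151,
    "rbd": 56 / 151,
    "rls": 13 / 151,
    "dm": 34 / 151,
    "htn": 60 / 151,
    "dyslipidemia": 61 / 151,
    "cva": 6 / 151,
    "caod": 10 / 151,
    "depression": 32 / 151,
    "anxiety": 19 / 151,
    "sedatives": 0.15,
}

DEFAULT_HY_LEVELS = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
DEFAULT_HY_PROBS = (21 / 151, 5 / 151, 72 / 151, 32 / 151, 19 / 151, 2 / 151)


@dataclass
class CohortParams:
    """Parameters of a synthetic patient cohort.

    ``copy_intercept``/``copy_slope_hc_gain`` set the logistic model
    P(abnormal copying) on the side-averaged horizontal-canal gain;
    ``recall_coefs`` sets the logistic model for abnormal delayed recall on
    (mmse, age, sex_male, schooling) plus an intercept.
    """

    n_patients: int = 151
    seed: int = 0
    age_mean: float = 68.0
    age_sd: float = 9.0
    sex_ratio: float = 0.49  # fraction female
    gain_location: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAIN_LOCATION)
    )
    gain_scale: float = 0.12
    copy_intercept: float = 2.0
    copy_slope_hc_gain: float = -4.0
    recall_coefs: Dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 6.0,
            "mmse": -0.4,
            "age": 0.04,
            "sex_male": 0.8,
            "schooling": 0.0,
        }
    )
    mmse_mean: float = 27.0
    mmse_sd: float = 2.0
    schooling_mean: float = 10.0
    schooling_sd: float = 4.0
    duration_log_median: float = math.log(12.0)  # months
    duration_log_sd: float = 0.8
    updrs_mean: float = 23.0
    updrs_sd: float = 10.0
    scopa_mean: float = 4.0
    scopa_sd: float = 2.0
    hy_levels: Sequence[float] = DEFAULT_HY_LEVELS
    hy_probs: Sequence[float] = DEFAULT_HY_PROBS
    comorbidity_prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    cadence_mean: float = 110.0
    cadence_sd: float = 10.0
    velocity_mean: float = 110.0
    velocity_sd: float = 20.0
    step_diff_sd: float = 3.0

    def validate(self) -> "CohortParams":
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ParameterError("sex_ratio must be in [0, 1]")
        for name in (
            "age_sd",
            "gain_scale",
            "mmse_sd",
            "schooling_sd",
            "duration_log_sd",
            "updrs_sd",
            "scopa_sd",
            "cadence_sd",
            "velocity_sd",
            "step_diff_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for k, p in self.comorbidity_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"prevalence of {k!r} must be in [0, 1]")
        if abs(sum(self.hy_probs) - 1.0) > 1e-9:
            raise ParameterError("hy_probs must sum to 1")
        return self


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_z(rng: np.random.Generator, abnormal: np.ndarray) -> np.ndarray:
    """Z-scores consistent with abnormality labels.

    Abnormal patients draw from a normal truncated above at -2 (so z < -2);
    normal patients from a normal truncated below at -2 — consistency with
    the classification rule without modeling the scoring instrument.
    """
    n = abnormal.size
    z = np.empty(n)
    n_ab = int(abnormal.sum())
    if n_ab:
        loc, scale = -2.6, 0.5
        a, b = -np.inf, (-2.0 - loc) / scale
        z[abnormal] = truncnorm.rvs(a, b, loc=loc, scale=scale, size=n_ab, random_state=rng)
    n_norm = n - n_ab
    if n_norm:
        loc, scale = -0.5, 1.0
        a, b = (-2.0 - loc) / scale, np.inf
        z[~abnormal] = truncnorm.rvs(a, b, loc=loc, scale=scale, size=n_norm, random_state=rng)
    return z


def simulate_cohort(params: CohortParams) -> List[PatientRecord]:
    """Draw a seed-reproducible synthetic cohort.

    Canal gains are normal draws around their per-canal locations; abnormal
    RCFT-copying is Bernoulli with logit linear in the side-averaged
    horizontal-canal gain; abnormal delayed recall follows the
    ``recall_coefs`` logistic model; z-scores are drawn consistently with
    the labels and t-scores are the affine companion ``50 + 10 z``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    age = rng.normal(params.age_mean, params.age_sd, n)
    female = rng.random(n) < params.sex_ratio
    gains = {
        col: rng.normal(loc, params.gain_scale, n)
        for col, loc in params.gain_location.items()
    }
    hc_gain = 0.5 * (gains["gain_rhc"] + gains["gain_lhc"])

    mmse = np.clip(np.round(rng.normal(params.mmse_mean, params.mmse_sd, n)), 0, 30)
    schooling = np.clip(np.round(rng.normal(params.schooling_mean, params.schooling_sd, n)), 0, 22)
    duration = np.exp(rng.normal(params.duration_log_median, params.duration_log_sd, n))
    updrs = np.clip(np.round(rng.normal(params.updrs_mean, params.updrs_sd, n)), 0, 132)
    kinetic_tremor = rng.integers(0, 5, n).astype(float)
    hy = rng.choice(np.asarray(params.hy_levels, dtype=float), size=n, p=np.asarray(params.hy_probs))
    scopa = np.clip(np.round(rng.normal(params.scopa_mean, params.scopa_sd, n)), 0, 21)

    logit_copy = params.copy_intercept + params.copy_slope_hc_gain * hc_gain
    abnormal_copy = rng.random(n) < _expit(logit_copy)
    rc = params.recall_coefs
    logit_recall = (
        rc.get("intercept", 0.0)
        + rc.get("mmse", 0.0) * mmse
        + rc.get("age", 0.0) * age
        + rc.get("sex_male", 0.0) * (~female).astype(float)
        + rc.get("schooling", 0.0) * schooling
    )
    abnormal_recall = rng.random(n) < _expit(logit_recall)
    copy_z = _draw_z(rng, abnormal_copy)
    recall_z = _draw_z(rng, abnormal_recall)

    comorb = {
        k: (rng.random(n) < p).astype(int)
        for k, p in params.comorbidity_prevalence.items()
    }
    cadence = rng.normal(params.cadence_mean, params.cadence_sd, n)
    velocity = rng.normal(params.velocity_mean, params.velocity_sd, n)
    step_diff = np.abs(rng.normal(0.0, params.step_diff_sd, n))

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                age=float(age[i]),
                sex="female" if female[i] else "male",
                gain_rhc=float(gains["gain_rhc"][i]),
                gain_lhc=float(gains["gain_lhc"][i]),
                gain_rac=float(gains["gain_rac"][i]),
                gain_lac=float(gains["gain_lac"][i]),
                gain_rpc=float(gains["gain_rpc"][i]),
                gain_lpc=float(gains["gain_lpc"][i]),
                rcft_copy_z=float(copy_z[i]),
                rcft_recall_z=float(recall_z[i]),
                rcft_copy_t=float(50.0 + 10.0 * copy_z[i]),
                rcft_recall_t=float(50.0 + 10.0 * recall_z[i]),
                mmse=float(mmse[i]),
                schooling=float(schooling[i]),
                disease_duration=float(duration[i]),
                mds_updrs_iii=float(updrs[i]),
                kinetic_tremor=float(kinetic_tremor[i]),
                hy=float(hy[i]),
                scopa_pc=float(scopa[i]),
                orthostatic_hypotension=int(comorb["orthostatic_hypotension"][i]),
                rbd=int(comorb["rbd"][i]),
                rls=int(comorb["rls"][i]),
                dm=int(comorb["dm"][i]),
                htn=int(comorb["htn"][i]),
                dyslipidemia=int(comorb["dyslipidemia"][i]),
                cva=int(comorb["cva"][i]),
                caod=int(comorb["caod"][i]),
                depression=int(comorb["depression"][i]),
                anxiety=int(comorb["anxiety"][i]),
                sedatives=int(comorb["sedatives"][i]),
                cadence=float(cadence[i]),
                walking_velocity=float(velocity[i]),
                step_length_difference=float(step_diff[i]),
            )
        )
    return records
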