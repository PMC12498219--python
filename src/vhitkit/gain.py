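"""VOR gain estimation: 40-ms window and area-ratio estimators.

The window estimator — the primary statistic — is the ratio of mean eye to
mean head velocity over the 40-ms window centered at peak head acceleration.
At 120 Hz that window is 4.8 samples wide; the closest symmetric odd window
(5 samples, peak index +/- 2) is used so results are bit-reproducible.

The area estimator is the ratio of the areas under the rectified eye and
head velocity curves over the impulse support, with detected saccade lobes
excised before integration.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from vhitkit.errors import InputError, UndefinedGainError
from vhitkit.types import CanalGainSummary, ImpulseTrial, TrialGain
from vhitkit import saccades as _sacc

#: Half-width of the gain window in seconds (40-ms total window).
WINDOW_HALF_WIDTH_S = 0.020

#: Impulse support: samples where |head velocity| is at least this fraction
#: of its peak.
SUPPORT_FRACTION = 0.10

#: Minimum accepted trials for a side-level canal summary.
MIN_TRIALS_PER_DIRECTION = 10

_EPS_VELOCITY = 1e-12  # deg/s, below this mean head velocity gain is undefined


def window_indices(
    trial: ImpulseTrial, peak_index: int, half_width_s: float = WINDOW_HALF_WIDTH_S
) -> Tuple[int, int]:
    """Inclusive-exclusive index span of the gain window around the peak."""
    half = int(round(half_width_s * trial.sample_rate))
    start, stop = peak_index - half, peak_index + half + 1
    if start < 0 or stop > trial.n_samples:
        raise InputError(
            f"gain window [{start}, {stop}) exceeds trace bounds "
            f"[0, {trial.n_samples})"
        )
    return start, stop


def window_gain(
    trial: ImpulseTrial, peak_index: int, half_width_s: float = WINDOW_HALF_WIDTH_S
) -> float:
    """Gain as |mean eye velocity| / |mean head velocity| over the window."""
    start, stop = window_indices(trial, peak_index, half_width_s)
    mean_head = float(np.mean(trial.head_velocity[start:stop]))
    if abs(mean_head) < _EPS_VELOCITY:
        raise UndefinedGainError("mean head velocity is zero in the gain window")
    mean_eye = float(np.mean(trial.eye_velocity[start:stop]))
    return abs(mean_eye) / abs(mean_head)


def signed_window_ratio(
    trial: ImpulseTrial, peak_index: int, half_width_s: float = WINDOW_HALF_WIDTH_S
) -> float:
    """Signed eye/head mean-velocity ratio over the gain window.

    Negative for a compensatory response; used to remove the slow-phase
    component regardless of trace orientation.
    """
    start, stop = window_indices(trial, peak_index, half_width_s)
    mean_head = float(np.mean(trial.head_velocity[start:stop]))
    if abs(mean_head) < _EPS_VELOCITY:
        raise UndefinedGainError("mean head velocity is zero in the gain window")
    return float(np.mean(trial.eye_velocity[start:stop])) / mean_head


def impulse_support_mask(
    head_velocity: np.ndarray, fraction: float = SUPPORT_FRACTION
) -> np.ndarray:
    """Boolean mask of samples where |head| >= fraction * peak |head|."""
    head = np.abs(np.asarray(head_velocity, dtype=float))
    peak = head.max(initial=0.0)
    if peak <= _EPS_VELOCITY:
        raise InputError("head velocity trace is identically zero: no support")
    return head >= fraction * peak


def _masked_trapezoid(x: np.ndarray, keep: np.ndarray, dt: float) -> float:
    """Trapezoidal integral of |x| over the kept contiguous segments."""
    total = 0.0
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return 0.0
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [idx.size]))
    for a, b in zip(starts, stops):
        seg = idx[a:b]
        if seg.size == 1:
            total += abs(x[seg[0]]) * dt
        else:
            total += float(np.trapezoid(np.abs(x[seg[0] : seg[-1] + 1]), dx=dt))
    return total


def auc_gain(
    trial: ImpulseTrial,
    support_fraction: float = SUPPORT_FRACTION,
    slow_phase_gain: Optional[float] = None,
) -> float:
    """Gain as the area under |eye| divided by the area under |head|.

    Integration runs over the impulse support. Saccade lobes are excised
    symmetrically from both integrals (removing the eye lobe alone would
    also discard the slow-phase signal beneath it and bias the ratio down).
    """
    support = impulse_support_mask(trial.head_velocity, support_fraction)
    if slow_phase_gain is None:
        peak_index = int(np.argmax(np.abs(trial.head_velocity)))
        try:
            slow_phase_gain = -signed_window_ratio(trial, peak_index)
        except (InputError, UndefinedGainError):
            slow_phase_gain = 1.0
    lobes = _sacc.find_lobes(
        trial.eye_velocity + slow_phase_gain * trial.head_velocity,
        _sacc.DEFAULT_SACCADE_THRESHOLD,
    )
    keep = support.copy()
    for start, stop in lobes:
        keep[start:stop] = False
    dt = trial.dt
    area_head = _masked_trapezoid(trial.head_velocity, keep, dt)
    if area_head <= _EPS_VELOCITY:
        raise UndefinedGainError("head velocity area over support is zero")
    area_eye = _masked_trapezoid(trial.eye_velocity, keep, dt)
    return area_eye / area_head


def trial_gain(trial: ImpulseTrial, peak_index: int) -> TrialGain:
    """Both estimators for one trial."""
    start, stop = window_indices(trial, peak_index)
    return TrialGain(
        gain_window=window_gain(trial, peak_index),
        gain_auc=auc_gain(trial),
        window_start_index=start,
        window_end_index=stop - 1,
    )


def summarize_canal(
    gains: Sequence[float],
    canal: str,
    side: str,
    min_trials: int = MIN_TRIALS_PER_DIRECTION,
) -> CanalGainSummary:
    """Mean per-trial window gain for one canal/side.

    Summaries with fewer than ``min_trials`` trials are flagged unavailable
    (mean_gain NaN) rather than raising, mirroring the exclusion of
    directions that never reached enough valid impulses.
    """
    gains = [float(g) for g in gains]
    n = len(gains)
    if n < min_trials:
        return CanalGainSummary(canal, side, float("nan"), n, available=False)
    return CanalGainSummary(canal, side, float(np.mean(gains)), n, available=True)


def combine_sides(
    left: CanalGainSummary, right: CanalGainSummary
) -> CanalGainSummary:
    """Side-averaged summary: arithmetic mean of the two side means."""
    if left.canal != right.canal:
        raise InputError("cannot combine summaries of different canals")
    if not (left.available and right.available):
        return CanalGainSummary(
            left.canal, "both", float("nan"), left.n_trials + right.n_trials, False
        )
    return CanalGainSummary(
        left.canal,
        "both",
        0.5 * (left.mean_gain + right.mean_gain),
        left.n_trials + right.n_trials,
        True,
    )


def gain_table_row(
    patient_id: str,
    window_summary: CanalGainSummary,
    auc_mean: float,
) -> dict:
    """One row of the per-patient gain table (both estimators reported)."""
    s = window_summary
    return {
        "patient_id": patient_id,
        "canal": s.canal,
        "side": s.side,
        "mean_gain_window": s.mean_gain,
        "mean_gain_auc": auc_mean,
        "n_trials": s.n_trials,
        "available": s.available,
    }
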