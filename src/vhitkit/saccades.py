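"""Catch-up saccade detection and reversed-saccade classification.

Saccades are found as velocity lobes in the residual eye trace after the
slow-phase (compensatory) component is removed, then screened against the
saccadic main sequence to separate true saccades from artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from vhitkit.errors import InputError
from vhitkit.types import CANAL_CLASSES, DetectedSaccade, ImpulseTrial

#: Detection threshold on residual eye velocity, deg/s.
DEFAULT_SACCADE_THRESHOLD = 60.0

#: Lobes separated by fewer than this many below-threshold samples merge.
DEFAULT_MERGE_GAP = 2

#: Tolerance factor on the main-sequence prediction.
DEFAULT_MS_TOLERANCE = 0.25


@dataclass
class MainSequenceModel:
    """Amplitude/peak-velocity relation: v = v_max * (1 - exp(-A / c)).

    Defaults are standard human saccade parameters; the study device's own
    cutoff is not published, so both fields are configurable.
    """

    v_max: float = 500.0  # deg/s, asymptotic peak velocity
    c: float = 5.0  # deg, amplitude constant

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.c <= 0:
            raise ValueError("v_max and c must be positive")

    def predict(self, amplitude: float) -> float:
        """Expected peak velocity (deg/s) for a saccade of this amplitude."""
        return self.v_max * (1.0 - np.exp(-amplitude / self.c))


def find_lobes(
    x: np.ndarray, threshold: float, merge_gap: int = DEFAULT_MERGE_GAP
) -> List[Tuple[int, int]]:
    """Contiguous runs where ``|x| > threshold``, as (start, stop) slices.

    Runs separated by a gap of fewer than ``merge_gap`` samples are merged,
    preventing noise-split lobes from being counted twice.
    """
    above = np.abs(np.asarray(x, dtype=float)) > threshold
    if not above.any():
        return []
    runs: List[Tuple[int, int]] = []
    idx = np.flatnonzero(above)
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append((start, prev + 1))
        start = i
        prev = i
    runs.append((start, prev + 1))
    if merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe < merge_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    return runs


def detect_saccades(
    eye_velocity: np.ndarray,
    head_velocity: np.ndarray,
    sample_rate: float,
    slow_phase_gain: float,
    threshold: float = DEFAULT_SACCADE_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
    peak_head_index: Optional[int] = None,
) -> List[DetectedSaccade]:
    """Detect saccadic lobes in an eye-velocity trace.

    The slow-phase component is removed as ``eye + slow_phase_gain * head``
    (compensatory eye velocity opposes head velocity), so covert saccades
    superimposed on the compensatory response are detectable. A lobe is a
    contiguous run of residual samples exceeding ``threshold`` in magnitude.

    Parameters
    ----------
    slow_phase_gain
        The trial's window gain, used to remove the compensatory component.
    peak_head_index
        If given, saccade latency is reported relative to this sample.
    """
    eye = np.asarray(eye_velocity, dtype=float)
    head = np.asarray(head_velocity, dtype=float)
    if eye.shape != head.shape:
        raise InputError("eye and head traces must have equal length")
    residual = eye + slow_phase_gain * head
    head_sign = np.sign(head[np.argmax(np.abs(head))])
    dt = 1.0 / sample_rate
    lobes = find_lobes(residual, threshold, merge_gap)
    # extend lobe edges down to a low boundary so the amplitude integral
    # covers the whole velocity lobe, not just its supra-threshold core
    boundary = 0.2 * threshold
    extended = []
    n = residual.size
    for start, stop in lobes:
        while start > 0 and abs(residual[start - 1]) > boundary:
            start -= 1
        while stop < n and abs(residual[stop]) > boundary:
            stop += 1
        if extended and start <= extended[-1][1]:
            extended[-1] = (extended[-1][0], max(stop, extended[-1][1]))
        else:
            extended.append((start, stop))
    out: List[DetectedSaccade] = []
    for start, stop in extended:
        seg = residual[start:stop]
        peak_pos = start + int(np.argmax(np.abs(seg)))
        lobe_sign = np.sign(residual[peak_pos])
        direction = "with_head" if lobe_sign == head_sign else "against_head"
        amplitude = float(np.trapezoid(np.abs(seg), dx=dt)) if stop - start > 1 else float(
            abs(seg[0]) * dt
        )
        latency = (
            (start - peak_head_index) * dt if peak_head_index is not None else np.nan
        )
        out.append(
            DetectedSaccade(
                onset_index=int(start),
                offset_index=int(stop),
                peak_velocity=float(np.abs(residual[peak_pos])),
                amplitude=amplitude,
                direction=direction,
                latency=float(latency),
            )
        )
    return out


def detect_trial_saccades(
    trial: ImpulseTrial,
    threshold: float = DEFAULT_SACCADE_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> List[DetectedSaccade]:
    """Detect saccades in a trial, deriving the slow-phase gain internally."""
    from vhitkit.gain import signed_window_ratio  # local import avoids a cycle
    from vhitkit.qc import head_acceleration

    _, _, peak_index = head_acceleration(trial)
    g = -signed_window_ratio(trial, peak_index)
    return detect_saccades(
        trial.eye_velocity,
        trial.head_velocity,
        trial.sample_rate,
        slow_phase_gain=g,
        threshold=threshold,
        merge_gap=merge_gap,
        peak_head_index=peak_index,
    )


def is_reversed(
    saccade: DetectedSaccade,
    ms_model: Optional[MainSequenceModel] = None,
    min_peak_velocity: float = DEFAULT_SACCADE_THRESHOLD,
    tolerance: float = DEFAULT_MS_TOLERANCE,
) -> bool:
    """Classify a detected saccade as a reversed catch-up saccade.

    True iff (1) the saccade is directed with the head rotation, (2) its peak
    velocity strictly exceeds ``min_peak_velocity`` (60 deg/s), and (3) the
    amplitude/peak-velocity pair lies on the saccadic main sequence within
    ``tolerance`` — events far above the main-sequence prediction are
    artifacts, not saccades.
    """
    model = ms_model or MainSequenceModel()
    if saccade.direction != "with_head":
        return False
    if not saccade.peak_velocity > min_peak_velocity:
        return False
    predicted = model.predict(saccade.amplitude)
    return saccade.peak_velocity <= predicted * (1.0 + tolerance)


def patient_reversed_flags(
    trials: Iterable[ImpulseTrial],
    ms_model: Optional[MainSequenceModel] = None,
    threshold: float = DEFAULT_SACCADE_THRESHOLD,
) -> dict:
    """Per-canal-plane reversed-saccade flags over a patient's accepted trials.

    Returns a dict mapping each canal class to True if any trial in that
    plane contains a reversed catch-up saccade. Order of trials is irrelevant.
    """
    flags = {c: False for c in CANAL_CLASSES}
    for trial in trials:
        if flags.get(trial.canal, False):
            continue
        for s in detect_trial_saccades(trial, threshold=threshold):
            if is_reversed(s, ms_model):
                flags[trial.canal] = True
                break
    return flags


def saccade_table_rows(
    trial_id: str,
    trial: ImpulseTrial,
    saccades: Sequence[DetectedSaccade],
    ms_model: Optional[MainSequenceModel] = None,
) -> List[dict]:
    """Rows for the saccade report table, one per detected saccade."""
    rows = []
    for s in saccades:
        rows.append(
            {
                "trial_id": trial_id,
                "canal": trial.canal,
                "side": trial.side,
                "onset_s": s.onset_index / trial.sample_rate,
                "peak_vel_dps": s.peak_velocity,
                "amplitude_deg": s.amplitude,
                "direction": s.direction,
                "reversed": is_reversed(s, ms_model),
            }
        )
    return rows
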