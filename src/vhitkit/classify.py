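"""Normative classification of canal gains and cohort pattern counting.

Per-canal gains are classified against mean +/- 2 SD normative ranges
(published control ranges shipped as frozen defaults), RCFT z-scores
against a strict threshold (primary -2.0; -1.0 for sensitivity analyses),
and patient-level patterns are aggregated into cohort counts with integer
percentages.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from vhitkit.errors import InputError
from vhitkit.types import (
    CANAL_CLASSES,
    CANAL_SIDE_TO_COLUMN,
    CanalStatus,
    NormativeRange,
    PatientRecord,
    RCFTStatus,
)

#: Published normative VOR-gain ranges (mean +/- 2 SD of 18 healthy controls).
DEFAULT_NORMATIVE_RANGES: Dict[str, NormativeRange] = {
    "HC": NormativeRange("HC", 0.86, 1.20, "fixed_published"),
    "AC": NormativeRange("AC", 0.74, 1.23, "fixed_published"),
    "PC": NormativeRange("PC", 0.72, 1.29, "fixed_published"),
}

#: Primary RCFT abnormality threshold in z units; -1.0 for sensitivity runs.
DEFAULT_RCFT_THRESHOLD = -2.0

CohortLike = Union[Sequence[PatientRecord], pd.DataFrame]


def build_normative_range(
    control_gains: Sequence[float], canal_class: str
) -> NormativeRange:
    """Normative range from control gains: mean +/- 2 * sample SD (ddof=1)."""
    vals = np.asarray(control_gains, dtype=float)
    if vals.size < 2:
        raise InputError("at least 2 control values are required")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            f"controls for {canal_class} are all equal; normative range is "
            "degenerate",
            stacklevel=2,
        )
    return NormativeRange(
        canal_class, mean - 2.0 * sd, mean + 2.0 * sd, "derived_from_controls"
    )


def canal_status(
    gain: Optional[float],
    normative: NormativeRange,
    canal: Optional[str] = None,
    side: str = "both",
) -> CanalStatus:
    """Classify a gain against its normative range (inclusive bounds).

    A result is abnormal only strictly outside the range; a gain exactly at
    a bound is normal. Missing gains give status ``unavailable``.
    """
    canal = canal or normative.canal_class
    if gain is None or (isinstance(gain, float) and math.isnan(gain)):
        return CanalStatus(canal, side, "unavailable")
    if gain < normative.low:
        return CanalStatus(canal, side, "decreased")
    if gain > normative.high:
        return CanalStatus(canal, side, "overestimated")
    return CanalStatus(canal, side, "normal")


def patient_statuses(
    record: PatientRecord,
    ranges: Optional[Mapping[str, NormativeRange]] = None,
) -> List[CanalStatus]:
    """All six canal/side statuses for one patient."""
    ranges = ranges or DEFAULT_NORMATIVE_RANGES
    return [
        canal_status(record.gain(canal, side), ranges[canal], canal, side)
        for canal in CANAL_CLASSES
        for side in ("right", "left")
    ]


def _side_pattern(statuses: Iterable[CanalStatus], category: str) -> str:
    right = any(s.side == "right" and s.status == category for s in statuses)
    left = any(s.side == "left" and s.status == category for s in statuses)
    if right and left:
        return "both"
    if right:
        return "right_only"
    if left:
        return "left_only"
    return "none"


def patient_pattern(statuses: Sequence[CanalStatus]) -> dict:
    """Patient-level VOR pattern from the six canal/side statuses.

    A patient can be in both the decreased and the overestimated category
    (different canals); ``all_normal`` means neither occurs anywhere.
    """
    if len(statuses) != 6:
        raise InputError(f"expected 6 canal statuses, got {len(statuses)}")
    any_dec = any(s.status == "decreased" for s in statuses)
    any_over = any(s.status == "overestimated" for s in statuses)
    pattern = {
        "any_decreased": any_dec,
        "any_overestimated": any_over,
        "all_normal": not any_dec and not any_over,
        "decreased": {},
        "overestimated": {},
    }
    for canal in CANAL_CLASSES:
        canal_statuses = [s for s in statuses if s.canal == canal]
        pattern["decreased"][canal] = _side_pattern(canal_statuses, "decreased")
        pattern["overestimated"][canal] = _side_pattern(canal_statuses, "overestimated")
    return pattern


def rcft_status(
    z: Optional[float],
    threshold: float = DEFAULT_RCFT_THRESHOLD,
    domain: str = "copying",
) -> RCFTStatus:
    """Abnormality call: abnormal iff z is strictly below the threshold."""
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return RCFTStatus(domain, None, threshold)
    return RCFTStatus(domain, bool(z < threshold), threshold)


def _round_percent(count: int, n: int) -> int:
    """Integer percentage, half rounded away from zero."""
    return int(math.floor(count / n * 100.0 + 0.5))


def _records(cohort: CohortLike) -> List[PatientRecord]:
    if isinstance(cohort, pd.DataFrame):
        from vhitkit.io import frame_to_records

        return frame_to_records(cohort)
    return list(cohort)


def cohort_counts(
    cohort: CohortLike,
    ranges: Optional[Mapping[str, NormativeRange]] = None,
    rcft_threshold: float = DEFAULT_RCFT_THRESHOLD,
) -> dict:
    """Cohort-level pattern counts and integer percentages.

    For each canal class and each abnormality category the side-pattern
    subgroups (right_only / left_only / both) and their total are counted;
    patient-level macro-states (all normal, any decreased, any
    overestimated, both categories) and RCFT abnormality counts follow,
    with percentages of the cohort size rounded to integers.
    """
    records = _records(cohort)
    if not records:
        raise InputError("empty cohort")
    n = len(records)

    counts = {
        "n": n,
        "decreased": {
            c: {"right_only": 0, "left_only": 0, "both": 0, "total": 0}
            for c in CANAL_CLASSES
        },
        "overestimated": {
            c: {"right_only": 0, "left_only": 0, "both": 0, "total": 0}
            for c in CANAL_CLASSES
        },
    }
    n_all_normal = n_any_dec = n_any_over = n_both = 0
    n_ab_copy = n_ab_recall = 0

    for rec in records:
        pattern = patient_pattern(patient_statuses(rec, ranges))
        if pattern["all_normal"]:
            n_all_normal += 1
        if pattern["any_decreased"]:
            n_any_dec += 1
        if pattern["any_overestimated"]:
            n_any_over += 1
        if pattern["any_decreased"] and pattern["any_overestimated"]:
            n_both += 1
        for category in ("decreased", "overestimated"):
            for canal in CANAL_CLASSES:
                side_pattern = pattern[category][canal]
                if side_pattern != "none":
                    counts[category][canal][side_pattern] += 1
                    counts[category][canal]["total"] += 1
        if rcft_status(rec.rcft_copy_z, rcft_threshold, "copying").abnormal:
            n_ab_copy += 1
        if rcft_status(rec.rcft_recall_z, rcft_threshold, "delayed_recall").abnormal:
            n_ab_recall += 1

    counts.update(
        {
            "n_all_normal": n_all_normal,
            "n_any_decreased": n_any_dec,
            "n_any_overestimated": n_any_over,
            "n_both_categories": n_both,
            "n_abnormal_copy": n_ab_copy,
            "n_abnormal_recall": n_ab_recall,
            "percent": {
                "all_normal": _round_percent(n_all_normal, n),
                "any_decreased": _round_percent(n_any_dec, n),
                "any_overestimated": _round_percent(n_any_over, n),
                "abnormal_copy": _round_percent(n_ab_copy, n),
                "abnormal_recall": _round_percent(n_ab_recall, n),
            },
        }
    )
    return counts


def counts_report(counts: dict) -> str:
    """Human-readable summary of the cohort counts."""
    lines = [
        f"Cohort of {counts['n']} patients.",
        f"VOR gain normal for all canals in {counts['n_all_normal']} "
        f"({counts['percent']['all_normal']}%).",
        f"Decreased gain for at least one canal in {counts['n_any_decreased']}; "
        f"overestimated gain for at least one canal in "
        f"{counts['n_any_overestimated']} ({counts['percent']['any_overestimated']}%); "
        f"{counts['n_both_categories']} patients in both categories.",
    ]
    for category in ("decreased", "overestimated"):
        for canal in CANAL_CLASSES:
            c = counts[category][canal]
            lines.append(
                f"{category.capitalize()} {canal}: {c['total']} patients "
                f"(right only {c['right_only']}; left only {c['left_only']}; "
                f"both {c['both']})."
            )
    lines.append(
        f"Abnormal RCFT-copying in {counts['n_abnormal_copy']} "
        f"({counts['percent']['abnormal_copy']}%); abnormal delayed recall in "
        f"{counts['n_abnormal_recall']} ({counts['percent']['abnormal_recall']}%)."
    )
    return "\n".join(lines)
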