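"""Deterministic worked-example cohorts for the aggregation rules.

These constructors build cohort tables with exactly prescribed canal-status
side patterns and cognitive abnormality counts, so the pattern counter can
be exercised against hand-countable ground truth. Patient order is shuffled
by seed; all counts are invariant to the shuffle.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from vhitkit.errors import ParameterError
from vhitkit.types import CANAL_CLASSES, CANAL_SIDE_TO_COLUMN, PatientRecord

#: Gains producing decreased / normal / overestimated status in every class.
DECREASED_GAIN = 0.5
NORMAL_GAIN = 1.0
OVERESTIMATED_GAIN = 1.5

#: z-scores on either side of the primary -2.0 threshold.
ABNORMAL_Z = -2.5
NORMAL_Z = -0.5


def normal_patient(pid: str) -> PatientRecord:
    """A patient normal on every canal and both cognitive domains."""
    return PatientRecord(
        patient_id=pid,
        age=68.0,
        sex="female",
        gain_rhc=NORMAL_GAIN,
        gain_lhc=NORMAL_GAIN,
        gain_rac=NORMAL_GAIN,
        gain_lac=NORMAL_GAIN,
        gain_rpc=NORMAL_GAIN,
        gain_lpc=NORMAL_GAIN,
        rcft_copy_z=NORMAL_Z,
        rcft_recall_z=NORMAL_Z,
        rcft_copy_t=50 + 10 * NORMAL_Z,
        rcft_recall_t=50 + 10 * NORMAL_Z,
        mmse=27.0,
        schooling=10.0,
        disease_duration=12.0,
        mds_updrs_iii=23.0,
        kinetic_tremor=1.0,
        hy=2.0,
        scopa_pc=3.0,
    )


def _shuffled(records: List[PatientRecord], seed: int) -> List[PatientRecord]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def side_pattern_cohort(
    category: str,
    canal_class: str,
    counts: Tuple[int, int, int],
    n_patients: int = 151,
    seed: int = 0,
) -> List[PatientRecord]:
    """A cohort where one canal class carries prescribed side patterns.

    ``counts`` is (right_only, left_only, both) for the given ``category``
    ('decreased' or 'overestimated'); all remaining patients are normal
    everywhere.
    """
    if category not in ("decreased", "overestimated"):
        raise ParameterError(f"unknown category {category!r}")
    if canal_class not in CANAL_CLASSES:
        raise ParameterError(f"unknown canal class {canal_class!r}")
    right_only, left_only, both = counts
    if right_only + left_only + both > n_patients:
        raise ParameterError("side-pattern counts exceed the cohort size")
    value = DECREASED_GAIN if category == "decreased" else OVERESTIMATED_GAIN
    right_col = CANAL_SIDE_TO_COLUMN[(canal_class, "right")]
    left_col = CANAL_SIDE_TO_COLUMN[(canal_class, "left")]

    records = [normal_patient(f"P{i + 1:04d}") for i in range(n_patients)]
    k = 0
    for _ in range(right_only):
        setattr(records[k], right_col, value)
        k += 1
    for _ in range(left_only):
        setattr(records[k], left_col, value)
        k += 1
    for _ in range(both):
        setattr(records[k], right_col, value)
        setattr(records[k], left_col, value)
        k += 1
    return _shuffled(records, seed)


def rcft_prevalence_cohort(
    n_patients: int = 151,
    n_abnormal_copy: int = 0,
    n_abnormal_recall: int = 0,
    seed: int = 0,
) -> List[PatientRecord]:
    """A cohort with prescribed numbers of abnormal cognitive scores."""
    if max(n_abnormal_copy, n_abnormal_recall) > n_patients:
        raise ParameterError("abnormal counts exceed the cohort size")
    records = [normal_patient(f"P{i + 1:04d}") for i in range(n_patients)]
    for rec in records[:n_abnormal_copy]:
        rec.rcft_copy_z = ABNORMAL_Z
        rec.rcft_copy_t = 50 + 10 * ABNORMAL_Z
    for rec in records[:n_abnormal_recall]:
        rec.rcft_recall_z = ABNORMAL_Z
        rec.rcft_recall_t = 50 + 10 * ABNORMAL_Z
    return _shuffled(records, seed)


def macro_state_cohort(
    n_patients: int = 151,
    n_abnormal: int = 0,
    category: str = "overestimated",
    seed: int = 0,
) -> List[PatientRecord]:
    """A cohort where ``n_abnormal`` patients have one abnormal canal.

    The abnormal patients carry a single right-anterior-canal gain outside
    the normative range in the requested direction; the remainder are
    all-normal.
    """
    if n_abnormal > n_patients:
        raise ParameterError("n_abnormal exceeds the cohort size")
    value = DECREASED_GAIN if category == "decreased" else OVERESTIMATED_GAIN
    records = [normal_patient(f"P{i + 1:04d}") for i in range(n_patients)]
    for rec in records[:n_abnormal]:
        rec.gain_rac = value
    return _shuffled(records, seed)
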