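"""Rule-based periodontitis stage and grade assignment.

Radiographic staging follows the 2017 World Workshop convention as applied to
percentage bone loss (BL%): stage I for BL% < 15, stage II for 15–33, and a
merged stage III/IV for BL% > 33 (tooth-loss and complexity criteria are not
observable on a single radiograph, so III and IV cannot be separated).  The
grade — a proxy for progression rate — divides BL% by the patient's age:
index < 0.25 is grade A, 0.25–1 grade B, > 1 grade C.

Boundary convention: both interval endpoints belong to the middle category
(15 and 33 are stage II; 0.25 and 1 are grade B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "StageGradeThresholds",
    "PeriodontitisAssessment",
    "classify_stage",
    "classify_grade",
    "assess_patient",
    "STAGES",
    "GRADES",
]

STAGES = ("I", "II", "III/IV")
GRADES = ("A", "B", "C")


@dataclass(frozen=True)
class StageGradeThresholds:
    """Cut points for stage (on BL%) and grade (on BL%/age).

    Defaults: stage I < 15 ≤ stage II ≤ 33 < stage III/IV;
    grade A < 0.25 ≤ grade B ≤ 1 < grade C.
    """

    stage_low: float = 15.0
    stage_high: float = 33.0
    grade_low: float = 0.25
    grade_high: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.stage_low < self.stage_high):
            raise ValueError("stage thresholds must satisfy 0 < low < high")
        if not (0 < self.grade_low < self.grade_high):
            raise ValueError("grade thresholds must satisfy 0 < low < high")


DEFAULT_THRESHOLDS = StageGradeThresholds()


@dataclass(frozen=True)
class PeriodontitisAssessment:
    """Patient-level result: worst-tooth BL% mapped to stage and grade."""

    patient_id: str
    max_bl_percent: float
    age: float
    grade_index: float
    stage: str
    grade: str


def classify_stage(
    max_bl_percent: float, thresholds: StageGradeThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Map a bone-loss percentage to a radiographic stage.

    Parameters
    ----------
    max_bl_percent : float
        Maximum BL% over the patient's measured teeth, in [0, 100].
    """
    if not 0 <= max_bl_percent <= 100:
        raise ValueError(f"max_bl_percent must be in [0, 100], got {max_bl_percent}")
    if max_bl_percent < thresholds.stage_low:
        return "I"
    if max_bl_percent <= thresholds.stage_high:
        return "II"
    return "III/IV"


def classify_grade(
    max_bl_percent: float,
    age: float,
    thresholds: StageGradeThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Map BL%/age to a progression grade (A/B/C)."""
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    index = max_bl_percent / age
    if index < thresholds.grade_low:
        return "A"
    if index <= thresholds.grade_high:
        return "B"
    return "C"


def assess_patient(
    bl_percents: Iterable[float],
    age: float,
    patient_id: str = "",
    thresholds: StageGradeThresholds = DEFAULT_THRESHOLDS,
) -> Optional[PeriodontitisAssessment]:
    """Assess a patient from per-tooth BL percentages.

    The worst (maximum) tooth drives both stage and grade.  Returns ``None``
    when no tooth has an assessable measurement (all filtered out upstream),
    which callers must treat as "no assessable bone loss", not as a stage.
    """
    values = [float(v) for v in bl_percents]
    if not values:
        return None
    max_bl = max(values)
    return PeriodontitisAssessment(
        patient_id=patient_id,
        max_bl_percent=max_bl,
        age=float(age),
        grade_index=max_bl / float(age),
        stage=classify_stage(max_bl, thresholds),
        grade=classify_grade(max_bl, age, thresholds),
    )
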