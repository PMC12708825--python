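"""Categorical clinical covariates: RECIST response, Brunt steatosis grade,
chemotherapy pretreatment status.

Response to neoadjuvant chemotherapy is scored per lesion from the
radiological longest diameters (RECIST 1.1 percentage rule only, no absolute
5 mm growth minimum): disappearance is complete response, a decrease of at
least 30% partial response, an increase of at least 20% progressive disease,
anything in between stable disease.  Steatosis is graded on the Brunt bins
(none < 5%, mild 5–33%, moderate 34–66%, severe > 66%); the unassigned
33–34% sliver goes to mild so every fraction maps to exactly one grade.  A
patient counts as pretreated when the last chemotherapy cycle started within
three months (operationalized as 90 days) before surgery.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime


class ResponseClass(str, enum.Enum):
    COMPLETE_RESPONSE = "complete_response"
    PARTIAL_RESPONSE = "partial_response"
    STABLE_DISEASE = "stable_disease"
    PROGRESSIVE_DISEASE = "progressive_disease"


class SteatosisGrade(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class RecistResult:
    response: ResponseClass
    percent_change: float


PRETREATMENT_WINDOW_DAYS = 90


def classify_recist(baseline_mm: float, post_mm: float) -> RecistResult:
    """Classify one lesion's response from pre/post longest diameters (mm).

    Boundary ties resolve toward PR / PD: exactly −30% is partial response
    and exactly +20% progressive disease ("at least" wording).
    """
    if not baseline_mm > 0:
        raise ValueError(f"baseline diameter must be positive, got {baseline_mm}")
    if post_mm < 0:
        raise ValueError(f"post-treatment diameter must be non-negative, got {post_mm}")
    change = 100.0 * (post_mm - baseline_mm) / baseline_mm
    if post_mm == 0:
        cls = ResponseClass.COMPLETE_RESPONSE
    elif change <= -30.0:
        cls = ResponseClass.PARTIAL_RESPONSE
    elif change >= 20.0:
        cls = ResponseClass.PROGRESSIVE_DISEASE
    else:
        cls = ResponseClass.STABLE_DISEASE
    return RecistResult(response=cls, percent_change=change)


def grade_steatosis(fraction_percent: float) -> SteatosisGrade:
    """Map a steatotic-hepatocyte fraction (0–100%) to its Brunt grade."""
    if not 0.0 <= fraction_percent <= 100.0:
        raise ValueError(f"steatosis fraction must lie in [0, 100], got {fraction_percent}")
    if fraction_percent < 5.0:
        return SteatosisGrade.NONE
    if fraction_percent < 34.0:
        return SteatosisGrade.MILD
    if fraction_percent < 67.0:
        return SteatosisGrade.MODERATE
    return SteatosisGrade.SEVERE


def is_pretreated(
    chemo_last_cycle_start: date | datetime | None,
    surgery_date: date | datetime,
) -> bool:
    """True iff the last chemotherapy cycle started within 90 days before surgery."""
    if chemo_last_cycle_start is None:
        return False
    delta = _as_date(surgery_date) - _as_date(chemo_last_cycle_start)
    if delta.days < 0:
        raise ValueError("chemotherapy start date is after the surgery date")
    return delta.days <= PRETREATMENT_WINDOW_DAYS


def _as_date(d: date | datetime) -> date:
    return d.date() if isinstance(d, datetime) else d
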