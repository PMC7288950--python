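"""Tiered immune scoring against age-stratified reference limits.

Each of the 8 composite parameters earns a tier in {-2, -1, 0, +1, +2}
from its position relative to the subject's age-group reference interval
[L, U] — in the style of organ-failure severity scores, where each organ
system contributes a small integer:

    +2  value > 1.5 U
    +1  U < value <= 1.5 U
     0  L <= value <= U
    -1  0.5 L <= value < L
    -2  value < 0.5 L

The total (sum over the 8 parameters, range [-16, +16]) classifies the
subject: total > 0 flags hyperimmune status, total < 0 hypoimmune status,
total = 0 normal.  "Within the reference range" is read as the closed
interval; the extreme tiers require strict inequality ("higher than" /
"lower than"), and the +-1 bands absorb the remaining boundary points.
When L = 0 the -1/-2 bands are empty and any value up to U scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import (
    COMPOSITE_PARAMETERS,
    LymphocytePanel,
    SubjectRecord,
    assign_age_group,
    derive_parameters,
)
from .reference import ReferenceRange, ReferenceTable

__all__ = [
    "ScoreBreakdown",
    "score_parameter",
    "score_subject",
    "score_cohort",
    "classify",
]


@dataclass(frozen=True)
class ScoreBreakdown:
    subject_id: str
    group_used: str
    per_parameter: dict[str, int]
    total: int
    classification: str
    table_provenance: str = ""


def score_parameter(value: float, range_: ReferenceRange) -> int:
    """Tier of one composite value against its reference interval."""
    if not (isinstance(value, (int, float)) and math.isfinite(value)) or value < 0:
        raise ValueError(f"composite value must be finite and >= 0, got {value!r}")
    lower, upper = range_.lower, range_.upper
    if value > 1.5 * upper:
        return 2
    if value > upper:
        return 1
    if value >= lower:
        return 0
    if value >= 0.5 * lower:
        return -1
    return -2


def classify(total: int) -> str:
    """hyperimmune if total > 0, hypoimmune if total < 0, else normal."""
    if total > 0:
        return "hyperimmune"
    if total < 0:
        return "hypoimmune"
    return "normal"


def score_subject(
    subject: SubjectRecord,
    panel: LymphocytePanel,
    table: ReferenceTable,
    parameter_subset: Sequence[str] | None = None,
) -> ScoreBreakdown:
    """Score one subject: derive composites, tier each against the
    subject's age-group entry, sum and classify.

    With ``parameter_subset`` (a subset of the 8 composite names) only the
    selected parameters contribute and the total ranges over [-2k, +2k].
    """
    params = _validated_subset(parameter_subset)
    group = assign_age_group(subject.age).label
    composites = derive_parameters(panel).as_dict()
    tiers: dict[str, int] = {}
    for name in params:
        entry = table.get(name, group)
        if entry is None:
            raise KeyError(
                f"reference table {table.provenance!r} has no entry for "
                f"({name!r}, {group!r}) needed by subject {subject.subject_id!r}"
            )
        tiers[name] = score_parameter(composites[name], entry)
    total = sum(tiers.values())
    return ScoreBreakdown(
        subject_id=subject.subject_id,
        group_used=group,
        per_parameter=tiers,
        total=total,
        classification=classify(total),
        table_provenance=table.provenance,
    )


def score_cohort(
    cohort: Iterable[tuple[SubjectRecord, LymphocytePanel]],
    table: ReferenceTable,
    parameter_subset: Sequence[str] | None = None,
) -> list[ScoreBreakdown]:
    """Score every subject of a cohort; deterministic, order-preserving."""
    params = _validated_subset(parameter_subset)
    return [score_subject(rec, panel, table, params) for rec, panel in cohort]


def _validated_subset(parameter_subset: Sequence[str] | None) -> tuple[str, ...]:
    if parameter_subset is None:
        return COMPOSITE_PARAMETERS
    unknown = [p for p in parameter_subset if p not in COMPOSITE_PARAMETERS]
    if unknown:
        raise ValueError(f"unknown scoring parameters: {unknown}")
    if not parameter_subset:
        raise ValueError("parameter subset must not be empty")
    return tuple(parameter_subset)
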