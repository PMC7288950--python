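"""Domain model: subjects, lymphocyte panels, age groups, composite parameters.

The measured panel holds 12 flow-cytometry summaries per subject: four
absolute lymphocyte subset counts (CD4+ T, CD8+ T, B, NK cells, cells per
volume), three functional readouts (percent of the subset producing IFN-γ
after PMA/ionomycin stimulation), and five phenotype-marker fractions
(CD28, HLA-DR, CD45RO on CD4+ T cells; CD28, HLA-DR on CD8+ T cells).

Eight composite parameters — a subset count multiplied by a within-subset
fraction, yielding cells per volume of functional or marker-positive
cells — are derived from the measured panel and form the inputs of the
immune scoring model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "AgeGroup",
    "AGE_GROUPS",
    "SubjectRecord",
    "LymphocytePanel",
    "DerivedPanel",
    "MEASURED_PARAMETERS",
    "COUNT_PARAMETERS",
    "PERCENT_PARAMETERS",
    "COMPOSITE_PARAMETERS",
    "ALL_PARAMETERS",
    "COMPOSITE_RECIPES",
    "IngestError",
    "assign_age_group",
    "derive_parameters",
]


class IngestError(ValueError):
    """A subject or panel failed validation at ingest."""


@dataclass(frozen=True)
class AgeGroup:
    """A pediatric-to-geriatric age stratum.

    ``age_max`` is inclusive in integer-year semantics; ``None`` means
    open-ended (the eldest stratum).
    """

    label: str
    age_min: int
    age_max: int | None

    def contains(self, age_years: float) -> bool:
        whole = math.floor(age_years)
        if whole < self.age_min:
            return False
        return self.age_max is None or whole <= self.age_max


#: The four strata partition ages >= 1 year.  Adolescents end at 17 and
#: 18-year-olds are adults; elders begin at 66 (the eldest observed range
#: in clinical TBNK studies of this design starts at 66).
AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("children", 1, 5),
    AgeGroup("adolescents", 6, 17),
    AgeGroup("adults", 18, 65),
    AgeGroup("elders", 66, None),
)

AGE_GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in AGE_GROUPS)

COUNT_PARAMETERS: tuple[str, ...] = ("cd4_count", "cd8_count", "b_count", "nk_count")
PERCENT_PARAMETERS: tuple[str, ...] = (
    "cd4_func_pct",
    "cd8_func_pct",
    "nk_func_pct",
    "cd28_cd4_pct",
    "hladr_cd4_pct",
    "cd45ro_cd4_pct",
    "cd28_cd8_pct",
    "hladr_cd8_pct",
)
MEASURED_PARAMETERS: tuple[str, ...] = COUNT_PARAMETERS + PERCENT_PARAMETERS

#: composite name -> (count field, percentage field)
COMPOSITE_RECIPES: dict[str, tuple[str, str]] = {
    "cd4_num_x_func": ("cd4_count", "cd4_func_pct"),
    "cd8_num_x_func": ("cd8_count", "cd8_func_pct"),
    "nk_num_x_func": ("nk_count", "nk_func_pct"),
    "cd28_cd4_num": ("cd4_count", "cd28_cd4_pct"),
    "hladr_cd4_num": ("cd4_count", "hladr_cd4_pct"),
    "cd45ro_cd4_num": ("cd4_count", "cd45ro_cd4_pct"),
    "cd28_cd8_num": ("cd8_count", "cd28_cd8_pct"),
    "hladr_cd8_num": ("cd8_count", "hladr_cd8_pct"),
}

COMPOSITE_PARAMETERS: tuple[str, ...] = tuple(COMPOSITE_RECIPES)
ALL_PARAMETERS: tuple[str, ...] = MEASURED_PARAMETERS + COMPOSITE_PARAMETERS

SEXES = ("male", "female")
COHORT_LABELS = ("healthy", "hyperimmune", "hypoimmune")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    cohort: str = "healthy"

    def __post_init__(self) -> None:
        if not (isinstance(self.age, (int, float)) and math.isfinite(self.age)):
            raise IngestError(f"subject {self.subject_id!r}: non-finite age {self.age!r}")
        if self.age < 1:
            raise IngestError(
                f"subject {self.subject_id!r}: age {self.age} below the study minimum of 1 year"
            )
        if self.sex not in SEXES:
            raise IngestError(f"subject {self.subject_id!r}: unknown sex {self.sex!r}")
        if self.cohort not in COHORT_LABELS:
            raise IngestError(f"subject {self.subject_id!r}: unknown cohort {self.cohort!r}")


@dataclass(frozen=True)
class LymphocytePanel:
    """The 12 measured parameters for one subject.

    Counts are cells per volume in the unit of the input data (clinical
    reports print per-millilitre values); percentages are in [0, 100].
    """

    cd4_count: float
    cd8_count: float
    b_count: float
    nk_count: float
    cd4_func_pct: float
    cd8_func_pct: float
    nk_func_pct: float
    cd28_cd4_pct: float
    hladr_cd4_pct: float
    cd45ro_cd4_pct: float
    cd28_cd8_pct: float
    hladr_cd8_pct: float

    def __post_init__(self) -> None:
        for name in COUNT_PARAMETERS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)) or v < 0:
                raise IngestError(f"{name}={v!r}: counts must be finite and >= 0")
        for name in PERCENT_PARAMETERS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)) or not 0 <= v <= 100:
                raise IngestError(f"{name}={v!r}: percentages must lie in [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DerivedPanel:
    """The 8 composite scoring parameters (cells per volume)."""

    cd4_num_x_func: float
    cd8_num_x_func: float
    nk_num_x_func: float
    cd28_cd4_num: float
    hladr_cd4_num: float
    cd45ro_cd4_num: float
    cd28_cd8_num: float
    hladr_cd8_num: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def assign_age_group(age: float) -> AgeGroup:
    """Map an age in years to its stratum.

    Non-integer ages are floored to whole years, so 17.9 is an adolescent
    and 65.9 an adult.  Ages below 1 year are outside the model's domain.
    """
    if not (isinstance(age, (int, float)) and math.isfinite(age)):
        raise IngestError(f"non-finite age {age!r}")
    if age < 1:
        raise IngestError(f"age {age} below the study minimum of 1 year")
    for group in AGE_GROUPS:
        if group.contains(age):
            return group
    raise AssertionError("unreachable: AGE_GROUPS partition [1, inf)")


def derive_parameters(panel: LymphocytePanel) -> DerivedPanel:
    """Compute the 8 composite parameters: count x (percentage / 100).

    Each composite counts the marker-positive (or IFN-γ-producing) cells
    per volume, so it can never exceed its parent subset count.
    """
    values = {
        name: getattr(panel, count) * getattr(panel, pct) / 100.0
        for name, (count, pct) in COMPOSITE_RECIPES.items()
    }
    return DerivedPanel(**values)
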