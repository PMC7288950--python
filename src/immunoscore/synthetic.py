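"""Synthetic healthy and patient cohorts for end-to-end testing.

No subject-level data are deposited for the study design this package
implements, so every stage is exercised on simulated cohorts instead.
The generator draws each of the 12 measured parameters from a normal
distribution truncated to its support (counts >= 0, percentages in
[0, 100]) with age-group-specific mean and SD; the defaults are the
published group summaries bundled in :mod:`immunoscore.reference`.
Parameters are independent given age — all cross-parameter correlation is
carried by the age trend, which reproduces the qualitative lifespan
directions (T/B counts fall, NK count rises; IFN-γ+ function rises; CD28+
fractions fall, HLA-DR+/CD45RO+ fractions rise) without inventing a
covariance matrix.

Patient cohorts are healthy draws with multiplicative shifts applied
before composite derivation: the defaults scale counts down (hypoimmune)
or scale function/activation/memory percentages up (hyperimmune).  These
shifts produce score distributions spanning the reported patient score
ranges; they are not a mechanistic disease model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .core import (
    AGE_GROUP_LABELS,
    COUNT_PARAMETERS,
    MEASURED_PARAMETERS,
    PERCENT_PARAMETERS,
    LymphocytePanel,
    SubjectRecord,
    assign_age_group,
)
from .reference import _PUBLISHED_TABLE

__all__ = [
    "SyntheticCohortSpec",
    "PerturbationSpec",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_SEX_RATIO",
    "HYPOIMMUNE_SHIFTS",
    "HYPERIMMUNE_SHIFTS",
    "generate_healthy_cohort",
    "generate_patient_cohort",
    "match_controls",
    "truncated_normal_quantile",
]

#: Healthy-cohort stratum sizes of the reference study.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "children": 47,
    "adolescents": 72,
    "adults": 90,
    "elders": 52,
}

#: Male fraction per stratum (35/47, 52/72, 53/90, 28/52).
DEFAULT_SEX_RATIO: dict[str, float] = {
    "children": 35 / 47,
    "adolescents": 52 / 72,
    "adults": 53 / 90,
    "elders": 28 / 52,
}

#: Age-sampling intervals [lo, hi) per group; floored ages stay in-group.
_AGE_BOUNDS: dict[str, tuple[float, float]] = {
    "children": (1.0, 6.0),
    "adolescents": (6.0, 18.0),
    "adults": (18.0, 66.0),
    "elders": (66.0, 83.0),
}

#: Observed mean age per stratum, the knots for age-trend interpolation.
_GROUP_MID_AGES: dict[str, float] = {
    "children": 3.81,
    "adolescents": 10.81,
    "adults": 46.0,
    "elders": 71.04,
}

def _default_group_params() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        param: {group: (mean, sd) for group, (mean, sd, _, _) in per_group.items()}
        for param, per_group in _PUBLISHED_TABLE.items()
        if param in MEASURED_PARAMETERS
    }


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for a healthy cohort.

    ``group_params`` maps each measured parameter to per-group
    (mean, sd); ``age_trend`` switches from group-constant means/SDs to
    piecewise-linear interpolation in age across the group mean ages
    (flat beyond the outermost knots), which yields smooth lifespan trends
    with well-defined rank-correlation signs.
    """

    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_group_params
    )
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sex_ratio: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_RATIO))
    seed: int = 0
    age_trend: bool = False

    def __post_init__(self) -> None:
        for param, per_group in self.group_params.items():
            for group, (mean, sd) in per_group.items():
                if sd < 0:
                    raise ValueError(f"{param}/{group}: sd {sd} < 0")
                if param in PERCENT_PARAMETERS and not 0 <= mean <= 100:
                    raise ValueError(f"{param}/{group}: percentage mean {mean} outside [0,100]")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")


#: Default multiplicative shifts: an immunosuppressed profile with all
#: subset counts at 40%, and an activated profile with IFN-γ+ function
#: plus HLA-DR/CD45RO fractions at 160% (capped at 100%).
HYPOIMMUNE_SHIFTS: dict[str, float] = {p: 0.4 for p in COUNT_PARAMETERS}
HYPERIMMUNE_SHIFTS: dict[str, float] = {
    "cd4_func_pct": 1.6,
    "cd8_func_pct": 1.6,
    "nk_func_pct": 1.6,
    "hladr_cd4_pct": 1.6,
    "cd45ro_cd4_pct": 1.6,
    "hladr_cd8_pct": 1.6,
}


@dataclass
class PerturbationSpec:
    """Multiplicative shifts turning healthy draws into a patient cohort."""

    direction: str
    shifts: dict[str, float] = field(default_factory=dict)
    n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("hyperimmune", "hypoimmune"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.shifts:
            self.shifts = dict(
                HYPERIMMUNE_SHIFTS if self.direction == "hyperimmune" else HYPOIMMUNE_SHIFTS
            )
        if any(f <= 0 for f in self.shifts.values()):
            raise ValueError("shift factors must be > 0")


def _support(param: str) -> tuple[float, float]:
    return (0.0, np.inf) if param in COUNT_PARAMETERS else (0.0, 100.0)


def truncated_normal_quantile(
    q: float | np.ndarray,
    mean: float | np.ndarray,
    sd: float | np.ndarray,
    low: float,
    high: float,
) -> np.ndarray:
    """Quantile function of a normal(mean, sd) truncated to [low, high].

    This is both the sampling path (inverse-CDF on uniform draws, so
    cohorts are exactly reproducible from a seed) and the oracle for the
    generator's true quantiles in recovery checks.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = (low - mean) / np.where(sd > 0, sd, 1.0)
    b = (high - mean) / np.where(sd > 0, sd, 1.0)
    out = truncnorm.ppf(q, a, b, loc=mean, scale=sd)
    return np.where(sd > 0, out, mean)


def _param_moments(
    spec: SyntheticCohortSpec, param: str, ages: np.ndarray, groups: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (mean, sd) arrays, group-constant or age-interpolated."""
    per_group = spec.group_params[param]
    if not spec.age_trend:
        means = np.array([per_group[g][0] for g in groups], dtype=float)
        sds = np.array([per_group[g][1] for g in groups], dtype=float)
        return means, sds
    knots = np.array([_GROUP_MID_AGES[g] for g in AGE_GROUP_LABELS])
    knot_means = np.array([per_group[g][0] for g in AGE_GROUP_LABELS])
    knot_sds = np.array([per_group[g][1] for g in AGE_GROUP_LABELS])
    return np.interp(ages, knots, knot_means), np.interp(ages, knots, knot_sds)


def _draw_panels(
    spec: SyntheticCohortSpec,
    ages: np.ndarray,
    rng: np.random.Generator,
    shifts: dict[str, float] | None = None,
) -> list[LymphocytePanel]:
    groups = [assign_age_group(a).label for a in ages]
    columns: dict[str, np.ndarray] = {}
    for param in MEASURED_PARAMETERS:
        means, sds = _param_moments(spec, param, ages, groups)
        low, high = _support(param)
        values = truncated_normal_quantile(rng.uniform(size=ages.size), means, sds, low, high)
        if shifts and param in shifts:
            values = np.clip(values * shifts[param], low, min(high, np.finfo(float).max))
        columns[param] = values
    return [
        LymphocytePanel(**{param: float(columns[param][i]) for param in MEASURED_PARAMETERS})
        for i in range(ages.size)
    ]


def _draw_ages_and_sex(
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
    n: int | None,
    age_range: tuple[float, float] | None,
) -> tuple[np.ndarray, list[str]]:
    if age_range is not None:
        if n is None:
            raise ValueError("n is required when age_range is given")
        lo, hi = age_range
        ages = rng.uniform(lo, hi + 1.0, size=n)  # floored ages span [lo, hi]
        ages = np.minimum(ages, hi + 0.999)
    elif n is not None:
        # n subjects spread over the default strata proportionally
        total = sum(spec.group_sizes.values())
        labels = list(spec.group_sizes)
        probs = np.array([spec.group_sizes[g] / total for g in labels])
        picks = rng.choice(len(labels), size=n, p=probs)
        bounds = np.array([_AGE_BOUNDS[labels[k]] for k in picks])
        ages = rng.uniform(bounds[:, 0], bounds[:, 1])
    else:
        parts = []
        for group in AGE_GROUP_LABELS:
            size = spec.group_sizes.get(group, 0)
            lo, hi = _AGE_BOUNDS[group]
            parts.append(rng.uniform(lo, hi, size=size))
        ages = np.concatenate(parts) if parts else np.empty(0)
    sexes = []
    for age in ages:
        group = assign_age_group(age).label
        male_frac = spec.sex_ratio.get(group, 0.5)
        sexes.append("male" if rng.uniform() < male_frac else "female")
    return ages, sexes


def generate_healthy_cohort(
    spec: SyntheticCohortSpec,
    n: int | None = None,
    age_range: tuple[float, float] | None = None,
    id_prefix: str = "H",
) -> list[tuple[SubjectRecord, LymphocytePanel]]:
    """Draw a healthy cohort, reproducibly from ``spec.seed``.

    By default the cohort has the spec's per-group sizes with ages uniform
    within each group's bounds.  ``n`` with ``age_range=(lo, hi)`` instead
    draws ``n`` subjects with ages uniform over [lo, hi] (in whole-year
    semantics), e.g. to emulate an age-matched control pool.
    """
    rng = np.random.default_rng(spec.seed)
    ages, sexes = _draw_ages_and_sex(spec, rng, n, age_range)
    panels = _draw_panels(spec, ages, rng)
    width = max(4, len(str(max(ages.size, 1))))
    return [
        (
            SubjectRecord(f"{id_prefix}{i + 1:0{width}d}", float(ages[i]), sexes[i], "healthy"),
            panels[i],
        )
        for i in range(ages.size)
    ]


def generate_patient_cohort(
    base: SyntheticCohortSpec,
    perturb: PerturbationSpec,
    age_range: tuple[float, float] | None = None,
) -> list[tuple[SubjectRecord, LymphocytePanel]]:
    """Draw a patient cohort: healthy panels with multiplicative shifts.

    Shifted percentages are re-clipped to [0, 100].  With all shift
    factors equal to 1 and the same seed, the panels are identical to a
    healthy draw.  Cohort labels carry ``perturb.direction``.
    """
    rng = np.random.default_rng(perturb.seed)
    ages, sexes = _draw_ages_and_sex(base, rng, perturb.n, age_range)
    panels = _draw_panels(base, ages, rng, shifts=perturb.shifts)
    prefix = "HYPER" if perturb.direction == "hyperimmune" else "HYPO"
    width = max(4, len(str(max(ages.size, 1))))
    return [
        (
            SubjectRecord(
                f"{prefix}{i + 1:0{width}d}", float(ages[i]), sexes[i], perturb.direction
            ),
            panels[i],
        )
        for i in range(ages.size)
    ]


def match_controls(
    pool: list[tuple[SubjectRecord, LymphocytePanel]],
    n_keep: int | float,
    seed: int = 0,
) -> list[tuple[SubjectRecord, LymphocytePanel]]:
    """Random under-sampling of a control pool, without replacement.

    ``n_keep`` may be a count or a fraction in (0, 1]; keeping the whole
    pool returns it unchanged (original order preserved).
    """
    if isinstance(n_keep, float) and 0 < n_keep <= 1:
        n_keep = int(round(n_keep * len(pool)))
    n_keep = int(n_keep)
    if n_keep > len(pool):
        raise ValueError(f"cannot keep {n_keep} of a pool of {len(pool)}")
    if n_keep == len(pool):
        return list(pool)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pool), size=n_keep, replace=False))
    return [pool[i] for i in idx]
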