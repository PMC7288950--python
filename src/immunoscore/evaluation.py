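"""Diagnostic evaluation of the immune score and cohort descriptive tests.

The score is read as two one-sided rules sharing one control group:
total > 0 flags hyperimmune status and total < 0 flags hypoimmune status.
Sensitivity is the flagged fraction of the case group; specificity counts
a control as a false positive only when it crosses the cutoff *in the
tested direction* (a control scoring below 0 is not a false positive for
the hyperimmune rule).  Descriptive comparisons use the field-standard
nonparametric tests: Spearman rank correlation (midranks for ties) and
the two-sided Mann-Whitney U rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .scoring import ScoreBreakdown

__all__ = [
    "ScoreBins",
    "DiagnosticResult",
    "bin_scores",
    "sensitivity_specificity",
    "correlation_profile",
    "group_compare",
]

#: At or below this per-group size the rank-sum test enumerates the exact
#: null distribution; above it the normal approximation (with tie
#: correction and continuity correction) is used.
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class ScoreBins:
    """Counts of total scores by sign."""

    n_below: int
    n_zero: int
    n_above: int

    @property
    def total(self) -> int:
        return self.n_below + self.n_zero + self.n_above


@dataclass(frozen=True)
class DiagnosticResult:
    condition: str
    sensitivity: float
    specificity: float
    positives: int
    negatives: int


def bin_scores(breakdowns: Iterable[ScoreBreakdown | int]) -> ScoreBins:
    """Bin totals by sign; accepts breakdowns or raw integer totals."""
    below = zero = above = 0
    for item in breakdowns:
        total = item.total if isinstance(item, ScoreBreakdown) else int(item)
        if total < 0:
            below += 1
        elif total > 0:
            above += 1
        else:
            zero += 1
    return ScoreBins(below, zero, above)


def sensitivity_specificity(
    case_bins: ScoreBins,
    control_bins: ScoreBins,
    condition: str,
) -> DiagnosticResult:
    """Sensitivity/specificity of one one-sided cutoff rule.

    For ``condition="hyperimmune"`` the positive call is total > 0; a
    control is a true negative unless its total > 0.  Mirrored for
    ``"hypoimmune"`` with total < 0.
    """
    if condition not in ("hyperimmune", "hypoimmune"):
        raise ValueError(f"unknown condition {condition!r}")
    if case_bins.total == 0 or control_bins.total == 0:
        raise ValueError("case and control groups must be non-empty")
    if condition == "hyperimmune":
        true_pos = case_bins.n_above
        false_pos = control_bins.n_above
    else:
        true_pos = case_bins.n_below
        false_pos = control_bins.n_below
    return DiagnosticResult(
        condition=condition,
        sensitivity=true_pos / case_bins.total,
        specificity=(control_bins.total - false_pos) / control_bins.total,
        positives=case_bins.total,
        negatives=control_bins.total,
    )


def correlation_profile(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p; ties take midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError(f"need at least 3 paired finite observations, got {mask.sum()}")
    res = stats.spearmanr(x[mask], y[mask])
    return float(res.statistic), float(res.pvalue)


def group_compare(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank-sum comparison of two groups.

    Exact null enumeration when both groups have at most
    ``EXACT_RANKSUM_MAX_N`` observations and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.  Returns (U statistic of the first group, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (max(a.size, b.size) <= EXACT_RANKSUM_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
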