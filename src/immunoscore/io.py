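"""Cohort file handling and the end-to-end pipeline.

Cohort files are delimited text (comma or tab, sniffed), one row per
subject, with the canonical header::

    subject_id, age, sex, cohort, cd4_count, cd8_count, b_count, nk_count,
    cd4_func_pct, cd8_func_pct, nk_func_pct, cd28_cd4_pct, hladr_cd4_pct,
    cd45ro_cd4_pct, cd28_cd8_pct, hladr_cd8_pct

Rows violating the panel or subject invariants are rejected one by one
with a logged reason — never silently dropped: rows in = rows accepted +
rows rejected.  Output formatting is fixed (counts and composites to 2
decimals, percentages and fractions to 4) so that identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    COMPOSITE_PARAMETERS,
    COUNT_PARAMETERS,
    IngestError,
    LymphocytePanel,
    MEASURED_PARAMETERS,
    PERCENT_PARAMETERS,
    SubjectRecord,
)
from .evaluation import bin_scores, sensitivity_specificity
from .reference import ReferenceTable, build_reference_table, bundled_paper_table, load_table
from .scoring import ScoreBreakdown, score_cohort
from .synthetic import (
    PerturbationSpec,
    SyntheticCohortSpec,
    generate_healthy_cohort,
    generate_patient_cohort,
)

__all__ = [
    "CANONICAL_COLUMNS",
    "CohortReadResult",
    "RunConfig",
    "read_cohort",
    "read_cohort_detailed",
    "write_cohort",
    "write_scores",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "age",
    "sex",
    "cohort",
) + MEASURED_PARAMETERS

Cohort = list[tuple[SubjectRecord, LymphocytePanel]]


@dataclass
class CohortReadResult:
    accepted: Cohort
    rejected: list[tuple[int, str]]  # (0-based data-row index, reason)

    @property
    def n_read(self) -> int:
        return len(self.accepted) + len(self.rejected)


def read_cohort_detailed(path: str | Path) -> CohortReadResult:
    """Read a cohort file, keeping per-row rejection reasons."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required columns {missing}")

    accepted: Cohort = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            if any(pd.isna(row[c]) for c in CANONICAL_COLUMNS):
                bad = [c for c in CANONICAL_COLUMNS if pd.isna(row[c])]
                raise IngestError(f"missing values in {bad}")
            record = SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                cohort=str(row["cohort"]).strip().lower(),
            )
            panel = LymphocytePanel(**{p: float(row[p]) for p in MEASURED_PARAMETERS})
        except (IngestError, ValueError, TypeError) as exc:
            logger.warning("%s: row %d rejected: %s", path, i, exc)
            rejected.append((i, str(exc)))
            continue
        accepted.append((record, panel))
    logger.info(
        "%s: %d rows read, %d accepted, %d rejected",
        path,
        len(accepted) + len(rejected),
        len(accepted),
        len(rejected),
    )
    return CohortReadResult(accepted=accepted, rejected=rejected)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort file; rejected rows are logged (see
    :func:`read_cohort_detailed` for programmatic access to reasons)."""
    return read_cohort_detailed(path).accepted


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def write_cohort(cohort: Iterable[tuple[SubjectRecord, LymphocytePanel]], path: str | Path) -> None:
    """Write a cohort CSV in the canonical schema with fixed formatting."""
    rows = []
    for record, panel in cohort:
        row: dict[str, str] = {
            "subject_id": record.subject_id,
            "age": _fmt(record.age, 2),
            "sex": record.sex,
            "cohort": record.cohort,
        }
        for p in COUNT_PARAMETERS:
            row[p] = _fmt(getattr(panel, p), 2)
        for p in PERCENT_PARAMETERS:
            row[p] = _fmt(getattr(panel, p), 4)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def write_scores(breakdowns: Sequence[ScoreBreakdown], path: str | Path) -> None:
    """Write one row per subject: tiers, total, classification."""
    params = list(COMPOSITE_PARAMETERS)
    rows = []
    for b in breakdowns:
        row = {"subject_id": b.subject_id, "group_used": b.group_used}
        for p in params:
            row[p] = b.per_parameter.get(p, "")
        row["total"] = b.total
        row["classification"] = b.classification
        rows.append(row)
    columns = ["subject_id", "group_used", *params, "total", "classification"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, lineterminator="\n")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one cohort source: ``cohort_path`` or simulation sizes.
    Exactly one reference-table source: ``table="bundled"``, a file path,
    or ``"build"`` (estimate from the healthy members of the cohort).
    """

    cohort_path: str | None = None
    simulate_healthy_n: int | None = None
    simulate_hyper_n: int | None = None
    simulate_hypo_n: int | None = None
    age_range: tuple[float, float] | None = None
    table: str = "bundled"
    subset: list[str] | None = None
    seed: int = 0
    out_dir: str = "immunoscore_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "age_range" in raw and raw["age_range"] is not None:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)


def _assemble_cohort(config: RunConfig) -> tuple[Cohort, list[tuple[int, str]]]:
    if config.cohort_path is not None:
        result = read_cohort_detailed(config.cohort_path)
        return result.accepted, result.rejected
    cohort: Cohort = []
    if config.simulate_healthy_n:
        spec = SyntheticCohortSpec(seed=config.seed)
        cohort.extend(
            generate_healthy_cohort(spec, n=config.simulate_healthy_n, age_range=config.age_range)
        )
    if config.simulate_hyper_n:
        perturb = PerturbationSpec("hyperimmune", n=config.simulate_hyper_n, seed=config.seed + 1)
        cohort.extend(
            generate_patient_cohort(SyntheticCohortSpec(seed=config.seed), perturb, config.age_range)
        )
    if config.simulate_hypo_n:
        perturb = PerturbationSpec("hypoimmune", n=config.simulate_hypo_n, seed=config.seed + 2)
        cohort.extend(
            generate_patient_cohort(SyntheticCohortSpec(seed=config.seed), perturb, config.age_range)
        )
    if not cohort:
        raise ValueError("config selects no cohort: set cohort_path or a simulate_*_n size")
    return cohort, []


def _resolve_table(config: RunConfig, cohort: Cohort) -> ReferenceTable:
    if config.table == "bundled":
        return bundled_paper_table()
    if config.table == "build":
        healthy = [(r, p) for r, p in cohort if r.cohort == "healthy"]
        return build_reference_table(healthy)
    return load_table(config.table)


def run_pipeline(config: RunConfig) -> dict:
    """Execute ranges → derive → score → classify → evaluate.

    Writes ``scores.csv``, ``evaluation.json`` and ``run_log.json`` under
    ``config.out_dir`` and returns the evaluation report.  Deterministic:
    identical config (including seed) gives byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    cohort, rejected = _assemble_cohort(config)
    table = _resolve_table(config, cohort)
    breakdowns = score_cohort(cohort, table, config.subset)

    by_label: dict[str, list[ScoreBreakdown]] = {}
    for (record, _), breakdown in zip(cohort, breakdowns):
        by_label.setdefault(record.cohort, []).append(breakdown)

    report: dict = {
        "table_provenance": table.provenance,
        "n_scored": len(breakdowns),
        "n_rejected": len(rejected),
        "bins": {},
        "diagnostics": {},
    }
    for label, group in sorted(by_label.items()):
        bins = bin_scores(group)
        totals = [b.total for b in group]
        report["bins"][label] = {
            "n_below": bins.n_below,
            "n_zero": bins.n_zero,
            "n_above": bins.n_above,
            "mean_total": round(sum(totals) / len(totals), 4),
            "min_total": min(totals),
            "max_total": max(totals),
        }
    if "healthy" in by_label:
        control_bins = bin_scores(by_label["healthy"])
        for condition in ("hyperimmune", "hypoimmune"):
            if condition in by_label:
                result = sensitivity_specificity(
                    bin_scores(by_label[condition]), control_bins, condition
                )
                report["diagnostics"][condition] = {
                    "cutoff": "total > 0" if condition == "hyperimmune" else "total < 0",
                    "sensitivity": round(result.sensitivity, 4),
                    "specificity": round(result.specificity, 4),
                    "positives": result.positives,
                    "negatives": result.negatives,
                }

    out_dir.mkdir(parents=True, exist_ok=True)
    write_scores(breakdowns, out_dir / "scores.csv")
    (out_dir / "evaluation.json").write_text(json.dumps(report, indent=1) + "\n")
    log = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "rows_in": len(cohort) + len(rejected),
        "rows_scored": len(breakdowns),
        "rows_rejected": len(rejected),
        "rejection_reasons": rejected,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1) + "\n")
    return report
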