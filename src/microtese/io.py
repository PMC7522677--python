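"""Patient-record CSV schema, JSON report serialization, table formatting."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .cohort import PatientRecord, SubgroupSummary, VocabularyError
from .geometry import AreaBreakdown, TestisEllipsoid
from .strategies import Recommendation, StrategyComparison, strategy_by_label

CSV_COLUMNS = ["id", "cohort", "subgroup", "histopathology", "outcome"]
_OUTCOME_TO_STR = {True: "success", False: "failure"}
_STR_TO_OUTCOME = {"success": True, "failure": False}


class CsvSchemaError(ValueError):
    """Patient CSV violating the schema; message lists offending rows."""


def write_patient_csv(records: list[PatientRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "cohort": [r.cohort for r in records],
            "subgroup": [r.subgroup for r in records],
            "histopathology": [r.histopathology for r in records],
            "outcome": [_OUTCOME_TO_STR[r.outcome] for r in records],
        },
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_patient_csv(path: str | Path) -> list[PatientRecord]:
    """Read a patient CSV, reporting schema violations with row numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CsvSchemaError(f"{path}: missing required columns {missing}")
    records: list[PatientRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            outcome = _STR_TO_OUTCOME.get(str(row.outcome).strip().lower())
            if outcome is None:
                raise ValueError(
                    f"outcome must be 'success' or 'failure', got {row.outcome!r}"
                )
            records.append(
                PatientRecord(
                    id=str(row.id),
                    cohort=str(row.cohort),
                    subgroup=str(row.subgroup),
                    histopathology=str(row.histopathology),
                    outcome=outcome,
                )
            )
        except (ValueError, VocabularyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise CsvSchemaError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return records


def _breakdown_dict(b: AreaBreakdown) -> dict[str, float]:
    return {
        "bivalve_face_area_mm2": b.bivalve_face_area,
        "slice_face_sum_mm2": b.slice_face_sum,
        "total_mm2": b.total,
    }


def comparison_report(
    comparison: StrategyComparison, *, seed: int | None = None
) -> dict[str, Any]:
    """JSON-serializable per-strategy report with provenance."""
    t = comparison.testis
    return {
        "provenance": {
            "package": "microtese",
            "version": __version__,
            "seed": seed,
            "inputs": {
                "ratios": list(t.ratios),
                "slice_width_mm": t.l,
                "strict": t.strict,
            },
        },
        "strategies": {
            str(label): {
                "description": strategy_by_label(label).describe(),
                **_breakdown_dict(b),
            }
            for label, b in sorted(comparison.breakdowns.items())
        },
        "ranking": list(comparison.order),
        "ties": [sorted(g) for g in comparison.ties],
        "pairwise_differences_mm2": {
            f"{i}-{j}": d for (i, j), d in sorted(comparison.differences.items())
        },
    }


def recommendation_report(rec: Recommendation, *, seed: int | None = None) -> dict[str, Any]:
    report = comparison_report(rec.comparison, seed=seed)
    report["provenance"]["inputs"]["semi_axes_mm"] = list(rec.semi_axes_mm)
    report["recommendation"] = {
        "best_method": rec.best.method_label,
        "description": rec.best.describe(),
        "rounding_residuals_mm": list(rec.rounding_residuals_mm),
        "gain_over_second_pct": rec.gain_over_second_pct,
    }
    return report


def summaries_to_json(rows: list[SubgroupSummary], alpha: float) -> dict[str, Any]:
    return {
        "alpha": alpha,
        "rows": [
            {
                "label": r.label,
                "kind": r.kind,
                "previous": {"successes": r.successes_g1, "n": r.n_g1, "srr_pct": r.srr_g1},
                "new": {"successes": r.successes_g2, "n": r.n_g2, "srr_pct": r.srr_g2},
                "chi2": r.statistic,
                "p": r.p,
                "significant": r.significant,
            }
            for r in rows
        ],
    }


def format_summary_table(rows: list[SubgroupSummary], alpha: float) -> str:
    """Aligned-text cohort table mirroring the published layout."""
    header = ["Subgroup", "Previous method", "New method", "P"]
    lines = [header]
    for r in rows:
        if r.p is None:
            p_cell = "-"
        elif r.significant:
            p_cell = f"{r.p:.3f}".lstrip("0")
        else:
            p_cell = "NS"
        lines.append([r.label, r.fraction(1), r.fraction(2), p_cell])
    widths = [max(len(row[k]) for row in lines) for k in range(4)]
    out = []
    for row in lines:
        out.append("  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip())
    out.insert(1, "-" * len(out[0]))
    out.append(f"(uncorrected Pearson chi-square, alpha={alpha:g}; '-' = not computable)")
    return "\n".join(out)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
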