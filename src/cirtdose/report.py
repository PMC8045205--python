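"""Deterministic rendering of conversion tables and compliance reports.

All engine computation is carried at full floating precision; this module
owns the only rounding step (half-up, 2 decimals by default), matching the
precision at which dose constraints are conventionally printed.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .dvh import CohortSummary, ComplianceReport
from .strategies import ConstraintTable

__all__ = [
    "round_half_up",
    "render_constraint_table",
    "constraint_table_json",
    "compliance_frame",
    "summary_frame",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (printed-table convention), returned as float."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def render_constraint_table(table: ConstraintTable, decimals: int = 2) -> pd.DataFrame:
    """Rounded copy of a constraint table, ready for CSV output."""
    frame = table.frame.copy()
    for col in frame.columns:
        if col == "label":
            continue
        frame[col] = frame[col].map(lambda v: round_half_up(v, decimals))
    return frame


def constraint_table_json(
    table: ConstraintTable, config: dict | None = None
) -> str:
    """Full-precision provenance of every conversion, as JSON."""
    results = [
        {
            "source_label": r.source.label,
            "source_limit": r.source.limit,
            "source_model": r.source.model_tag,
            "source_n_fractions": r.source.scheme.n_fractions,
            "strategy": r.strategy.value,
            "target_n_fractions": r.target.scheme.n_fractions,
            "target_model": r.target.model_tag,
            "target_limit": r.target.limit,
            "intermediates": [
                {"step": step, "dose_gy_rbe": value} for step, value in r.intermediates
            ],
            "curve_id": r.curve_id,
            "alpha_beta": r.alpha_beta,
        }
        for r in table.results
    ]
    payload = {"config": config or {}, "results": results}
    return json.dumps(payload, indent=2)


def compliance_frame(reports: Sequence[ComplianceReport]) -> pd.DataFrame:
    """Long-format per-patient, per-constraint compliance records."""
    rows = []
    for rep in reports:
        for rec in rep.records:
            rows.append(
                {
                    "patient_id": rep.patient_id,
                    "constraint": rec.constraint_label,
                    "measured_gy_rbe": rec.measured,
                    "limit_gy_rbe": rec.limit,
                    "margin_gy_rbe": rec.margin,
                    "passed": "" if rec.passed is None else str(rec.passed).lower(),
                    "evaluable": str(rec.evaluable).lower(),
                }
            )
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "patient_id", "constraint", "measured_gy_rbe", "limit_gy_rbe",
            "margin_gy_rbe", "passed", "evaluable",
        ],
    )


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    rows = [
        {
            "constraint": label,
            "median_gy_rbe": summary.median[label],
            "max_gy_rbe": summary.maximum[label],
            "exceedance_count": summary.exceedance_count[label],
            "not_evaluable_count": summary.not_evaluable_count[label],
            "n_patients": summary.n_patients,
        }
        for label in summary.median
    ]
    return pd.DataFrame.from_records(rows)


def write_text(path: str | Path, text: str) -> None:
    Path(path).write_text(text)
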