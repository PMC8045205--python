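"""Cumulative DVH metrics (D_x%, D_xcc) and constraint-compliance evaluation.

Convention: a DVH is the cumulative dose-volume curve of one structure —
``rel_volume[i]`` is the fraction of the structure receiving at least
``dose_grid[i]`` Gy (RBE).  Metrics are read off by linear interpolation;
flat segments resolve to the lowest dose achieving the volume level
(left-most crossing), which is the conservative choice for organ-at-risk
limits.  D0% is the v -> 0 crossing, i.e. the maximum dose received by any
part of the structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constraints import ConstraintSet, DoseConstraint

__all__ = [
    "DVH",
    "ComplianceRecord",
    "ComplianceReport",
    "CohortSummary",
    "dose_at_relative_volume",
    "dose_at_absolute_volume",
    "evaluate_compliance",
    "cohort_summary",
    "read_dvh_csv",
    "write_dvh_csv",
]


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram for one structure.

    ``dose_grid`` is strictly increasing starting at 0 Gy (RBE);
    ``rel_volume`` is non-increasing with ``rel_volume[0] == 1``.
    """

    structure_name: str
    total_volume: float  # cc
    dose_grid: np.ndarray
    rel_volume: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_grid, dtype=float)
        vol = np.asarray(self.rel_volume, dtype=float)
        object.__setattr__(self, "dose_grid", dose)
        object.__setattr__(self, "rel_volume", vol)
        if not (math.isfinite(self.total_volume) and self.total_volume > 0):
            raise ValueError(f"total_volume must be > 0 cc, got {self.total_volume}")
        if dose.ndim != 1 or vol.ndim != 1 or dose.size != vol.size or dose.size < 2:
            raise ValueError("dose_grid and rel_volume must be 1-D, equal length >= 2")
        if dose[0] != 0.0:
            raise ValueError(f"dose_grid must start at 0 Gy, got {dose[0]}")
        if np.any(np.diff(dose) <= 0):
            raise ValueError("dose_grid must be strictly increasing")
        if vol[0] != 1.0:
            raise ValueError(
                f"rel_volume[0] must be 1 (cumulative DVH), got {vol[0]}; "
                "differential DVHs are not accepted — convert to cumulative upstream"
            )
        if np.any(np.diff(vol) > 0):
            raise ValueError(
                "rel_volume must be non-increasing (cumulative DVH); "
                "differential DVHs are not accepted — convert to cumulative upstream"
            )
        if vol[-1] < 0 or vol[0] > 1:
            raise ValueError("rel_volume must lie in [0, 1]")


def dose_at_relative_volume(dvh: DVH, v: float) -> float:
    """Dose at which the cumulative curve crosses relative volume ``v``.

    Left-most crossing: the smallest dose (on the piecewise-linear curve)
    whose relative volume is <= ``v``.  ``v = 0`` gives the maximum dose;
    ``v = 1`` gives 0 Gy.  If the recorded curve never falls to ``v`` the
    final grid dose is returned (the curve's information ends there).
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"relative volume must be in [0, 1], got {v}")
    dose, vol = dvh.dose_grid, dvh.rel_volume
    if vol[0] <= v:
        return float(dose[0])
    if vol[-1] > v:
        return float(dose[-1])
    # first index where the curve has dropped to <= v
    idx = int(np.argmax(vol <= v))
    d0, d1 = dose[idx - 1], dose[idx]
    r0, r1 = vol[idx - 1], vol[idx]
    if r0 == r1:  # defensive; r0 > v >= r1 rules this out
        return float(d0)
    return float(d0 + (d1 - d0) * (r0 - v) / (r0 - r1))


def dose_at_absolute_volume(dvh: DVH, v_cc: float) -> float:
    """D_xcc: dose to the hottest ``v_cc`` cc, via the ratio identity."""
    if v_cc <= 0:
        raise ValueError(f"absolute volume must be > 0 cc, got {v_cc}")
    if v_cc > dvh.total_volume:
        raise ValueError(
            f"absolute volume {v_cc} cc exceeds structure volume "
            f"{dvh.total_volume} cc; constraint is not evaluable"
        )
    return dose_at_relative_volume(dvh, v_cc / dvh.total_volume)


def measure_constraint(dvh: DVH, constraint: DoseConstraint) -> float:
    """Measured value of a constraint's metric on a DVH (raises if vacuous)."""
    if constraint.metric_kind == "percent-volume":
        return dose_at_relative_volume(dvh, constraint.volume_param)
    return dose_at_absolute_volume(dvh, constraint.volume_param)


# ---------------------------------------------------------------------- #
# Compliance


@dataclass(frozen=True)
class ComplianceRecord:
    constraint_label: str
    measured: float  # NaN when not evaluable
    limit: float
    margin: float  # measured - limit; NaN when not evaluable
    passed: bool | None  # None = not evaluable
    evaluable: bool = True


@dataclass(frozen=True)
class ComplianceReport:
    patient_id: str
    records: tuple[ComplianceRecord, ...]

    def exceeded_labels(self) -> list[str]:
        return [r.constraint_label for r in self.records if r.passed is False]


def evaluate_compliance(dvh: DVH, constraints: ConstraintSet,
                        patient_id: str = "") -> ComplianceReport:
    """Measure every constraint metric on a DVH and flag pass/fail.

    A constraint passes iff its margin (measured - limit) is <= 0.
    Absolute-volume constraints larger than the structure are reported as
    not evaluable — never as a silent pass.
    """
    records = []
    for c in constraints:
        if c.metric_kind == "absolute-volume" and c.volume_param > dvh.total_volume:
            records.append(
                ComplianceRecord(c.label, float("nan"), c.limit, float("nan"),
                                 passed=None, evaluable=False)
            )
            continue
        measured = measure_constraint(dvh, c)
        margin = measured - c.limit
        records.append(
            ComplianceRecord(c.label, measured, c.limit, margin, passed=margin <= 0)
        )
    return ComplianceReport(patient_id=patient_id, records=tuple(records))


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    median: dict[str, float]  # per metric label
    maximum: dict[str, float]
    exceedance_count: dict[str, int]  # per constraint label
    not_evaluable_count: dict[str, int]


def cohort_summary(reports: Sequence[ComplianceReport]) -> CohortSummary:
    """Per-metric medians/maxima and per-constraint exceedance counts."""
    if not reports:
        raise ValueError("need at least one compliance report")
    labels = [r.constraint_label for r in reports[0].records]
    for rep in reports[1:]:
        if [r.constraint_label for r in rep.records] != labels:
            raise ValueError(
                f"inconsistent constraint labels across reports (patient {rep.patient_id!r})"
            )
    median: dict[str, float] = {}
    maximum: dict[str, float] = {}
    exceed: dict[str, int] = {}
    not_eval: dict[str, int] = {}
    for i, label in enumerate(labels):
        values = [rep.records[i].measured for rep in reports if rep.records[i].evaluable]
        median[label] = float(np.median(values)) if values else float("nan")
        maximum[label] = float(np.max(values)) if values else float("nan")
        exceed[label] = sum(1 for rep in reports if rep.records[i].passed is False)
        not_eval[label] = sum(1 for rep in reports if not rep.records[i].evaluable)
    return CohortSummary(
        n_patients=len(reports),
        median=median,
        maximum=maximum,
        exceedance_count=exceed,
        not_evaluable_count=not_eval,
    )


# ---------------------------------------------------------------------- #
# DVH CSV dialect: metadata comments "# structure=<name>" and
# "# total_volume_cc=<value>", header "dose_gy_rbe,relative_volume".

_DVH_HEADER = "dose_gy_rbe,relative_volume"


def write_dvh_csv(dvh: DVH, path: str | Path) -> None:
    lines = [
        f"# structure={dvh.structure_name}",
        f"# total_volume_cc={dvh.total_volume:g}",
        _DVH_HEADER,
    ]
    lines += [
        f"{d:.6g},{v:.8g}" for d, v in zip(dvh.dose_grid, dvh.rel_volume)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dvh_csv(path: str | Path) -> DVH:
    structure = Path(path).stem
    total_volume: float | None = None
    doses: list[float] = []
    vols: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("structure="):
                structure = body.split("=", 1)[1].strip()
            elif body.startswith("total_volume_cc="):
                total_volume = float(body.split("=", 1)[1])
            continue
        if not header_seen:
            if line.replace(" ", "") != _DVH_HEADER:
                raise ValueError(
                    f"{path}:{lineno}: expected header {_DVH_HEADER!r}, got {line!r}"
                )
            header_seen = True
            continue
        fields = line.split(",")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            doses.append(float(fields[0]))
            vols.append(float(fields[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not header_seen:
        raise ValueError(f"{path}: missing header line {_DVH_HEADER!r}")
    if total_volume is None:
        raise ValueError(f"{path}: missing '# total_volume_cc=' metadata line")
    try:
        return DVH(structure, total_volume, np.array(doses), np.array(vols))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
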