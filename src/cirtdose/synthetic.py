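"""Seeded synthetic inputs: DVHs, patient cohorts, and conversion curves.

No patient DVHs are published for this problem domain, so every pipeline
stage is exercised against generated data whose ground truth is known by
construction: DVHs with prescribed D_x%/D_xcc values, cohorts with an exact
number of constraint exceedances, and smooth monotone conversion curves
with a decreasing LEM/MKM dose ratio.

Seeding: one root seed; per-patient generators are spawned as
``default_rng([root_seed, patient_index])`` so that changing the cohort
size never reshuffles existing patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constraints import ConstraintSet, DoseConstraint, parse_metric_label
from .curve import ConversionCurve, build_curve
from .dvh import DVH, write_dvh_csv

__all__ = [
    "DVHShapeParams",
    "CohortSpec",
    "SyntheticPatient",
    "SyntheticCohort",
    "generate_dvh",
    "generate_dvh_with_metrics",
    "generate_cohort",
    "generate_conversion_curve",
    "fit_ratio_params",
    "write_cohort",
]

GRID_STEP = 0.1  # Gy (RBE); finer than any tolerance used in tests


@dataclass(frozen=True)
class DVHShapeParams:
    """Logistic-shoulder cumulative DVH shape.

    ``d50`` is the dose at 50% relative volume, ``steepness`` the logistic
    width in Gy, ``tail_dmax`` the end of the dose grid, ``noise_sd`` the
    standard deviation of pointwise volume noise (isotonically repaired).
    """

    d50: float
    steepness: float
    tail_dmax: float
    noise_sd: float = 0.0
    seed: int = 0
    total_volume: float = 50.0
    structure_name: str = "rectum"

    def __post_init__(self) -> None:
        if self.d50 <= 0 or self.steepness <= 0:
            raise ValueError("d50 and steepness must be > 0")
        if self.tail_dmax <= self.d50:
            raise ValueError("tail_dmax must exceed d50")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_dvh(params: DVHShapeParams) -> DVH:
    """Monotone non-increasing logistic cumulative DVH on a 0.1 Gy grid.

    With ``noise_sd = 0`` the curve is ``1 / (1 + exp((d - d50)/steepness))``
    clamped to start at exactly 1; noise is added pointwise, clipped to
    [0, 1] and repaired to non-increasing by a running minimum.
    Deterministic for a fixed seed.
    """
    grid = np.arange(0.0, params.tail_dmax + GRID_STEP / 2, GRID_STEP)
    rel = 1.0 / (1.0 + np.exp((grid - params.d50) / params.steepness))
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        rel = rel + rng.normal(0.0, params.noise_sd, size=rel.shape)
    rel = np.clip(rel, 0.0, 1.0)
    rel[0] = 1.0
    rel = np.minimum.accumulate(rel)
    return DVH(params.structure_name, params.total_volume, grid, rel)


def _normalize_targets(
    targets: Sequence[tuple[str, float]], total_volume: float
) -> list[tuple[float, float]]:
    """Targets as (relative volume, dose) pairs, validated for consistency."""
    points: list[tuple[float, float]] = []
    for label, dose in targets:
        kind, param = parse_metric_label(label)
        v = param if kind == "percent-volume" else param / total_volume
        if not 0.0 <= v < 1.0:
            raise ValueError(
                f"target {label!r} implies relative volume {v:.3f} outside [0, 1)"
            )
        if dose <= 0:
            raise ValueError(f"target {label!r} dose must be > 0, got {dose}")
        points.append((v, dose))
    points.sort(key=lambda p: p[0])
    for (v0, d0), (v1, d1) in zip(points, points[1:]):
        if v0 == v1:
            raise ValueError(f"duplicate volume parameter {v0:.3f} in targets")
        if d0 <= d1:
            raise ValueError(
                "inconsistent targets: dose must decrease as the volume "
                f"parameter increases (v={v0:.3f} -> {d0} vs v={v1:.3f} -> {d1})"
            )
    return points


def generate_dvh_with_metrics(
    targets: Sequence[tuple[str, float]],
    seed: int | None = None,
    total_volume: float = 50.0,
    structure_name: str = "rectum",
) -> DVH:
    """Piecewise-linear cumulative DVH hitting each (metric, value) target.

    ``targets`` are ``(label, dose)`` pairs with labels like ``"D20%"`` or
    ``"D10cc"``.  Construction is deterministic (``seed`` is accepted for
    interface symmetry with the other generators but unused): a piecewise-
    linear curve through (0 Gy, 1) and the implied (dose, volume) points,
    closed by a max-dose point, sampled on the union of the 0.1 Gy grid and
    the exact breakpoints so that re-measuring recovers every target.
    """
    points = _normalize_targets(targets, total_volume)
    # breakpoints in dose order: (0,1), then targets with v descending
    bp_d = [0.0]
    bp_v = [1.0]
    for v, d in sorted(points, key=lambda p: -p[0]):
        bp_d.append(d)
        bp_v.append(v)
    if bp_v[-1] > 0.0:  # close the curve at a max dose beyond the last target
        bp_d.append(bp_d[-1] + 2.0)
        bp_v.append(0.0)
    bp_d_arr = np.array(bp_d)
    bp_v_arr = np.array(bp_v)
    grid = np.union1d(np.arange(0.0, bp_d_arr[-1] + GRID_STEP / 2, GRID_STEP), bp_d_arr)
    grid = grid[grid <= bp_d_arr[-1] + 1e-12]
    rel = np.interp(grid, bp_d_arr, bp_v_arr)
    rel[0] = 1.0
    rel = np.minimum.accumulate(np.clip(rel, 0.0, 1.0))
    return DVH(structure_name, total_volume, grid, rel)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of ``n_patients`` with controlled constraint exceedances.

    ``exceed_counts`` maps constraint labels to the exact number of
    patients whose DVH must exceed that limit.  Exceeding subsets are
    nested by construction: the patients exceeding any constraint are
    always the first ``k`` of the cohort, so a spec like
    ``{"D20%": 8, "D10%": 4}`` makes the 4 D10% violators a subset of the
    8 D20% violators (mirroring nested serial-organ exceedances).
    """

    n_patients: int
    n_fractions: int = 16
    exceed_counts: Mapping[str, int] = field(default_factory=dict)
    volume_range: tuple[float, float] = (34.59, 75.29)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for label, k in self.exceed_counts.items():
            if not 0 <= k <= self.n_patients:
                raise ValueError(
                    f"exceedance count for {label!r} must be in [0, {self.n_patients}]"
                )
        lo, hi = self.volume_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid volume range {self.volume_range}")


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    dvh: DVH
    truth: tuple[tuple[str, float, bool], ...]  # (label, true metric, exceeds)


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    patients: tuple[SyntheticPatient, ...]

    def truth_exceedance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.patients:
            for label, _, exceeds in p.truth:
                counts[label] = counts.get(label, 0) + int(exceeds)
        return counts


# margins used when drawing per-patient metric values, Gy (RBE)
_EXCEED_MARGIN_MAX = 2.0
_CLEARANCE_MIN = 0.3
_CLEARANCE_MAX = 5.0
_MIN_METRIC_GAP = 0.2


def _draw_patient_metrics(
    rng: np.random.Generator,
    constraints: Sequence[DoseConstraint],
    exceed_flags: Sequence[bool],
    total_volume: float,
) -> list[tuple[str, float, bool]]:
    """Metric values consistent with a cumulative DVH and the exceed flags.

    Constraints are processed in decreasing effective relative volume, so
    metric values must be strictly increasing; exceeders land in
    (limit, limit + 2], compliers strictly below the limit.
    """
    def eff_v(c: DoseConstraint) -> float:
        if c.metric_kind == "percent-volume":
            return c.volume_param
        return c.volume_param / total_volume

    order = sorted(range(len(constraints)), key=lambda i: -eff_v(constraints[i]))
    prev = 0.0
    out: dict[int, tuple[str, float, bool]] = {}
    for i in order:
        c = constraints[i]
        if exceed_flags[i]:
            lo = max(c.limit, prev + _MIN_METRIC_GAP)
            hi = c.limit + _EXCEED_MARGIN_MAX
            if lo >= hi:
                raise ValueError(
                    f"infeasible joint exceedance pattern at {c.label!r}: "
                    f"previous metric {prev:.2f} leaves no room above limit {c.limit}"
                )
            value = rng.uniform(max(lo, hi - _EXCEED_MARGIN_MAX), hi)
            if value <= c.limit:  # guard against landing exactly on the limit
                value = c.limit + 1e-6
        else:
            lo = max(c.limit - _CLEARANCE_MAX, prev + _MIN_METRIC_GAP)
            hi = c.limit - _CLEARANCE_MIN
            if lo >= hi:
                raise ValueError(
                    f"infeasible pattern at {c.label!r}: previous metric "
                    f"{prev:.2f} too close to limit {c.limit}"
                )
            value = rng.uniform(lo, hi)
        out[i] = (c.label, float(value), bool(exceed_flags[i]))
        prev = value
    return [out[i] for i in range(len(constraints))]


def generate_cohort(spec: CohortSpec, constraints: ConstraintSet) -> SyntheticCohort:
    """Cohort whose exceedance truth table exactly matches ``spec``.

    Patient ``p`` exceeds constraint ``label`` iff ``p < exceed_counts[label]``.
    Per-patient randomness comes from ``default_rng([seed, p])`` so cohorts
    are bit-reproducible and extendable without reshuffling.
    """
    labels = [c.label for c in constraints]
    for label in spec.exceed_counts:
        if label not in labels:
            raise KeyError(f"exceedance target {label!r} not in constraint set")
    patients = []
    for p in range(spec.n_patients):
        rng = np.random.default_rng([spec.seed, p])
        total_volume = float(rng.uniform(*spec.volume_range))
        flags = [p < spec.exceed_counts.get(c.label, 0) for c in constraints]
        truth = _draw_patient_metrics(rng, list(constraints), flags, total_volume)
        dvh = generate_dvh_with_metrics(
            [(label, value) for label, value, _ in truth],
            total_volume=total_volume,
            structure_name="rectum",
        )
        patients.append(
            SyntheticPatient(
                patient_id=f"P{p + 1:03d}", dvh=dvh, truth=tuple(truth)
            )
        )
    return SyntheticCohort(spec=spec, patients=tuple(patients))


# ---------------------------------------------------------------------- #
# Synthetic conversion curves


def fit_ratio_params(
    anchor_low: tuple[float, float], anchor_high: tuple[float, float]
) -> tuple[float, float]:
    """Solve ``lem/mkm = 1 + a*exp(-mkm/b)`` through two anchor pairs."""
    (m1, l1), (m2, l2) = anchor_low, anchor_high
    r1, r2 = l1 / m1 - 1.0, l2 / m2 - 1.0
    if r1 <= 0 or r2 <= 0 or r1 <= r2:
        raise ValueError("anchors must have decreasing LEM/MKM ratio > 1")
    b = (m2 - m1) / math.log(r1 / r2)
    a = r1 * math.exp(m1 / b)
    return a, b


def generate_conversion_curve(
    dose_range: tuple[float, float],
    a: float,
    b: float,
    spacing: float = 5.0,
    scheme_label: str = "synthetic",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ConversionCurve:
    """Smooth monotone curve ``lem = mkm * (1 + a*exp(-mkm/b))``.

    ``a = 0`` yields the identity line.  The LEM/MKM ratio decreases with
    dose for any ``a, b > 0``, matching the shape of measured conversion
    curves.  Optional anchor noise is isotonically repaired; the result is
    validated by :func:`cirtdose.curve.build_curve`.
    """
    if a < 0 or b <= 0:
        raise ValueError("require a >= 0 and b > 0")
    lo, hi = dose_range
    if not 0 < lo < hi:
        raise ValueError(f"invalid dose range {dose_range}")
    mkm = np.arange(lo, hi + spacing / 2, spacing)
    lem = mkm * (1.0 + a * np.exp(-mkm / b))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        lem = lem + rng.normal(0.0, noise_sd, size=lem.shape)
        lem = np.maximum.accumulate(lem)
        if np.any(np.diff(lem) <= 0):
            lem += np.arange(lem.size) * 1e-6
    return build_curve(list(zip(mkm, lem)), scheme_label=scheme_label)


# ---------------------------------------------------------------------- #
# On-disk artifacts (same dialects dvh_metrics reads)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write DVH CSVs, a cohort manifest, and the ground-truth table.

    Returns the manifest path.  Truth table columns:
    ``patient_id,metric,true_value,exceeds``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_lines = ["patient_id,dvh_path,n_fractions"]
    truth_lines = ["patient_id,metric,true_value,exceeds"]
    for patient in cohort.patients:
        dvh_path = out / f"{patient.patient_id}_dvh.csv"
        write_dvh_csv(patient.dvh, dvh_path)
        manifest_lines.append(
            f"{patient.patient_id},{dvh_path.name},{cohort.spec.n_fractions}"
        )
        for label, value, exceeds in patient.truth:
            truth_lines.append(
                f"{patient.patient_id},{label},{value:.6f},{int(exceeds)}"
            )
    manifest = out / "cohort_manifest.csv"
    manifest.write_text("\n".join(manifest_lines) + "\n")
    (out / "truth_table.csv").write_text("\n".join(truth_lines) + "\n")
    return manifest
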