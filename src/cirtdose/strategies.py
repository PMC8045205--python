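"""Constraint-conversion strategies composing LQ rescaling and RBE curves.

Two orderings of the same two operations are supported for converting a
16-fraction MKM constraint to a hypofractionated LEM constraint:

* ``MKM_LQ`` — LQ-rescale in MKM space first, then map MKM -> LEM with the
  conversion curve of the *target* scheme.
* ``LEM_LQ`` — map MKM -> LEM with the *source*-scheme curve first, then
  LQ-rescale in LEM space.

LEM-native constraint sets (absolute-volume limits) are adapted by first
inverting the source-scheme curve back to MKM when the MKM_LQ ordering is
requested; the LEM_LQ ordering applies LQ rescaling directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .constraints import ConstraintSet, DoseConstraint
from .curve import ConversionCurve
from .lq import FractionationScheme, LQParameters, TotalDose, isoeffect_total_dose

__all__ = [
    "Strategy",
    "ConversionResult",
    "convert_mkm_lq",
    "convert_lem_lq",
    "adapt_cnao",
    "convert_constraint",
    "relative_difference",
    "build_constraint_table",
]


class Strategy(str, enum.Enum):
    """Ordering of the LQ and RBE-conversion steps."""

    MKM_LQ = "MKM_LQ"  # LQ in MKM space first, curve second
    LEM_LQ = "LEM_LQ"  # curve first, LQ in LEM space second

    @classmethod
    def parse(cls, text: str) -> "Strategy":
        key = text.strip().upper().replace("-", "_").replace(" ", "_")
        return cls[key]


@dataclass(frozen=True)
class ConversionResult:
    """A converted constraint with full provenance of the conversion chain."""

    source: DoseConstraint
    target: DoseConstraint
    strategy: Strategy
    intermediates: tuple[tuple[str, float], ...]
    curve_id: str
    alpha_beta: float

    def __post_init__(self) -> None:
        if not self.intermediates:
            raise ValueError("intermediates must be non-empty")
        last = self.intermediates[-1][1]
        if last != self.target.limit:
            raise ValueError(
                f"provenance mismatch: final intermediate {last} != target {self.target.limit}"
            )


def _lq_rescale(
    value: float, model_tag: str, scheme_from: FractionationScheme,
    scheme_to: FractionationScheme, lq: LQParameters,
) -> float:
    dose = TotalDose(value, model_tag, scheme_from)
    return isoeffect_total_dose(dose, scheme_to, lq).value


def convert_mkm_lq(
    source: DoseConstraint,
    scheme_to: FractionationScheme,
    target_curve: ConversionCurve,
    lq: LQParameters,
) -> ConversionResult:
    """MKM_LQ ordering: LQ in MKM space, then the target-scheme curve."""
    if source.model_tag != "MKM":
        raise ValueError(f"MKM_LQ source must be MKM-tagged, got {source.model_tag}")
    mkm_at_target = _lq_rescale(source.limit, "MKM", source.scheme, scheme_to, lq)
    lem = target_curve.mkm_to_lem(mkm_at_target)
    steps = (
        (f"MKM@{scheme_to.n_fractions}fx (LQ)", mkm_at_target),
        (f"LEM@{scheme_to.n_fractions}fx (curve)", lem),
    )
    return ConversionResult(
        source=source,
        target=source.with_limit(lem, model_tag="LEM", scheme=scheme_to),
        strategy=Strategy.MKM_LQ,
        intermediates=steps,
        curve_id=target_curve.scheme_label,
        alpha_beta=lq.alpha_beta,
    )


def convert_lem_lq(
    source: DoseConstraint,
    scheme_to: FractionationScheme,
    curve_source_scheme: ConversionCurve,
    lq: LQParameters,
) -> ConversionResult:
    """LEM_LQ ordering: source-scheme curve first, then LQ in LEM space."""
    if source.model_tag != "MKM":
        raise ValueError(f"LEM_LQ source must be MKM-tagged, got {source.model_tag}")
    lem_at_source = curve_source_scheme.mkm_to_lem(source.limit)
    lem = _lq_rescale(lem_at_source, "LEM", source.scheme, scheme_to, lq)
    steps = (
        (f"LEM@{source.scheme.n_fractions}fx (curve)", lem_at_source),
        (f"LEM@{scheme_to.n_fractions}fx (LQ)", lem),
    )
    return ConversionResult(
        source=source,
        target=source.with_limit(lem, model_tag="LEM", scheme=scheme_to),
        strategy=Strategy.LEM_LQ,
        intermediates=steps,
        curve_id=curve_source_scheme.scheme_label,
        alpha_beta=lq.alpha_beta,
    )


def adapt_cnao(
    source: DoseConstraint,
    strategy: Strategy,
    scheme_to: FractionationScheme,
    curves: Mapping[int, ConversionCurve],
    lq: LQParameters,
) -> ConversionResult:
    """Adapt a LEM-native constraint to another scheme under either ordering.

    ``curves`` maps fraction number to the conversion curve for that scheme;
    the MKM_LQ ordering needs both the source-scheme curve (inverted) and
    the target-scheme curve, the LEM_LQ ordering needs no curve at all.
    """
    if source.model_tag != "LEM":
        raise ValueError(f"adapt_cnao source must be LEM-tagged, got {source.model_tag}")
    n_from = source.scheme.n_fractions
    if strategy is Strategy.LEM_LQ:
        lem = _lq_rescale(source.limit, "LEM", source.scheme, scheme_to, lq)
        steps = ((f"LEM@{scheme_to.n_fractions}fx (LQ)", lem),)
        curve_id = ""
    else:
        try:
            curve_from = curves[n_from]
            curve_to = curves[scheme_to.n_fractions]
        except KeyError as exc:
            raise KeyError(
                f"no conversion curve available for {exc.args[0]} fractions"
            ) from exc
        mkm_at_source = curve_from.lem_to_mkm(source.limit)
        mkm_at_target = _lq_rescale(mkm_at_source, "MKM", source.scheme, scheme_to, lq)
        lem = curve_to.mkm_to_lem(mkm_at_target)
        steps = (
            (f"MKM@{n_from}fx (inverse curve)", mkm_at_source),
            (f"MKM@{scheme_to.n_fractions}fx (LQ)", mkm_at_target),
            (f"LEM@{scheme_to.n_fractions}fx (curve)", lem),
        )
        curve_id = f"{curve_from.scheme_label}+{curve_to.scheme_label}"
    return ConversionResult(
        source=source,
        target=source.with_limit(lem, model_tag="LEM", scheme=scheme_to),
        strategy=strategy,
        intermediates=steps,
        curve_id=curve_id,
        alpha_beta=lq.alpha_beta,
    )


def convert_constraint(
    source: DoseConstraint,
    strategy: Strategy,
    scheme_to: FractionationScheme,
    curves: Mapping[int, ConversionCurve],
    lq: LQParameters,
) -> ConversionResult:
    """Dispatch on the source model tag (MKM-native vs LEM-native sets)."""
    if source.model_tag == "LEM":
        return adapt_cnao(source, strategy, scheme_to, curves, lq)
    if strategy is Strategy.MKM_LQ:
        try:
            curve_to = curves[scheme_to.n_fractions]
        except KeyError as exc:
            raise KeyError(
                f"no conversion curve available for {exc.args[0]} fractions"
            ) from exc
        return convert_mkm_lq(source, scheme_to, curve_to, lq)
    try:
        curve_from = curves[source.scheme.n_fractions]
    except KeyError as exc:
        raise KeyError(
            f"no conversion curve available for {exc.args[0]} fractions"
        ) from exc
    return convert_lem_lq(source, scheme_to, curve_from, lq)


def relative_difference(lem_lq_value: float, mkm_lq_value: float) -> float:
    """(LEM_LQ - MKM_LQ) / MKM_LQ * 100, in percent."""
    if mkm_lq_value <= 0:
        raise ValueError(f"denominator must be > 0, got {mkm_lq_value}")
    return (lem_lq_value - mkm_lq_value) / mkm_lq_value * 100.0


@dataclass
class ConstraintTable:
    """Wide table of converted limits plus per-conversion provenance."""

    frame: pd.DataFrame
    results: list[ConversionResult] = field(default_factory=list)


def build_constraint_table(
    sources: ConstraintSet,
    schemes: Sequence[FractionationScheme],
    strategies: Sequence[Strategy],
    curves: Mapping[int, ConversionCurve],
    lq: LQParameters,
) -> ConstraintTable:
    """One row per source constraint; scheme x strategy columns plus differences.

    All values are carried at full floating precision; rounding to printed
    precision is the renderer's job.
    """
    strategies = list(strategies)
    records: list[dict] = []
    results: list[ConversionResult] = []
    for src in sources:
        row: dict = {"label": src.label, "source_limit": src.limit}
        for scheme in schemes:
            per_strategy: dict[Strategy, float] = {}
            for strat in strategies:
                res = convert_constraint(src, strat, scheme, curves, lq)
                results.append(res)
                per_strategy[strat] = res.target.limit
                col = f"{scheme.n_fractions}fx_{strat.value.lower()}"
                row[col] = res.target.limit
            if Strategy.MKM_LQ in per_strategy and Strategy.LEM_LQ in per_strategy:
                row[f"{scheme.n_fractions}fx_diff_pct"] = relative_difference(
                    per_strategy[Strategy.LEM_LQ], per_strategy[Strategy.MKM_LQ]
                )
        records.append(row)
    columns = ["label", "source_limit"]
    for scheme in schemes:
        for strat in strategies:
            columns.append(f"{scheme.n_fractions}fx_{strat.value.lower()}")
        if Strategy.MKM_LQ in strategies and Strategy.LEM_LQ in strategies:
            columns.append(f"{scheme.n_fractions}fx_diff_pct")
    frame = pd.DataFrame.from_records(records, columns=columns)
    return ConstraintTable(frame=frame, results=results)
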