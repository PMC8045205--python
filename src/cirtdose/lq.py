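"""Linear-quadratic (LQ) iso-effect conversion of RBE-weighted total doses.

The iso-effect condition between two fractionation schemes is equality of
biologically effective dose (BED),

    N2 * d2 * (1 + d2 / (alpha/beta)) = N1 * d1 * (1 + d1 / (alpha/beta)),

where ``d`` is the dose per fraction and ``N`` the number of fractions.
Solving for ``d2`` uses the unique positive root of the quadratic; no
iterative solver is involved, so conversions are exact to floating-point
precision and trivially reversible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FractionationScheme",
    "LQParameters",
    "TotalDose",
    "RBE_MODELS",
    "bed",
    "isoeffect_total_dose",
]

#: Recognised RBE-model tags for RBE-weighted doses.
RBE_MODELS = ("MKM", "LEM")

#: Default alpha/beta ratio for rectum, in Gy.
DEFAULT_ALPHA_BETA = 3.9


@dataclass(frozen=True, order=True)
class FractionationScheme:
    """A treatment course of ``n_fractions`` equal fractions."""

    n_fractions: int

    def __post_init__(self) -> None:
        if not isinstance(self.n_fractions, int) or isinstance(self.n_fractions, bool):
            raise TypeError(f"n_fractions must be an integer, got {self.n_fractions!r}")
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions}")


@dataclass(frozen=True)
class LQParameters:
    """Tissue-specific LQ parameters (only the alpha/beta ratio is needed)."""

    alpha_beta: float = DEFAULT_ALPHA_BETA

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha_beta) or self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta}")


@dataclass(frozen=True)
class TotalDose:
    """An RBE-weighted total dose in Gy (RBE), tagged with its RBE model and scheme."""

    value: float
    model_tag: str
    scheme: FractionationScheme

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"dose value must be >= 0, got {self.value}")
        if self.model_tag not in RBE_MODELS:
            raise ValueError(
                f"model_tag must be one of {RBE_MODELS}, got {self.model_tag!r}"
            )

    @property
    def dose_per_fraction(self) -> float:
        return self.value / self.scheme.n_fractions


def bed(dose: TotalDose, lq: LQParameters) -> float:
    """Biologically effective dose N*d*(1 + d/(alpha/beta)) in Gy.

    Strictly increasing in ``dose.value``; zero iff the dose is zero.
    """
    d = dose.dose_per_fraction
    return dose.value * (1.0 + d / lq.alpha_beta)


def isoeffect_total_dose(
    dose_from: TotalDose,
    scheme_to: FractionationScheme,
    lq: LQParameters,
) -> TotalDose:
    """Total dose at ``scheme_to`` with the same BED as ``dose_from``.

    The per-fraction dose is the positive root

        d2 = (-(a/b) + sqrt((a/b)^2 + 4*(a/b)*BED/N2)) / 2

    and the returned total dose is ``N2 * d2``.  The RBE-model tag is
    preserved: LQ rescaling never changes the dose-reporting model.
    Equal schemes return the input dose bit-exactly.
    """
    if scheme_to == dose_from.scheme:
        return dose_from
    ab = lq.alpha_beta
    b = bed(dose_from, lq)
    n2 = scheme_to.n_fractions
    d2 = (-ab + math.sqrt(ab * ab + 4.0 * ab * b / n2)) / 2.0
    return TotalDose(value=n2 * d2, model_tag=dose_from.model_tag, scheme=scheme_to)


def isoeffect_value(
    value: float,
    n_from: int,
    n_to: int,
    alpha_beta: float = DEFAULT_ALPHA_BETA,
) -> float:
    """Convenience scalar form of :func:`isoeffect_total_dose`."""
    dose = TotalDose(value, "LEM", FractionationScheme(n_from))
    return isoeffect_total_dose(
        dose, FractionationScheme(n_to), LQParameters(alpha_beta)
    ).value
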