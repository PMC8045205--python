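"""Packaged constraint sets and conversion-curve fixtures.

The 16-fraction curve merges every published forward (MKM -> LEM) pair with
the published backward pairs into one 7-anchor monotone curve; it is the
best available public approximation of the underlying model.

The 12/8/4-fraction "reconstructed" curves are different in kind: their MKM
anchor positions are obtained by LQ-rescaling the published 16-fraction MKM
values, and their LEM anchor values are the published outputs of the
MKM-then-LQ conversion chain.  They therefore reproduce those published
outputs *by construction* and are packaged as demonstrations, not as
independent evidence about the curve shapes.
"""

from __future__ import annotations

from functools import lru_cache

from .constraints import ConstraintSet, DoseConstraint
from .curve import ConversionCurve, build_curve
from .lq import DEFAULT_ALPHA_BETA, LQParameters, isoeffect_value

__all__ = [
    "constraint_set",
    "curve",
    "CONSTRAINT_SET_NAMES",
    "CURVE_NAMES",
]

# ---------------------------------------------------------------------- #
# Constraint sets (all limits in Gy (RBE))

_CONSTRAINT_SETS: dict[str, tuple[str, list[tuple[str, float]], int]] = {
    # NIRS percent-volume MKM set used for 16-fraction courses
    "nirs-16fx": ("MKM", [("D20%", 28.80), ("D10%", 46.40), ("D5%", 56.00), ("D0%", 60.80)], 16),
    # the variant of the NIRS set as cited by CNAO (D5% and D1% differ)
    "nirs-16fx-cnao-cited": ("MKM", [("D20%", 28.80), ("D10%", 46.40), ("D5%", 60.00), ("D1%", 66.00)], 16),
    # CNAO absolute-volume LEM set
    "cnao-16fx": ("LEM", [("D10cc", 54.00), ("D5cc", 61.00), ("D1cc", 66.00)], 16),
    # percent-volume LEM set (NIRS set mapped through the 16-fraction curve)
    "center-lem-16fx": ("LEM", [("D20%", 43.14), ("D10%", 58.48), ("D5%", 65.11), ("D0%", 68.33)], 16),
}

CONSTRAINT_SET_NAMES = tuple(_CONSTRAINT_SETS)


def constraint_set(name: str) -> ConstraintSet:
    """Return a packaged constraint set by name (see ``CONSTRAINT_SET_NAMES``)."""
    try:
        model, rows, n = _CONSTRAINT_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown constraint set {name!r}; available: {CONSTRAINT_SET_NAMES}"
        ) from None
    return ConstraintSet(
        name, [DoseConstraint.from_label(lbl, lim, model, n) for lbl, lim in rows]
    )


# ---------------------------------------------------------------------- #
# Conversion curves

# 16-fraction anchors: four forward pairs plus three backward pairs, jointly
# strictly monotone.
_ANCHORS_16FX = [
    (28.80, 43.14),
    (39.99, 54.00),
    (46.40, 58.48),
    (49.84, 61.00),
    (56.00, 65.11),
    (57.31, 66.00),
    (60.80, 68.33),
]

# 12-fraction pairs published alongside an external 12-fraction protocol:
# a 10 cc limit (80% of the 51.6 Gy (RBE) prescription) and the
# prescription itself.
_ANCHORS_12FX_PUBLISHED = [
    (41.28, 49.00),
    (51.60, 55.71),
]

# Published outputs of the MKM-then-LQ chain at each target scheme, keyed by
# the 16-fraction MKM value they originate from (percent-volume sources and
# backward-converted absolute-volume sources interleaved).
_MKM_SOURCES_16FX = [28.80, 39.99, 46.40, 49.84, 56.00, 57.31, 60.80]
_MKM_LQ_OUTPUTS = {
    12: [37.60, 45.97, 49.74, 51.70, 55.27, 55.97, 58.01],
    8: [30.40, 36.53, 39.25, 40.73, 43.41, 43.97, 45.46],
    4: [20.80, 23.94, 25.66, 26.62, 28.33, 28.67, 29.64],
}


@lru_cache(maxsize=None)
def _reconstructed_curve(n_fractions: int, alpha_beta: float) -> ConversionCurve:
    outputs = _MKM_LQ_OUTPUTS[n_fractions]
    anchors = [
        (isoeffect_value(mkm, 16, n_fractions, alpha_beta), lem)
        for mkm, lem in zip(_MKM_SOURCES_16FX, outputs)
    ]
    return build_curve(anchors, scheme_label=f"{n_fractions}fx-reconstructed")


CURVE_NAMES = (
    "16fx",
    "12fx-published",
    "12fx-reconstructed",
    "8fx-reconstructed",
    "4fx-reconstructed",
)


def curve(name: str, lq: LQParameters | None = None) -> ConversionCurve:
    """Return a packaged conversion curve by name (see ``CURVE_NAMES``).

    Reconstructed curves depend on the alpha/beta ratio used for the LQ
    anchor positions; pass ``lq`` to override the default 3.9 Gy.
    """
    ab = (lq or LQParameters(DEFAULT_ALPHA_BETA)).alpha_beta
    if name == "16fx":
        return build_curve(_ANCHORS_16FX, scheme_label="16fx")
    if name == "12fx-published":
        return build_curve(_ANCHORS_12FX_PUBLISHED, scheme_label="12fx-published")
    if name.endswith("-reconstructed"):
        try:
            n = int(name.split("fx", 1)[0])
            return _reconstructed_curve(n, ab)
        except (ValueError, KeyError):
            pass
    raise KeyError(f"unknown curve {name!r}; available: {CURVE_NAMES}")


def default_curves(lq: LQParameters | None = None) -> dict[int, ConversionCurve]:
    """Scheme -> curve mapping used by the CLI when none is supplied."""
    return {
        16: curve("16fx"),
        12: curve("12fx-reconstructed", lq),
        8: curve("8fx-reconstructed", lq),
        4: curve("4fx-reconstructed", lq),
    }
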