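"""Monotone dose-conversion curves between MKM- and LEM-reported doses.

A :class:`ConversionCurve` is an anchor-interpolated, strictly increasing
mapping from MKM RBE-weighted total dose to LEM RBE-weighted total dose for
one fractionation scheme.  The inverse direction is evaluated by bracketed
root-finding on the forward interpolant, so forward and inverse always agree
to the bisection tolerance regardless of the interpolation method chosen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "CurveAnchor",
    "ConversionCurve",
    "CurveDomainError",
    "CurveMonotonicityError",
    "ExtrapolationWarning",
    "build_curve",
    "read_curve_csv",
    "write_curve_csv",
]

INTERPOLATION_METHODS = ("monotone-cubic", "piecewise-linear")
EXTRAPOLATION_POLICIES = ("error", "linear-tail-with-warning")

#: Fraction of the anchor span tolerated beyond either end under the
#: linear-tail policy.
_TAIL_FRACTION = 0.10

#: Absolute dose tolerance of the inverse bisection, Gy (RBE).
_INVERSE_TOL = 1e-9


class CurveMonotonicityError(ValueError):
    """Anchor set is not jointly strictly increasing."""


class CurveDomainError(ValueError):
    """Requested dose lies outside the curve's (policy-extended) domain."""


class ExtrapolationWarning(UserWarning):
    """Emitted when the linear tail beyond the anchor range is used."""


@dataclass(frozen=True)
class CurveAnchor:
    """One (MKM dose, LEM dose) pair in Gy (RBE)."""

    mkm_dose: float
    lem_dose: float

    def __post_init__(self) -> None:
        for name, v in (("mkm_dose", self.mkm_dose), ("lem_dose", self.lem_dose)):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


class ConversionCurve:
    """Strictly monotone MKM <-> LEM dose mapping for one fractionation scheme.

    Parameters
    ----------
    anchors
        At least two (MKM, LEM) pairs, jointly strictly increasing after
        sorting by MKM dose.
    scheme_label
        Free-text label of the fractionation scheme the curve was built for
        (e.g. ``"16fx"``).
    interpolation_method
        ``"monotone-cubic"`` (shape-preserving PCHIP, default) or
        ``"piecewise-linear"``.
    extrapolation_policy
        ``"linear-tail-with-warning"`` (default) extends the end segments
        linearly for up to 10% of the anchor span and warns;
        ``"error"`` raises :class:`CurveDomainError` outside the anchors.
    """

    def __init__(
        self,
        anchors: Iterable[CurveAnchor],
        scheme_label: str = "",
        interpolation_method: str = "monotone-cubic",
        extrapolation_policy: str = "linear-tail-with-warning",
    ) -> None:
        if interpolation_method not in INTERPOLATION_METHODS:
            raise ValueError(f"unknown interpolation method {interpolation_method!r}")
        if extrapolation_policy not in EXTRAPOLATION_POLICIES:
            raise ValueError(f"unknown extrapolation policy {extrapolation_policy!r}")
        anchors = sorted(anchors, key=lambda a: a.mkm_dose)
        if len(anchors) < 2:
            raise ValueError(f"need at least 2 anchors, got {len(anchors)}")
        for prev, cur in zip(anchors, anchors[1:]):
            if cur.mkm_dose <= prev.mkm_dose or cur.lem_dose <= prev.lem_dose:
                raise CurveMonotonicityError(
                    "anchors must be jointly strictly increasing; offending pair: "
                    f"({prev.mkm_dose}, {prev.lem_dose}) -> "
                    f"({cur.mkm_dose}, {cur.lem_dose})"
                )
        self.anchors: tuple[CurveAnchor, ...] = tuple(anchors)
        self.scheme_label = scheme_label
        self.interpolation_method = interpolation_method
        self.extrapolation_policy = extrapolation_policy

        self._mkm = np.array([a.mkm_dose for a in anchors], dtype=float)
        self._lem = np.array([a.lem_dose for a in anchors], dtype=float)
        if interpolation_method == "monotone-cubic":
            self._interp = PchipInterpolator(self._mkm, self._lem, extrapolate=False)
        else:
            self._interp = None
        # end-segment slopes used by the linear tails
        self._lo_slope = (self._lem[1] - self._lem[0]) / (self._mkm[1] - self._mkm[0])
        self._hi_slope = (self._lem[-1] - self._lem[-2]) / (
            self._mkm[-1] - self._mkm[-2]
        )

    # ------------------------------------------------------------------ #

    @property
    def domain(self) -> tuple[float, float]:
        """MKM dose range covered by the anchors."""
        return float(self._mkm[0]), float(self._mkm[-1])

    @property
    def image(self) -> tuple[float, float]:
        """LEM dose range covered by the anchors."""
        return float(self._lem[0]), float(self._lem[-1])

    def _eval_in_domain(self, dose: float) -> float:
        if self._interp is not None:
            return float(self._interp(dose))
        return float(np.interp(dose, self._mkm, self._lem))

    def mkm_to_lem(self, dose: float) -> float:
        """Map an MKM-reported dose to the LEM-reported dose, Gy (RBE)."""
        lo, hi = self.domain
        if lo <= dose <= hi:
            return self._eval_in_domain(dose)
        span = hi - lo
        tail = _TAIL_FRACTION * span
        if self.extrapolation_policy == "error" or not (
            lo - tail <= dose <= hi + tail
        ):
            raise CurveDomainError(
                f"MKM dose {dose:g} Gy (RBE) outside curve domain "
                f"[{lo:g}, {hi:g}] (policy={self.extrapolation_policy})"
            )
        warnings.warn(
            f"MKM dose {dose:g} Gy (RBE) outside anchor range [{lo:g}, {hi:g}]; "
            "using linear tail",
            ExtrapolationWarning,
            stacklevel=2,
        )
        if dose < lo:
            return float(self._lem[0] + self._lo_slope * (dose - lo))
        return float(self._lem[-1] + self._hi_slope * (dose - hi))

    def lem_to_mkm(self, dose: float) -> float:
        """Inverse mapping, by bracketed root-finding on the forward curve."""
        ilo, ihi = self.image
        if ilo <= dose <= ihi:
            # anchor shortcut keeps anchors bit-exact under inversion
            hit = np.nonzero(self._lem == dose)[0]
            if hit.size:
                return float(self._mkm[hit[0]])
            root = brentq(
                lambda x: self._eval_in_domain(x) - dose,
                self._mkm[0],
                self._mkm[-1],
                xtol=_INVERSE_TOL,
            )
            return float(root)
        span = ihi - ilo
        tail = _TAIL_FRACTION * (self.domain[1] - self.domain[0])
        if self.extrapolation_policy == "error":
            raise CurveDomainError(
                f"LEM dose {dose:g} Gy (RBE) outside curve image [{ilo:g}, {ihi:g}] "
                "(policy=error)"
            )
        if dose < ilo:
            x = self.domain[0] + (dose - ilo) / self._lo_slope
        else:
            x = self.domain[1] + (dose - ihi) / self._hi_slope
        if not (self.domain[0] - tail <= x <= self.domain[1] + tail):
            raise CurveDomainError(
                f"LEM dose {dose:g} Gy (RBE) too far outside curve image "
                f"[{ilo:g}, {ihi:g}]"
            )
        warnings.warn(
            f"LEM dose {dose:g} Gy (RBE) outside anchor range [{ilo:g}, {ihi:g}]; "
            "using linear tail",
            ExtrapolationWarning,
            stacklevel=2,
        )
        return float(x)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.domain
        return (
            f"ConversionCurve({self.scheme_label!r}, {len(self.anchors)} anchors, "
            f"domain=[{lo:g}, {hi:g}], {self.interpolation_method})"
        )


def build_curve(
    anchors: Sequence[CurveAnchor | tuple[float, float]],
    method: str = "monotone-cubic",
    policy: str = "linear-tail-with-warning",
    scheme_label: str = "",
) -> ConversionCurve:
    """Validate anchors and construct a :class:`ConversionCurve`.

    Bare ``(mkm, lem)`` tuples are accepted in place of anchors.
    """
    normalized = [
        a if isinstance(a, CurveAnchor) else CurveAnchor(*a) for a in anchors
    ]
    return ConversionCurve(
        normalized,
        scheme_label=scheme_label,
        interpolation_method=method,
        extrapolation_policy=policy,
    )


# ---------------------------------------------------------------------- #
# CSV dialect: comment line "# scheme=<label>", header
# "mkm_dose_gy_rbe,lem_dose_gy_rbe", one anchor per row.

_CURVE_HEADER = "mkm_dose_gy_rbe,lem_dose_gy_rbe"


def write_curve_csv(curve: ConversionCurve, path: str | Path) -> None:
    lines = [f"# scheme={curve.scheme_label}", _CURVE_HEADER]
    lines += [f"{a.mkm_dose:.6g},{a.lem_dose:.6g}" for a in curve.anchors]
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve_csv(
    path: str | Path,
    method: str = "monotone-cubic",
    policy: str = "linear-tail-with-warning",
) -> ConversionCurve:
    scheme_label = ""
    anchors: list[CurveAnchor] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("scheme="):
                scheme_label = body.split("=", 1)[1].strip()
            continue
        if not header_seen:
            if line.replace(" ", "") != _CURVE_HEADER:
                raise ValueError(
                    f"{path}:{lineno}: expected header {_CURVE_HEADER!r}, got {line!r}"
                )
            header_seen = True
            continue
        fields = line.split(",")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        anchors.append(CurveAnchor(float(fields[0]), float(fields[1])))
    if not header_seen:
        raise ValueError(f"{path}: missing header line {_CURVE_HEADER!r}")
    return build_curve(anchors, method=method, policy=policy, scheme_label=scheme_label)
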