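"""Dose-constraint types and their CSV/JSON file dialects.

A :class:`DoseConstraint` is a single dose limit in Gy (RBE) at a volume
parameter, expressed either as a relative volume (percent-volume metrics
such as D20%; ``volume_param`` is the fraction in [0, 1], with 0 meaning
D0%, the near-maximum dose) or as an absolute volume in cc (D_10cc style
metrics).  Constraints carry the RBE model and fractionation scheme they
apply to.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .lq import RBE_MODELS, FractionationScheme

__all__ = [
    "DoseConstraint",
    "ConstraintSet",
    "parse_metric_label",
    "read_constraints_csv",
    "write_constraints_csv",
    "read_constraints_json",
    "write_constraints_json",
]

METRIC_KINDS = ("percent-volume", "absolute-volume")

_LABEL_RE = re.compile(r"^D\s*_?\s*(\d+(?:\.\d+)?)\s*(%|cc)_?$", re.IGNORECASE)


def parse_metric_label(label: str) -> tuple[str, float]:
    """Parse a metric label like ``"D20%"`` or ``"D_10cc"``.

    Returns ``(metric_kind, volume_param)`` where percent labels yield a
    fraction in [0, 1] and cc labels yield the absolute volume in cc.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse metric label {label!r} (expected DX% or DXcc)")
    value, unit = float(m.group(1)), m.group(2).lower()
    if unit == "%":
        if value > 100:
            raise ValueError(f"percent volume > 100 in label {label!r}")
        return "percent-volume", value / 100.0
    if value <= 0:
        raise ValueError(f"absolute volume must be > 0 in label {label!r}")
    return "absolute-volume", value


@dataclass(frozen=True)
class DoseConstraint:
    """One dose limit at a volume parameter, tagged with RBE model and scheme."""

    label: str
    metric_kind: str
    volume_param: float
    limit: float
    model_tag: str
    scheme: FractionationScheme

    def __post_init__(self) -> None:
        if self.metric_kind not in METRIC_KINDS:
            raise ValueError(f"metric_kind must be one of {METRIC_KINDS}")
        if not math.isfinite(self.limit) or self.limit <= 0:
            raise ValueError(f"limit must be > 0, got {self.limit}")
        if self.model_tag not in RBE_MODELS:
            raise ValueError(f"model_tag must be one of {RBE_MODELS}")
        if self.metric_kind == "percent-volume":
            if not 0.0 <= self.volume_param <= 1.0:
                raise ValueError(
                    f"percent-volume parameter must be in [0, 1], got {self.volume_param}"
                )
        elif self.volume_param <= 0:
            raise ValueError(
                f"absolute-volume parameter must be > 0 cc, got {self.volume_param}"
            )

    @classmethod
    def from_label(
        cls,
        label: str,
        limit: float,
        model_tag: str,
        n_fractions: int,
    ) -> "DoseConstraint":
        kind, param = parse_metric_label(label)
        return cls(label, kind, param, limit, model_tag, FractionationScheme(n_fractions))

    def with_limit(
        self, limit: float, model_tag: str | None = None,
        scheme: FractionationScheme | None = None,
    ) -> "DoseConstraint":
        return replace(
            self,
            limit=limit,
            model_tag=model_tag or self.model_tag,
            scheme=scheme or self.scheme,
        )


class ConstraintSet:
    """A named, ordered collection of constraints sharing model tag and scheme."""

    def __init__(self, name: str, constraints: Iterable[DoseConstraint]) -> None:
        constraints = tuple(constraints)
        if constraints:
            tags = {c.model_tag for c in constraints}
            schemes = {c.scheme for c in constraints}
            if len(tags) > 1 or len(schemes) > 1:
                raise ValueError(
                    f"constraint set {name!r} mixes model tags {tags} or schemes {schemes}"
                )
        self.name = name
        self.constraints = constraints

    @property
    def model_tag(self) -> str | None:
        return self.constraints[0].model_tag if self.constraints else None

    @property
    def scheme(self) -> FractionationScheme | None:
        return self.constraints[0].scheme if self.constraints else None

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self) -> int:
        return len(self.constraints)

    def __getitem__(self, key: int | str) -> DoseConstraint:
        if isinstance(key, str):
            for c in self.constraints:
                if c.label == key:
                    return c
            raise KeyError(key)
        return self.constraints[key]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ConstraintSet({self.name!r}, {len(self.constraints)} constraints)"


# ---------------------------------------------------------------------- #
# File dialects

_CSV_HEADER = "label,metric_kind,volume_param,limit_gy_rbe,model,n_fractions"


def _constraint_to_row(c: DoseConstraint) -> dict:
    return {
        "label": c.label,
        "metric_kind": c.metric_kind,
        "volume_param": c.volume_param,
        "limit_gy_rbe": c.limit,
        "model": c.model_tag,
        "n_fractions": c.scheme.n_fractions,
    }


def _constraint_from_row(row: dict) -> DoseConstraint:
    return DoseConstraint(
        label=str(row["label"]),
        metric_kind=str(row["metric_kind"]),
        volume_param=float(row["volume_param"]),
        limit=float(row["limit_gy_rbe"]),
        model_tag=str(row["model"]),
        scheme=FractionationScheme(int(row["n_fractions"])),
    )


def write_constraints_csv(cset: ConstraintSet, path: str | Path) -> None:
    lines = [f"# name={cset.name}", _CSV_HEADER]
    for c in cset:
        r = _constraint_to_row(c)
        lines.append(
            f"{r['label']},{r['metric_kind']},{r['volume_param']:g},"
            f"{r['limit_gy_rbe']:g},{r['model']},{r['n_fractions']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraints_csv(path: str | Path) -> ConstraintSet:
    name = Path(path).stem
    rows: list[DoseConstraint] = []
    header: Sequence[str] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("name="):
                name = body.split("=", 1)[1].strip()
            continue
        fields = [f.strip() for f in line.split(",")]
        if header is None:
            header = fields
            expected = _CSV_HEADER.split(",")
            if fields != expected:
                raise ValueError(f"{path}:{lineno}: expected header {expected}")
            continue
        if len(fields) != len(header):
            raise ValueError(f"{path}:{lineno}: wrong number of columns")
        rows.append(_constraint_from_row(dict(zip(header, fields))))
    if header is None:
        raise ValueError(f"{path}: missing header")
    return ConstraintSet(name, rows)


def write_constraints_json(cset: ConstraintSet, path: str | Path) -> None:
    payload = {"name": cset.name, "constraints": [_constraint_to_row(c) for c in cset]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_constraints_json(path: str | Path) -> ConstraintSet:
    payload = json.loads(Path(path).read_text())
    return ConstraintSet(
        payload.get("name", Path(path).stem),
        [_constraint_from_row(r) for r in payload["constraints"]],
    )
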