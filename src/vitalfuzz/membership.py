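"""Piecewise-linear membership functions and fuzzification of vital readings.

Each linguistic label of each vital carries a triangular or trapezoidal
membership function over the vital's unit axis.  Fuzzification evaluates all
of a vital's label functions at a crisp reading, yielding a degree in [0, 1]
per label; the gradual overlap between neighbouring labels is what the
downstream Mamdani rule engine consumes.

Two built-in parameter sets ship:

``as_printed``
    The literature parameter listing this system reproduces, with one
    ordering repair (the oxygen Worrisome breakpoints arrive as
    (85, 90, 95, 93), violating c <= d; they are stored as (85, 90, 93, 95)).
    Its temperature triangles live on a rescaled axis (apexes at 0/20/30)
    and do not cover physiologic degC readings, so it is kept for fidelity
    rather than everyday use.

``range_consistent`` (default)
    Trapezoids built from the crisp range table: each label's plateau equals
    its crisp interval, with 2-unit linear shoulders extending past each
    printed interval end, giving the gradual transitions the crisp table
    cannot express while agreeing with it away from boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

from .core import (
    VITAL_ORDER,
    VOCABULARY,
    InvalidInputError,
    RangeTable,
    VitalKind,
    VitalSample,
    default_range_table,
)

#: Sentinel for plateaus that extend indefinitely to the right.
_UNBOUNDED = 1e9


class InvalidFunctionError(ValueError):
    """Raised when membership breakpoints are not monotonically ordered."""


@dataclass(frozen=True)
class MembershipFunction:
    """A triangular or trapezoidal membership function.

    Trapezoid: zero outside [a, d], linear rise on [a, b], plateau 1 on
    [b, c], linear fall on [c, d].  Triangle: a trapezoid with b == c (apex).
    Degenerate vertical edges (a == b or c == d) evaluate to the plateau
    value at the shared point, so e.g. trapezoid(0, 0, 60, 90) is 1 at 0.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise InvalidFunctionError(
                f"breakpoints must satisfy a <= b <= c <= d, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )

    @classmethod
    def triangular(cls, a: float, b: float, c: float) -> "MembershipFunction":
        return cls(a, b, b, c)

    @classmethod
    def trapezoidal(cls, a: float, b: float, c: float, d: float) -> "MembershipFunction":
        return cls(a, b, c, d)

    @property
    def shape(self) -> str:
        return "triangular" if self.b == self.c else "trapezoidal"

    def __call__(self, x: float) -> float:
        return eval_membership(self, x)


def eval_membership(mf: MembershipFunction, x: float) -> float:
    """Degree of membership of ``x`` in ``mf``, in [0, 1]."""
    a, b, c, d = mf.a, mf.b, mf.c, mf.d
    if b <= x <= c:
        return 1.0
    if x < b:
        if x < a or a == b:
            return 0.0 if x < a else 1.0
        return (x - a) / (b - a)
    # x > c
    if x > d or c == d:
        return 0.0 if x > d else 1.0
    return (d - x) / (d - c)


@dataclass(frozen=True)
class FuzzySystemConfig:
    """A complete membership-function assignment: per vital, label -> function."""

    paramset_name: str
    functions: Mapping[VitalKind, Mapping[str, MembershipFunction]]

    def __post_init__(self) -> None:
        for kind in VITAL_ORDER:
            labels = set(self.functions.get(kind, {}))
            expected = set(VOCABULARY[kind])
            if labels != expected:
                raise ValueError(
                    f"{kind.value}: expected functions for {sorted(expected)}, got {sorted(labels)}"
                )

    def to_json(self) -> str:
        payload = {
            kind.value: {
                label: {"shape": mf.shape, "a": mf.a, "b": mf.b, "c": mf.c, "d": mf.d}
                for label, mf in self.functions[kind].items()
            }
            for kind in VITAL_ORDER
        }
        return json.dumps({"paramset_name": self.paramset_name, "functions": payload}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FuzzySystemConfig":
        raw = json.loads(text)
        functions = {
            VitalKind(kind): {
                label: MembershipFunction(p["a"], p["b"], p["c"], p["d"])
                for label, p in labels.items()
            }
            for kind, labels in raw["functions"].items()
        }
        return cls(raw["paramset_name"], functions)


@dataclass(frozen=True)
class FuzzifiedSample:
    """Per-vital membership degrees for one sample."""

    degrees: Mapping[VitalKind, Mapping[str, float]]
    source: VitalSample

    def degree(self, kind: VitalKind, label: str) -> float:
        return self.degrees[kind][label]


# The as-printed parameter listing (see module docstring for the two
# documented repairs).
_AS_PRINTED: dict[VitalKind, dict[str, MembershipFunction]] = {
    VitalKind.blood_pressure: {
        "Low": MembershipFunction(0, 0, 60, 90),
        "Normal": MembershipFunction(80, 90, 100, 120),
        "Elevated": MembershipFunction(110, 120, 130, 140),
        "High": MembershipFunction(130, 140, 200, 200),
    },
    VitalKind.temperature: {
        "Low": MembershipFunction.triangular(0, 0, 17),
        "Normal": MembershipFunction.triangular(15, 20, 25),
        "High": MembershipFunction.triangular(23, 30, 40),
    },
    VitalKind.glucose: {
        "Low": MembershipFunction(0, 0, 40, 70),
        "Normal": MembershipFunction(50, 70, 90, 100),
        "Elevated": MembershipFunction(90, 100, 120, 125),
        "High": MembershipFunction(120, 125, 200, 200),
    },
    VitalKind.heart_rate: {
        "Low": MembershipFunction(0, 0, 90, 109),
        "Normal": MembershipFunction(100, 110, 145, 155),
        "High": MembershipFunction(150, 156, 200, 200),
    },
    VitalKind.oxygen_saturation: {
        "Critical": MembershipFunction(0, 0, 80, 89),
        # printed as (85, 90, 95, 93); c and d swapped to restore ordering
        "Worrisome": MembershipFunction(85, 90, 93, 95),
        "Normal": MembershipFunction(92, 94, 100, 100),
    },
}

#: Width (in each vital's unit) of the linear shoulders added around the
#: crisp interval ends when building the range_consistent parameter set.
DEFAULT_SHOULDER = 2.0


def _range_consistent(table: RangeTable, shoulder: float) -> dict[VitalKind, dict[str, MembershipFunction]]:
    out: dict[VitalKind, dict[str, MembershipFunction]] = {}
    for kind in VITAL_ORDER:
        rows = table.ranges[kind]
        funcs: dict[str, MembershipFunction] = {}
        for i, (lo, hi, label) in enumerate(rows):
            if i == 0:
                a, b = 0.0, 0.0
            else:
                a, b = lo - shoulder, lo + 0.0
            if hi is None:
                c, d = _UNBOUNDED, _UNBOUNDED
            else:
                c, d = float(hi), hi + shoulder
            funcs[label] = MembershipFunction(max(a, -shoulder), b, c, d)
        out[kind] = funcs
    return out


def builtin_paramset(
    name: str = "range_consistent",
    table: RangeTable | None = None,
    shoulder: float = DEFAULT_SHOULDER,
) -> FuzzySystemConfig:
    """Return one of the shipped membership parameter sets by name."""
    if name == "as_printed":
        return FuzzySystemConfig("as_printed", _AS_PRINTED)
    if name == "range_consistent":
        if table is None:
            table = default_range_table()
        return FuzzySystemConfig("range_consistent", _range_consistent(table, shoulder))
    raise ValueError(f"unknown parameter set {name!r}; choose 'as_printed' or 'range_consistent'")


def fuzzify_value(value: float, kind: VitalKind, cfg: FuzzySystemConfig) -> dict[str, float]:
    """Membership degree of ``value`` in every label of ``kind``."""
    import math

    if not math.isfinite(value):
        raise InvalidInputError(f"{kind.value} value must be finite, got {value!r}")
    if kind not in cfg.functions:
        raise InvalidInputError(f"unknown vital {kind!r}")
    return {label: eval_membership(mf, value) for label, mf in cfg.functions[kind].items()}


def fuzzify_sample(sample: VitalSample, cfg: FuzzySystemConfig) -> FuzzifiedSample:
    """Fuzzify all five vitals of one sample."""
    degrees = {
        kind: fuzzify_value(sample.value(kind), kind, cfg) for kind in VITAL_ORDER
    }
    return FuzzifiedSample(degrees=degrees, source=sample)
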