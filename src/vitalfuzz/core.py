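"""Domain types, crisp range classification, record cleaning and unit conversion.

The five monitored vitals are body temperature (degC), heart rate (bpm),
peripheral oxygen saturation (SpO2, %), systolic blood pressure (mmHg) and
blood glucose (mg/dL).  Each vital has a small vocabulary of linguistic
labels (e.g. blood pressure: Low / Normal / Elevated / High) together with a
crisp range table assigning every non-negative reading to exactly one label.
Intervals are closed on their lower bound; the top interval of each vital is
unbounded above ("X and above").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

#: Conversion factor mmol/L -> mg/dL for glucose (molar mass 180.16 g/mol).
MMOL_TO_MGDL = 18.016


class VitalKind(str, Enum):
    """The five monitored vital signs, in canonical order."""

    temperature = "temperature"
    heart_rate = "heart_rate"
    oxygen_saturation = "oxygen_saturation"
    blood_pressure = "blood_pressure"
    glucose = "glucose"


#: Canonical ordering used everywhere a per-vital vector appears.
VITAL_ORDER: tuple[VitalKind, ...] = (
    VitalKind.temperature,
    VitalKind.heart_rate,
    VitalKind.oxygen_saturation,
    VitalKind.blood_pressure,
    VitalKind.glucose,
)

#: Linguistic vocabulary per vital, ordered from lowest to highest reading.
VOCABULARY: dict[VitalKind, tuple[str, ...]] = {
    VitalKind.temperature: ("Low", "Normal", "High"),
    VitalKind.heart_rate: ("Low", "Normal", "High"),
    VitalKind.oxygen_saturation: ("Critical", "Worrisome", "Normal"),
    VitalKind.blood_pressure: ("Low", "Normal", "Elevated", "High"),
    VitalKind.glucose: ("Low", "Normal", "Elevated", "High"),
}


class InvalidInputError(ValueError):
    """Raised for non-finite, negative or otherwise unusable inputs."""


@dataclass(frozen=True)
class VitalSample:
    """One timestamped five-vital measurement for one patient.

    Missing readings are represented as NaN and rejected by
    :func:`clean_records`.
    """

    patient_id: str
    timestamp: float
    temperature: float
    heart_rate: float
    oxygen_saturation: float
    blood_pressure: float
    glucose: float

    def value(self, kind: VitalKind) -> float:
        return getattr(self, kind.value)

    def values(self) -> tuple[float, ...]:
        """Vital readings in canonical order."""
        return tuple(self.value(k) for k in VITAL_ORDER)


@dataclass(frozen=True)
class RangeTable:
    """Crisp classification ranges per vital.

    For each vital an ordered list of ``(lower, upper, label)`` with the
    lower bound inclusive and ``upper is None`` for the unbounded top
    interval.  Intervals must be contiguous from 0 and labels must come from
    the vital's vocabulary.
    """

    ranges: Mapping[VitalKind, tuple[tuple[float, float | None, str], ...]]

    def __post_init__(self) -> None:
        for kind in VITAL_ORDER:
            if kind not in self.ranges:
                raise ValueError(f"range table missing vital {kind.value!r}")
            rows = self.ranges[kind]
            if rows[0][0] != 0:
                raise ValueError(f"{kind.value}: first interval must start at 0")
            if rows[-1][1] is not None:
                raise ValueError(f"{kind.value}: top interval must be unbounded")
            for (lo, hi, label), (nlo, _, _) in zip(rows, rows[1:]):
                if hi is None or not lo <= hi < nlo:
                    raise ValueError(f"{kind.value}: intervals not contiguous")
            for lo, hi, label in rows:
                if label not in VOCABULARY[kind]:
                    raise ValueError(f"{label!r} not valid for {kind.value}")

    def boundaries(self, kind: VitalKind) -> list[float]:
        """Inclusive lower bounds of each interval after the first."""
        return [lo for lo, _, _ in self.ranges[kind][1:]]


def default_range_table() -> RangeTable:
    """The shipped crisp ranges for adult diabetic monitoring.

    Temperature 0-34 Low / 35-38 Normal / 39+ High; blood pressure
    0-90 / 91-119 / 120-129 / 130+; heart rate 0-109 / 110-155 / 156+;
    glucose 0-69 / 70-100 / 101-124 / 125+; SpO2 0-89 Critical /
    90-93 Worrisome / 94+ Normal.
    """
    return RangeTable(
        {
            VitalKind.temperature: ((0, 34, "Low"), (35, 38, "Normal"), (39, None, "High")),
            VitalKind.heart_rate: ((0, 109, "Low"), (110, 155, "Normal"), (156, None, "High")),
            VitalKind.oxygen_saturation: (
                (0, 89, "Critical"),
                (90, 93, "Worrisome"),
                (94, None, "Normal"),
            ),
            VitalKind.blood_pressure: (
                (0, 90, "Low"),
                (91, 119, "Normal"),
                (120, 129, "Elevated"),
                (130, None, "High"),
            ),
            VitalKind.glucose: (
                (0, 69, "Low"),
                (70, 100, "Normal"),
                (101, 124, "Elevated"),
                (125, None, "High"),
            ),
        }
    )


def classify_vital(value: float, kind: VitalKind, table: RangeTable | None = None) -> str:
    """Return the crisp linguistic label whose interval contains ``value``.

    Intervals are closed on their printed lower bound, so e.g. a glucose
    reading of 100.5 (between the printed Normal top 100 and Elevated
    bottom 101) classifies as Normal.
    """
    if table is None:
        table = default_range_table()
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"{kind.value} value must be finite and >= 0, got {value!r}")
    rows = table.ranges[kind]
    label = rows[0][2]
    for lo, _, lab in rows:
        if value >= lo:
            label = lab
        else:
            break
    return label


def classify_sample(sample: VitalSample, table: RangeTable | None = None) -> tuple[str, ...]:
    """Crisp label per vital, in canonical order."""
    if table is None:
        table = default_range_table()
    labels = []
    for kind in VITAL_ORDER:
        try:
            labels.append(classify_vital(sample.value(kind), kind, table))
        except InvalidInputError as exc:
            raise InvalidInputError(f"sample {sample.patient_id!r}: {exc}") from exc
    return tuple(labels)


#: Open physical-plausibility intervals used by clean_records, beyond the
#: zero-reading rule.  SpO2 is closed at 100 (a valid saturation ceiling).
DEFAULT_PLAUSIBLE_BOUNDS: dict[VitalKind, tuple[float, float]] = {
    VitalKind.temperature: (25.0, 45.0),
    VitalKind.heart_rate: (20.0, 250.0),
    VitalKind.oxygen_saturation: (50.0, 100.0),
    VitalKind.blood_pressure: (40.0, 250.0),
    VitalKind.glucose: (20.0, 600.0),
}


@dataclass
class CleanReport:
    """Accounting of a cleaning pass over raw records."""

    n_input: int = 0
    n_dropped: int = 0
    n_retained: int = 0
    dropped_missing: int = 0
    dropped_impossible_value: int = 0
    dropped_out_of_physical_bounds: int = 0

    def check(self) -> None:
        assert self.n_input == self.n_dropped + self.n_retained
        assert (
            self.n_dropped
            == self.dropped_missing
            + self.dropped_impossible_value
            + self.dropped_out_of_physical_bounds
        )


def _plausible(value: float, kind: VitalKind, bounds: Mapping[VitalKind, tuple[float, float]]) -> bool:
    lo, hi = bounds[kind]
    if kind is VitalKind.oxygen_saturation:
        return lo < value <= hi
    return lo < value < hi


def clean_records(
    records: Iterable[VitalSample],
    bounds: Mapping[VitalKind, tuple[float, float]] | None = None,
) -> tuple[list[VitalSample], CleanReport]:
    """Drop records with missing, impossible (zero) or implausible readings.

    Sensor anomalies show up as physically impossible values — a body
    temperature of 0 cannot occur — or as blank cells.  A record is dropped
    if any vital is NaN (missing), exactly zero (impossible) or outside the
    plausibility bounds.  Retained records keep their input order; the
    report's counters reconcile with the input size.  Idempotent.
    """
    if bounds is None:
        bounds = DEFAULT_PLAUSIBLE_BOUNDS
    retained: list[VitalSample] = []
    report = CleanReport()
    for rec in records:
        report.n_input += 1
        vals = rec.values()
        if any(isinstance(v, float) and math.isnan(v) for v in vals) or any(
            v is None for v in vals
        ):
            report.n_dropped += 1
            report.dropped_missing += 1
        elif any(not math.isfinite(v) or v == 0 for v in vals):
            report.n_dropped += 1
            report.dropped_impossible_value += 1
        elif any(not _plausible(v, k, bounds) for k, v in zip(VITAL_ORDER, vals)):
            report.n_dropped += 1
            report.dropped_out_of_physical_bounds += 1
        else:
            retained.append(rec)
            report.n_retained += 1
    report.check()
    return retained, report


def mmol_to_mgdl(value: float) -> float:
    """Convert a glucose concentration from mmol/L to mg/dL (factor 18.016)."""
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"glucose concentration must be finite and >= 0, got {value!r}")
    return value * MMOL_TO_MGDL


def fahrenheit_to_celsius(value: float) -> float:
    """Convert deg F to deg C, for ingest of Fahrenheit temperature columns."""
    return (value - 32.0) * 5.0 / 9.0
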