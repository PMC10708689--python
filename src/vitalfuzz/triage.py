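"""Priority filtering of sensor telemetry.

Sensor packets arrive as a timestamp-ordered stream, one reading per packet.
Each packet is checked against a per-sensor normal band (Vmin, Vmax); an
out-of-range reading gets high priority and raises an alert.  The stream is
processed in fixed-size cycles (default 5 packets, one per sensor): within
each cycle all high-priority packets are transmitted first, FIFO among
themselves, followed by normal packets, FIFO.  Every packet is transmitted
every cycle — nothing is deferred or dropped — so the output is always a
permutation of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .core import VITAL_ORDER, VitalKind


@dataclass(frozen=True)
class NormalRangeTable:
    """Inclusive normal band (Vmin, Vmax) per sensor."""

    bands: Mapping[VitalKind, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [k.value for k in VITAL_ORDER if k not in self.bands]
        if missing:
            raise ValueError(f"missing normal bands for sensors: {missing}")
        for kind, (vmin, vmax) in self.bands.items():
            if not vmin < vmax:
                raise ValueError(f"{kind.value}: Vmin must be < Vmax, got ({vmin}, {vmax})")


def default_normal_ranges() -> NormalRangeTable:
    """Normal bands matching each vital's crisp Normal range."""
    return NormalRangeTable(
        {
            VitalKind.temperature: (35.0, 38.0),
            VitalKind.heart_rate: (110.0, 155.0),
            VitalKind.oxygen_saturation: (94.0, 100.0),
            VitalKind.blood_pressure: (91.0, 119.0),
            VitalKind.glucose: (70.0, 100.0),
        }
    )


@dataclass(frozen=True)
class DataPacket:
    """One sensor reading in flight."""

    sensor_id: VitalKind
    value: float
    timestamp: float
    priority: str = "normal"  # "normal" | "high"
    alert: bool = False
    sequence_index: int = 0

    def __post_init__(self) -> None:
        if self.alert and self.priority != "high":
            raise ValueError("an alerting packet must have high priority")


def check_out_of_range(value: float, sensor: VitalKind, ranges: NormalRangeTable) -> bool:
    """True iff ``value`` lies strictly outside the sensor's normal band."""
    if sensor not in ranges.bands:
        raise KeyError(f"unknown sensor {sensor!r}")
    vmin, vmax = ranges.bands[sensor]
    return value < vmin or value > vmax


def assign_priority(packet: DataPacket, ranges: NormalRangeTable) -> DataPacket:
    """Recompute priority/alert from the current value (idempotent)."""
    out = check_out_of_range(packet.value, packet.sensor_id, ranges)
    return replace(packet, priority="high" if out else "normal", alert=out)


@dataclass
class AlertEvent:
    """One out-of-range detection (the on-device beep, as a log record)."""

    sequence_index: int
    sensor_id: VitalKind
    value: float
    timestamp: float


@dataclass
class TriageQueue:
    """Latest-packet-per-sensor slots plus the drained transmission buffer."""

    slots: dict[VitalKind, DataPacket]
    transmitted: list[DataPacket]


def process_stream(
    readings: Sequence[DataPacket],
    ranges: NormalRangeTable | None = None,
    cycle_size: int = 5,
) -> tuple[list[DataPacket], list[AlertEvent]]:
    """Prioritize a timestamp-ordered packet stream in fixed-size cycles.

    Returns the transmission order (a permutation of the input) and the
    alert log (one event per out-of-range packet).  Raises ``ValueError``
    if timestamps are not non-decreasing or ``cycle_size < 1``.
    """
    if ranges is None:
        ranges = default_normal_ranges()
    if cycle_size < 1:
        raise ValueError("cycle_size must be >= 1")
    for prev, cur in zip(readings, readings[1:]):
        if cur.timestamp < prev.timestamp:
            raise ValueError(
                f"stream not timestamp-ordered: {cur.timestamp} after {prev.timestamp}"
            )

    prioritized = [
        replace(assign_priority(p, ranges), sequence_index=i)
        for i, p in enumerate(readings)
    ]
    alerts = [
        AlertEvent(p.sequence_index, p.sensor_id, p.value, p.timestamp)
        for p in prioritized
        if p.alert
    ]
    transmitted: list[DataPacket] = []
    for start in range(0, len(prioritized), cycle_size):
        cycle = prioritized[start : start + cycle_size]
        transmitted.extend(p for p in cycle if p.priority == "high")
        transmitted.extend(p for p in cycle if p.priority == "normal")
    return transmitted, alerts
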