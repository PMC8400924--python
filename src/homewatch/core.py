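"""Domain types and minute-resolution time arithmetic.

The whole package runs on a minute clock: periodic ambient channels
(temperature, humidity, pressure, light, gas level) are sampled once per
minute, and binary channels (motion, fire, gas presence, TV-remote IR,
shock) emit time-stamped events truncated to the minute.  Time-of-day
ranges are half-open ``[start, end)`` in minutes since midnight and never
wrap midnight; a schedule crossing midnight is expressed as two ranges.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

MINUTES_PER_DAY = 1440

#: Plausibility bounds enforced at ingestion, per channel.
VALUE_BOUNDS = {
    "temperature": (-20.0, 60.0),
    "humidity": (0.0, 100.0),
    "pressure": (800.0, 1200.0),
    "light": (0.0, 100.0),
    "gas_level": (0.0, float("inf")),
}


class SensorKind(str, Enum):
    """The ten sensor channels: five periodic, five event-triggered."""

    temperature = "temperature"
    humidity = "humidity"
    pressure = "pressure"
    light = "light"
    gas_level = "gas_level"
    motion = "motion"
    fire = "fire"
    gas_presence = "gas_presence"
    tv_remote = "tv_remote"
    shock = "shock"

    @property
    def is_periodic(self) -> bool:
        return self in PERIODIC_KINDS

    @property
    def is_event(self) -> bool:
        return self in EVENT_KINDS


PERIODIC_KINDS = frozenset(
    {SensorKind.temperature, SensorKind.humidity, SensorKind.pressure,
     SensorKind.light, SensorKind.gas_level}
)
EVENT_KINDS = frozenset(
    {SensorKind.motion, SensorKind.fire, SensorKind.gas_presence,
     SensorKind.tv_remote, SensorKind.shock}
)


@dataclass(frozen=True, order=True)
class TimeOfDay:
    """A clock time as integer minutes since midnight, in ``[0, 1440)``."""

    minute: int

    def __post_init__(self) -> None:
        if not 0 <= self.minute < MINUTES_PER_DAY:
            raise ValueError(f"minute-of-day out of range: {self.minute}")

    @classmethod
    def from_hhmm(cls, hour: int, minute: int = 0) -> "TimeOfDay":
        return cls(hour * 60 + minute)

    @classmethod
    def parse(cls, text: str) -> "TimeOfDay":
        h, m = text.split(":")
        return cls.from_hhmm(int(h), int(m))

    @classmethod
    def of(cls, ts: dt.datetime) -> "TimeOfDay":
        return cls(ts.hour * 60 + ts.minute)

    def __str__(self) -> str:
        return f"{self.minute // 60:02d}:{self.minute % 60:02d}"


@dataclass(frozen=True, order=True)
class TimeRange:
    """Half-open minute range ``[start, end_exclusive)``; never wraps midnight."""

    start: int
    end_exclusive: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end_exclusive <= MINUTES_PER_DAY):
            raise ValueError(
                f"invalid time range [{self.start}, {self.end_exclusive})"
            )

    @property
    def duration(self) -> int:
        return self.end_exclusive - self.start

    def __str__(self) -> str:
        end = self.end_exclusive
        end_str = "24:00" if end == MINUTES_PER_DAY else str(TimeOfDay(end))
        return f"{TimeOfDay(self.start)}-{end_str}"


def make_time_range(start_min: int, end_min: int) -> TimeRange:
    """Validated half-open range from integer minute endpoints."""
    return TimeRange(int(start_min), int(end_min))


def in_range(t: TimeOfDay | int, r: TimeRange) -> bool:
    """True iff ``start <= t < end_exclusive`` (half-open)."""
    m = t.minute if isinstance(t, TimeOfDay) else int(t)
    return r.start <= m < r.end_exclusive


def normalize_ranges(rs: Iterable[TimeRange]) -> list[TimeRange]:
    """Sort ranges and merge overlapping or adjacent ones.

    The result is pairwise disjoint with gaps of at least one minute, and
    covers exactly the union of the inputs.  Idempotent.
    """
    rs = sorted(rs)
    out: list[TimeRange] = []
    for r in rs:
        if out and r.start <= out[-1].end_exclusive:
            last = out.pop()
            out.append(TimeRange(last.start, max(last.end_exclusive, r.end_exclusive)))
        else:
            out.append(r)
    return out


def subtract_range(rs: Sequence[TimeRange], cut: TimeRange) -> list[TimeRange]:
    """Remove ``cut`` from a list of ranges, splitting where necessary."""
    out: list[TimeRange] = []
    for r in rs:
        if cut.end_exclusive <= r.start or cut.start >= r.end_exclusive:
            out.append(r)
            continue
        if r.start < cut.start:
            out.append(TimeRange(r.start, cut.start))
        if cut.end_exclusive < r.end_exclusive:
            out.append(TimeRange(cut.end_exclusive, r.end_exclusive))
    return out


@dataclass(frozen=True)
class PeriodicReading:
    """One sample of a periodic channel at minute resolution."""

    timestamp: dt.datetime
    sensor: SensorKind
    value: float

    def __post_init__(self) -> None:
        if self.sensor not in PERIODIC_KINDS:
            raise ValueError(f"{self.sensor} is not a periodic channel")

    @property
    def minute(self) -> int:
        return self.timestamp.hour * 60 + self.timestamp.minute


@dataclass(frozen=True)
class SensorEvent:
    """A binary-channel trigger at minute resolution."""

    timestamp: dt.datetime
    sensor: SensorKind

    def __post_init__(self) -> None:
        if self.sensor not in EVENT_KINDS:
            raise ValueError(f"{self.sensor} is not an event channel")

    @property
    def minute(self) -> int:
        return self.timestamp.hour * 60 + self.timestamp.minute


class Severity(str, Enum):
    alert = "alert"
    emergency = "emergency"


@dataclass(frozen=True)
class Alert:
    """An emitted notification: which rule fired, when, and how serious."""

    timestamp: dt.datetime
    rule_id: str
    severity: Severity
    message: str


@dataclass
class DailyTrace:
    """One calendar day of readings and events from a single home.

    Readings are sorted and strictly increasing per channel; events are
    sorted with ties allowed.  All timestamps share ``date``.
    """

    date: dt.date
    readings: list[PeriodicReading] = field(default_factory=list)
    events: list[SensorEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.readings:
            if rec.timestamp.date() != self.date:
                raise ValueError(f"reading {rec.timestamp} not on {self.date}")
        for ev in self.events:
            if ev.timestamp.date() != self.date:
                raise ValueError(f"event {ev.timestamp} not on {self.date}")
        self.readings.sort(key=lambda r: (r.timestamp, r.sensor.value))
        self.events.sort(key=lambda e: (e.timestamp, e.sensor.value))

    def events_of(self, sensor: SensorKind) -> list[SensorEvent]:
        return [e for e in self.events if e.sensor == sensor]

    def readings_of(self, sensor: SensorKind) -> list[PeriodicReading]:
        return [r for r in self.readings if r.sensor == sensor]


@dataclass(frozen=True)
class Diagnostic:
    """A non-fatal problem found while validating a trace."""

    kind: str  # "gap" | "duplicate" | "bound"
    sensor: SensorKind
    detail: str


def validate_trace(trace: DailyTrace) -> list[Diagnostic]:
    """Report cadence gaps, duplicate minutes and out-of-bound values.

    Purely diagnostic: the trace is never mutated and no repair is
    attempted (repair policy belongs to callers).
    """
    diags: list[Diagnostic] = []
    by_sensor: dict[SensorKind, list[PeriodicReading]] = {}
    for rec in trace.readings:
        by_sensor.setdefault(rec.sensor, []).append(rec)
    for sensor, recs in by_sensor.items():
        minutes = [r.minute for r in recs]
        seen: set[int] = set()
        for m in minutes:
            if m in seen:
                diags.append(Diagnostic("duplicate", sensor,
                                        f"duplicate sample at {TimeOfDay(m)}"))
            seen.add(m)
        # Cadence gaps inside the observed span (one sample per minute).
        lo, hi = min(minutes), max(minutes)
        missing = sorted(set(range(lo, hi + 1)) - seen)
        for start, end in _runs(missing):
            diags.append(Diagnostic(
                "gap", sensor,
                f"missing minutes {TimeOfDay(start)}-{TimeOfDay(end)}"))
        bounds = VALUE_BOUNDS.get(sensor.value)
        if bounds:
            for r in recs:
                if not bounds[0] <= r.value <= bounds[1]:
                    diags.append(Diagnostic(
                        "bound", sensor,
                        f"value {r.value} at {TimeOfDay(r.minute)} outside "
                        f"[{bounds[0]}, {bounds[1]}]"))
    return diags


def _runs(values: Sequence[int]):
    """Yield (first, last) for each maximal run of consecutive integers."""
    run_start = None
    prev = None
    for v in values:
        if run_start is None:
            run_start = prev = v
        elif v == prev + 1:
            prev = v
        else:
            yield run_start, prev
            run_start = prev = v
    if run_start is not None:
        yield run_start, prev
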