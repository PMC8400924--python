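"""Streaming rule engine over a one-minute home-sensor clock.

The engine evaluates a ruleset of IF-THEN rules against per-minute
ambient readings and event-triggered detections, and emits
cooldown-throttled alert messages:

* threshold rules on temperature (below 15 °C / above 38 °C by default);
* a consecutive-minute temperature-rise rule (≥2 °C per minute);
* a night-vs-day rule: bedtime temperature at or above the highest
  temperature stored over the 09:00–16:00 daytime window (heating left
  on at bedtime);
* presence/absence-of-activity rules over learned or default time-of-day
  ranges for motion and TV-remote use;
* light-level rules inside evening/night ranges;
* permanent event rules (gas presence);
* meta-rules over the coincidence of two conditions within a short
  window, which take priority and send a single notification — notably
  fire presence coinciding with a ≥1 °C/min temperature rise, which is
  the only path to a fire alert by default (a bare fire detection is
  ignored as a likely false positive) and carries emergency severity.

Alert throttling is an episode model: an alert for a given rule opens a
quiet period (30 min by default), and any further trigger of the same
rule during the quiet period is absorbed *and extends it*.  A second
message for the same rule is only sent once 30 quiet minutes have
elapsed since the last trigger, emitted or absorbed.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .core import (
    MINUTES_PER_DAY,
    Alert,
    DailyTrace,
    PeriodicReading,
    SensorEvent,
    SensorKind,
    Severity,
    TimeOfDay,
    TimeRange,
    in_range,
    make_time_range,
)

log = logging.getLogger(__name__)

DEFAULT_COOLDOWN_MIN = 30
DEFAULT_COINCIDENCE_WINDOW_MIN = 10

#: Daytime window over which the running temperature maximum is stored.
DEFAULT_DAY_WINDOW = make_time_range(9 * 60, 16 * 60)


class RuleKind(str, Enum):
    threshold_low = "threshold_low"
    threshold_high = "threshold_high"
    delta_rise = "delta_rise"
    night_vs_day = "night_vs_day"
    presence_in_range = "presence_in_range"
    absence_in_range = "absence_in_range"
    light_low_in_range = "light_low_in_range"
    light_high_in_range = "light_high_in_range"
    event_presence = "event_presence"


class Mutability(str, Enum):
    permanent = "permanent"
    modifiable = "modifiable"


class MetaKind(str, Enum):
    motion_tv = "motion_tv"
    motion_low_light = "motion_low_light"
    fire_temp_rise = "fire_temp_rise"


class Phase(str, Enum):
    calibration = "calibration"
    readjustment = "readjustment"
    stable = "stable"


@dataclass(frozen=True)
class RuleParams:
    """Parameters of a rule; which fields apply depends on the rule kind."""

    threshold: Optional[float] = None  # °C or % light
    delta: Optional[float] = None      # °C per consecutive minute
    ranges: tuple[TimeRange, ...] = ()
    day_window: TimeRange = DEFAULT_DAY_WINDOW
    #: None = all weekdays; otherwise the ISO weekday indices (Mon=0) the
    #: rule applies to.  Weekday-specific rules arise from stable review.
    weekdays: Optional[frozenset[int]] = None


@dataclass(frozen=True)
class Rule:
    rule_id: str
    kind: RuleKind
    sensor: SensorKind
    mutability: Mutability = Mutability.modifiable
    params: RuleParams = field(default_factory=RuleParams)

    def __post_init__(self) -> None:
        if self.kind == RuleKind.event_presence and self.mutability != Mutability.permanent:
            raise ValueError("event-presence rules are permanent")
        range_kinds = {
            RuleKind.presence_in_range, RuleKind.absence_in_range,
            RuleKind.light_low_in_range, RuleKind.light_high_in_range,
            RuleKind.night_vs_day,
        }
        if self.kind in range_kinds and not self.params.ranges:
            raise ValueError(f"{self.kind.value} rule needs at least one range")

    def applies_on(self, weekday: int) -> bool:
        return self.params.weekdays is None or weekday in self.params.weekdays


@dataclass(frozen=True)
class MetaRule:
    """Coincidence of two conditions within a window → one notification."""

    meta_id: str
    kind: MetaKind
    severity: Severity = Severity.alert
    mutability: Mutability = Mutability.modifiable
    coincidence_window_min: Optional[int] = None  # None → engine default
    suppress_components: bool = True
    delta: Optional[float] = None  # °C/min rise for fire_temp_rise


@dataclass
class Ruleset:
    rules: list[Rule] = field(default_factory=list)
    metas: list[MetaRule] = field(default_factory=list)

    def of_kind(self, kind: RuleKind, sensor: SensorKind | None = None) -> list[Rule]:
        return [r for r in self.rules
                if r.kind == kind and (sensor is None or r.sensor == sensor)]

    def get(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)


@dataclass
class EngineConfig:
    cooldown_min: int = DEFAULT_COOLDOWN_MIN
    coincidence_window_min: int = DEFAULT_COINCIDENCE_WINDOW_MIN
    #: Emit an alert for a bare fire detection (the literal permanent
    #: rule).  Off by default: bare fire detections are prone to false
    #: positives, so fire alerts go through the fire+temperature-rise
    #: meta-rule only.
    fire_plain_rule_enabled: bool = False
    #: Light level (%) below which the motion+low-light meta-rule
    #: considers the room dark.
    low_light_threshold: float = 1.0


def default_ruleset() -> Ruleset:
    """The factory ruleset: defaults covering a full day of behavior.

    Four movement rules (two presence-in-unusual-range, two
    absence-in-usual-range), two TV-remote presence rules, temperature
    thresholds at 15/38 °C, a 2 °C/min rise rule, the bedtime
    night-vs-day rule split at midnight, evening/night light rules, the
    permanent gas rule, and the three meta-rules.
    """
    h = TimeOfDay.from_hhmm
    rules = [
        Rule("temp_low", RuleKind.threshold_low, SensorKind.temperature,
             params=RuleParams(threshold=15.0)),
        Rule("temp_high", RuleKind.threshold_high, SensorKind.temperature,
             params=RuleParams(threshold=38.0)),
        Rule("temp_delta", RuleKind.delta_rise, SensorKind.temperature,
             params=RuleParams(delta=2.0)),
        Rule("temp_night_premidnight", RuleKind.night_vs_day, SensorKind.temperature,
             params=RuleParams(ranges=(make_time_range(h(23).minute, MINUTES_PER_DAY),))),
        Rule("temp_night_postmidnight", RuleKind.night_vs_day, SensorKind.temperature,
             params=RuleParams(ranges=(make_time_range(0, h(7).minute),))),
        Rule("gas_any", RuleKind.event_presence, SensorKind.gas_presence,
             mutability=Mutability.permanent),
        Rule("fire_any", RuleKind.event_presence, SensorKind.fire,
             mutability=Mutability.permanent),
        Rule("motion_presence_0000_0800", RuleKind.presence_in_range, SensorKind.motion,
             params=RuleParams(ranges=(make_time_range(0, h(8).minute),))),
        Rule("motion_presence_2300_2400", RuleKind.presence_in_range, SensorKind.motion,
             params=RuleParams(ranges=(make_time_range(h(23).minute, MINUTES_PER_DAY),))),
        Rule("motion_absence_0900_1200", RuleKind.absence_in_range, SensorKind.motion,
             params=RuleParams(ranges=(make_time_range(h(9).minute, h(12).minute),))),
        Rule("motion_absence_1600_1800", RuleKind.absence_in_range, SensorKind.motion,
             params=RuleParams(ranges=(make_time_range(h(16).minute, h(18).minute),))),
        Rule("tv_presence_0000_0800", RuleKind.presence_in_range, SensorKind.tv_remote,
             params=RuleParams(ranges=(make_time_range(0, h(8).minute),))),
        Rule("tv_presence_2200_2400", RuleKind.presence_in_range, SensorKind.tv_remote,
             params=RuleParams(ranges=(make_time_range(h(22).minute, MINUTES_PER_DAY),))),
        Rule("light_low_1800_2100", RuleKind.light_low_in_range, SensorKind.light,
             params=RuleParams(threshold=20.0,
                               ranges=(make_time_range(h(18).minute, h(21).minute),))),
        Rule("light_high_night", RuleKind.light_high_in_range, SensorKind.light,
             params=RuleParams(threshold=1.0,
                               ranges=(make_time_range(h(23).minute, MINUTES_PER_DAY),
                                       make_time_range(0, h(5).minute)))),
    ]
    metas = [
        MetaRule("meta_motion_tv", MetaKind.motion_tv),
        MetaRule("meta_motion_low_light", MetaKind.motion_low_light),
        MetaRule("meta_fire_temp", MetaKind.fire_temp_rise,
                 severity=Severity.emergency, mutability=Mutability.permanent,
                 delta=1.0),
    ]
    return Ruleset(rules=rules, metas=metas)


# ---------------------------------------------------------------------------
# Pure rule predicates


def eval_threshold(rule: Rule, reading: PeriodicReading) -> bool:
    """Strict comparison against the rule threshold."""
    if rule.kind not in (RuleKind.threshold_low, RuleKind.threshold_high):
        raise ValueError(f"not a threshold rule: {rule.rule_id}")
    if reading.sensor != rule.sensor:
        raise ValueError(f"sensor mismatch: {reading.sensor} vs {rule.sensor}")
    if rule.kind == RuleKind.threshold_low:
        return reading.value < rule.params.threshold
    return reading.value > rule.params.threshold


def eval_delta(rule: Rule, prev: PeriodicReading, cur: PeriodicReading) -> bool:
    """True iff the value rose by at least ``delta`` over one minute."""
    if prev.sensor != cur.sensor or cur.sensor != rule.sensor:
        raise ValueError("sensor mismatch")
    if cur.timestamp - prev.timestamp != dt.timedelta(minutes=1):
        raise ValueError("readings are not consecutive minutes")
    return cur.value - prev.value >= rule.params.delta


def eval_presence(rule: Rule, event: SensorEvent) -> bool:
    """True iff the event clock falls inside any of the rule's ranges."""
    if rule.kind != RuleKind.presence_in_range or event.sensor != rule.sensor:
        return False
    return any(in_range(event.minute, r) for r in rule.params.ranges)


@dataclass
class CooldownRegistry:
    """Last trigger time per alert key, for episode-style throttling.

    A key triggers whenever its rule condition fires.  The first trigger
    of an episode is emitted; triggers arriving within ``cooldown_min``
    of the previous trigger are absorbed, and every trigger — emitted or
    absorbed — restamps the clock, so an episode only ends after a full
    quiet interval.
    """

    last_trigger: dict[str, dt.datetime] = field(default_factory=dict)

    def gate(self, key: str, now: dt.datetime, cooldown_min: int) -> bool:
        prev = self.last_trigger.get(key)
        self.last_trigger[key] = now
        if prev is None:
            return True
        return (now - prev) >= dt.timedelta(minutes=cooldown_min)

    def stamp(self, key: str, now: dt.datetime) -> None:
        """Open/extend a quiet period without emitting (meta suppression)."""
        self.last_trigger[key] = now


class Engine:
    """Mutable engine state folded over a strictly increasing minute clock.

    ``phase`` gates emission: during calibration the engine evaluates
    everything and updates all state, but returns no alerts.
    """

    def __init__(self, ruleset: Ruleset | None = None,
                 config: EngineConfig | None = None,
                 phase: Phase = Phase.stable,
                 day_index: int = 0) -> None:
        self.ruleset = ruleset if ruleset is not None else default_ruleset()
        self.config = config if config is not None else EngineConfig()
        self.phase = phase
        self.day_index = day_index
        self.cooldown = CooldownRegistry()
        self.last_reading: dict[SensorKind, PeriodicReading] = {}
        self.day_max_temp: Optional[float] = None
        self.day_max_date: Optional[dt.date] = None
        #: (rule_id, range) pairs satisfied so far today.
        self.seen_activity: set[tuple[str, TimeRange]] = set()
        self.recent_events: deque[SensorEvent] = deque()
        #: (timestamp, rise °C) for completed consecutive-minute rises.
        self.recent_rises: deque[tuple[dt.datetime, float]] = deque()
        self._last_ts: Optional[dt.datetime] = None
        self._finalized_date: Optional[dt.date] = None

    # -- properties used by learning ---------------------------------------

    @property
    def cooldown_min(self) -> int:
        return self.config.cooldown_min

    # -- stepping ----------------------------------------------------------

    def step(self, ts: dt.datetime,
             readings: Sequence[PeriodicReading] = (),
             events: Sequence[SensorEvent] = ()) -> list[Alert]:
        """Process one minute of inputs; return the minute's alerts."""
        ts = ts.replace(second=0, microsecond=0)
        if self._last_ts is not None and ts <= self._last_ts:
            raise ValueError(f"time went backwards: {ts} after {self._last_ts}")
        for rec in list(readings) + list(events):
            if rec.timestamp.replace(second=0, microsecond=0) != ts:
                raise ValueError("minute inputs must share one timestamp")

        alerts: list[Alert] = []
        if self._last_ts is not None and ts.date() != self._last_ts.date():
            alerts.extend(self._finalize_day(self._last_ts.date()))
            self.seen_activity.clear()
        self._last_ts = ts
        clock = ts.hour * 60 + ts.minute

        # Daytime-maximum window restarts: forget yesterday's stored max.
        day_window = self._day_window()
        if clock == day_window.start:
            self.day_max_temp = None
            self.day_max_date = ts.date()

        self._prune_buffers(ts)
        rise_now = self._ingest_readings(ts, clock, readings)
        self._ingest_events(ts, clock, events)

        # Meta-rules take priority; their suppression stamps come first.
        alerts.extend(self._eval_metas(ts, events, rise_now))
        alerts.extend(self._eval_single_rules(ts, clock, readings, events, rise_now))
        if self.phase == Phase.calibration:
            return []
        return alerts

    def run_day(self, trace: DailyTrace) -> list[Alert]:
        """Fold :meth:`step` over all 1440 minutes of one day's trace.

        Minutes absent from the trace still advance the clock (so
        end-of-range absence checks happen) but evaluate no readings.
        End-of-day absence ranges and midnight resets are applied before
        returning, so the returned list is the day's complete alerts.
        """
        if self._last_ts is not None and trace.date <= self._last_ts.date():
            raise ValueError(f"trace for {trace.date} is out of order")
        by_minute_r: dict[int, list[PeriodicReading]] = {}
        for r in trace.readings:
            by_minute_r.setdefault(r.minute, []).append(r)
        by_minute_e: dict[int, list[SensorEvent]] = {}
        for e in trace.events:
            by_minute_e.setdefault(e.minute, []).append(e)
        alerts: list[Alert] = []
        for m in range(MINUTES_PER_DAY):
            ts = dt.datetime.combine(trace.date, dt.time(m // 60, m % 60))
            alerts.extend(self.step(ts, by_minute_r.get(m, ()), by_minute_e.get(m, ())))
        alerts.extend(self._finalize_day(trace.date))
        self.seen_activity.clear()
        return alerts

    # -- internals ---------------------------------------------------------

    def _day_window(self) -> TimeRange:
        for rule in self.ruleset.of_kind(RuleKind.night_vs_day):
            return rule.params.day_window
        return DEFAULT_DAY_WINDOW

    def _prune_buffers(self, ts: dt.datetime) -> None:
        horizon = ts - dt.timedelta(minutes=self._max_window())
        while self.recent_events and self.recent_events[0].timestamp < horizon:
            self.recent_events.popleft()
        while self.recent_rises and self.recent_rises[0][0] < horizon:
            self.recent_rises.popleft()

    def _max_window(self) -> int:
        windows = [m.coincidence_window_min or self.config.coincidence_window_min
                   for m in self.ruleset.metas]
        return max(windows, default=self.config.coincidence_window_min)

    def _ingest_readings(self, ts: dt.datetime, clock: int,
                         readings: Sequence[PeriodicReading]) -> Optional[float]:
        """Update last-reading/day-max state; return this minute's
        consecutive temperature rise (°C), if any."""
        rise_now: Optional[float] = None
        for reading in readings:
            prev = self.last_reading.get(reading.sensor)
            if reading.sensor == SensorKind.temperature:
                if (prev is not None
                        and reading.timestamp - prev.timestamp == dt.timedelta(minutes=1)):
                    rise_now = reading.value - prev.value
                    meta_delta = min(
                        (m.delta for m in self.ruleset.metas
                         if m.kind == MetaKind.fire_temp_rise and m.delta is not None),
                        default=None)
                    if meta_delta is not None and rise_now >= meta_delta:
                        self.recent_rises.append((ts, rise_now))
                self._update_day_max(ts, clock, reading)
            self.last_reading[reading.sensor] = reading
        return rise_now

    def _update_day_max(self, ts: dt.datetime, clock: int,
                        reading: PeriodicReading) -> None:
        if in_range(clock, self._day_window()):
            if self.day_max_temp is None or reading.value > self.day_max_temp:
                self.day_max_temp = reading.value
                self.day_max_date = ts.date()

    def _ingest_events(self, ts: dt.datetime, clock: int,
                       events: Sequence[SensorEvent]) -> None:
        for event in events:
            self.recent_events.append(event)
            for rule in self.ruleset.of_kind(RuleKind.absence_in_range, event.sensor):
                for r in rule.params.ranges:
                    if in_range(clock, r):
                        self.seen_activity.add((rule.rule_id, r))

    def _presence_hits(self, sensor: SensorKind, event: SensorEvent) -> list[Rule]:
        weekday = event.timestamp.weekday()
        return [rule for rule in self.ruleset.of_kind(RuleKind.presence_in_range, sensor)
                if rule.applies_on(weekday) and eval_presence(rule, event)]

    def _eval_metas(self, ts: dt.datetime, events: Sequence[SensorEvent],
                    rise_now: Optional[float]) -> list[Alert]:
        alerts: list[Alert] = []
        for meta in self.ruleset.metas:
            window = meta.coincidence_window_min or self.config.coincidence_window_min
            horizon = ts - dt.timedelta(minutes=window)
            fired = False
            components: list[str] = []
            if meta.kind == MetaKind.fire_temp_rise:
                delta = meta.delta if meta.delta is not None else 1.0
                fire_now = any(e.sensor == SensorKind.fire for e in events)
                rise_ok_now = rise_now is not None and rise_now >= delta
                if fire_now or rise_ok_now:
                    fire_in_window = any(
                        e.sensor == SensorKind.fire and e.timestamp >= horizon
                        for e in self.recent_events)
                    rise_in_window = any(
                        t >= horizon and v >= delta for t, v in self.recent_rises)
                    fired = fire_in_window and rise_in_window
                components = ["fire_any", "temp_delta_meta"]
                message = ("Fire detected together with a temperature rise "
                           "— possible fire emergency")
            elif meta.kind == MetaKind.motion_tv:
                trig = [e for e in events if e.sensor in
                        (SensorKind.motion, SensorKind.tv_remote)]
                if trig:
                    motion_hits = [
                        (e, self._presence_hits(SensorKind.motion, e))
                        for e in self.recent_events
                        if e.sensor == SensorKind.motion and e.timestamp >= horizon]
                    tv_hits = [
                        (e, self._presence_hits(SensorKind.tv_remote, e))
                        for e in self.recent_events
                        if e.sensor == SensorKind.tv_remote and e.timestamp >= horizon]
                    motion_rules = [r for _, rs in motion_hits for r in rs]
                    tv_rules = [r for _, rs in tv_hits for r in rs]
                    fired = bool(motion_rules) and bool(tv_rules)
                    components = [r.rule_id for r in motion_rules + tv_rules]
                message = "Watching TV at an unusual time (motion + TV remote)"
            elif meta.kind == MetaKind.motion_low_light:
                light = self.last_reading.get(SensorKind.light)
                dark = (light is not None
                        and light.value < self.config.low_light_threshold)
                hit_rules = [r for e in events if e.sensor == SensorKind.motion
                             for r in self._presence_hits(SensorKind.motion, e)]
                fired = dark and bool(hit_rules)
                components = [r.rule_id for r in hit_rules]
                message = "Motion in the dark at an unusual time"
            else:  # pragma: no cover - exhaustive enum
                continue
            if not fired:
                continue
            emit = self.cooldown.gate(meta.meta_id, ts, self.config.cooldown_min)
            if meta.suppress_components:
                for key in components:
                    self.cooldown.stamp(key, ts)
            if emit:
                alerts.append(Alert(ts, meta.meta_id, meta.severity, message))
        return alerts

    def _eval_single_rules(self, ts: dt.datetime, clock: int,
                           readings: Sequence[PeriodicReading],
                           events: Sequence[SensorEvent],
                           rise_now: Optional[float]) -> list[Alert]:
        alerts: list[Alert] = []
        weekday = ts.weekday()

        for event in events:
            for rule in self.ruleset.rules:
                if rule.sensor != event.sensor or not rule.applies_on(weekday):
                    continue
                if rule.kind == RuleKind.event_presence:
                    if (rule.sensor == SensorKind.fire
                            and not self.config.fire_plain_rule_enabled):
                        continue
                    self._gate_and_emit(
                        alerts, rule.rule_id, ts, Severity.alert,
                        f"{event.sensor.value.replace('_', ' ')} detected")
                elif rule.kind == RuleKind.presence_in_range and eval_presence(rule, event):
                    self._gate_and_emit(
                        alerts, rule.rule_id, ts, Severity.alert,
                        f"{event.sensor.value.replace('_', ' ')} detected during "
                        f"unusual hours ({rule.params.ranges[0]})")

        for reading in readings:
            for rule in self.ruleset.rules:
                if rule.sensor != reading.sensor or not rule.applies_on(weekday):
                    continue
                if rule.kind in (RuleKind.threshold_low, RuleKind.threshold_high):
                    if eval_threshold(rule, reading):
                        direction = ("below" if rule.kind == RuleKind.threshold_low
                                     else "above")
                        self._gate_and_emit(
                            alerts, rule.rule_id, ts, Severity.alert,
                            f"temperature {reading.value:.1f} °C {direction} "
                            f"{rule.params.threshold:.1f} °C")
                elif rule.kind == RuleKind.delta_rise:
                    if rise_now is not None and rise_now >= rule.params.delta:
                        self._gate_and_emit(
                            alerts, rule.rule_id, ts, Severity.alert,
                            f"temperature rose {rise_now:.1f} °C in one minute")
                elif rule.kind == RuleKind.night_vs_day:
                    if self._night_vs_day_fires(rule, clock, reading):
                        self._gate_and_emit(
                            alerts, rule.rule_id, ts, Severity.alert,
                            f"bedtime temperature {reading.value:.1f} °C at or above "
                            f"the daytime maximum {self.day_max_temp:.1f} °C "
                            f"— heating on at bedtime?")
                elif rule.kind == RuleKind.light_low_in_range:
                    if (any(in_range(clock, r) for r in rule.params.ranges)
                            and reading.value < rule.params.threshold):
                        self._gate_and_emit(
                            alerts, rule.rule_id, ts, Severity.alert,
                            f"light {reading.value:.1f}% below "
                            f"{rule.params.threshold:.1f}% in the evening")
                elif rule.kind == RuleKind.light_high_in_range:
                    if (any(in_range(clock, r) for r in rule.params.ranges)
                            and reading.value > rule.params.threshold):
                        self._gate_and_emit(
                            alerts, rule.rule_id, ts, Severity.alert,
                            f"light {reading.value:.1f}% above "
                            f"{rule.params.threshold:.1f}% at night")

        # Absence rules are only decidable at the minute a range closes.
        for rule in self.ruleset.of_kind(RuleKind.absence_in_range):
            if not rule.applies_on(weekday):
                continue
            for r in rule.params.ranges:
                if r.end_exclusive == clock and (rule.rule_id, r) not in self.seen_activity:
                    self._gate_and_emit(
                        alerts, rule.rule_id, ts, Severity.alert,
                        f"no {rule.sensor.value} detected during usual hours ({r})")
        return alerts

    def _night_vs_day_fires(self, rule: Rule, clock: int,
                            reading: PeriodicReading) -> bool:
        if not any(in_range(clock, r) for r in rule.params.ranges):
            return False
        if self.day_max_temp is None:
            log.debug("night-vs-day rule %s inert: no stored daytime maximum",
                      rule.rule_id)
            return False
        # ≥: an equal bedtime temperature already indicates heating on.
        return reading.value >= self.day_max_temp

    def _gate_and_emit(self, alerts: list[Alert], key: str, ts: dt.datetime,
                       severity: Severity, message: str) -> None:
        if self.cooldown.gate(key, ts, self.config.cooldown_min):
            alerts.append(Alert(ts, key, severity, message))

    def _finalize_day(self, date: dt.date) -> list[Alert]:
        """Evaluate absence ranges that end at midnight (minute 1440)."""
        if self._finalized_date == date:
            return []
        self._finalized_date = date
        alerts: list[Alert] = []
        ts = dt.datetime.combine(date + dt.timedelta(days=1), dt.time(0, 0))
        weekday = date.weekday()
        for rule in self.ruleset.of_kind(RuleKind.absence_in_range):
            if not rule.applies_on(weekday):
                continue
            for r in rule.params.ranges:
                if (r.end_exclusive == MINUTES_PER_DAY
                        and (rule.rule_id, r) not in self.seen_activity):
                    self._gate_and_emit(
                        alerts, rule.rule_id, ts, Severity.alert,
                        f"no {rule.sensor.value} detected during usual hours ({r})")
        if self.phase == Phase.calibration:
            return []
        return alerts


# ---------------------------------------------------------------------------
# Free-function facade mirroring the engine's operations

EngineState = Engine  # the engine object *is* the mutable state record


def cooldown_gate(state: Engine, key: str, now: dt.datetime) -> tuple[bool, Engine]:
    emit = state.cooldown.gate(key, now, state.config.cooldown_min)
    return emit, state


def update_day_max(state: Engine, reading: PeriodicReading) -> Engine:
    if reading.sensor != SensorKind.temperature:
        raise ValueError("day maximum tracks the temperature channel")
    clock = reading.timestamp.hour * 60 + reading.timestamp.minute
    state._update_day_max(reading.timestamp, clock, reading)
    return state


def eval_night_vs_day(rule: Rule, state: Engine, reading: PeriodicReading) -> bool:
    return state._night_vs_day_fires(rule, reading.minute, reading)


def eval_absence(rule: Rule, state: Engine, clock: TimeOfDay) -> bool:
    """True iff some rule range ends exactly at ``clock`` with no
    qualifying activity seen during it today."""
    if rule.kind != RuleKind.absence_in_range:
        raise ValueError(f"not an absence rule: {rule.rule_id}")
    return any(r.end_exclusive == clock.minute
               and (rule.rule_id, r) not in state.seen_activity
               for r in rule.params.ranges)


def eval_meta(meta: MetaRule, state: Engine, now: dt.datetime) -> bool:
    """True iff both of the meta-rule's component conditions held within
    the coincidence window ending at ``now`` (as recorded in the
    engine's recent-event buffers)."""
    window = meta.coincidence_window_min or state.config.coincidence_window_min
    horizon = now - dt.timedelta(minutes=window)
    if meta.kind == MetaKind.fire_temp_rise:
        delta = meta.delta if meta.delta is not None else 1.0
        fire = any(e.sensor == SensorKind.fire and e.timestamp >= horizon
                   for e in state.recent_events)
        rise = any(t >= horizon and v >= delta for t, v in state.recent_rises)
        return fire and rise
    if meta.kind == MetaKind.motion_tv:
        motion = any(e.sensor == SensorKind.motion and e.timestamp >= horizon
                     and state._presence_hits(SensorKind.motion, e)
                     for e in state.recent_events)
        tv = any(e.sensor == SensorKind.tv_remote and e.timestamp >= horizon
                 and state._presence_hits(SensorKind.tv_remote, e)
                 for e in state.recent_events)
        return motion and tv
    if meta.kind == MetaKind.motion_low_light:
        light = state.last_reading.get(SensorKind.light)
        dark = light is not None and light.value < state.config.low_light_threshold
        motion = any(e.sensor == SensorKind.motion and e.timestamp >= horizon
                     and state._presence_hits(SensorKind.motion, e)
                     for e in state.recent_events)
        return dark and motion
    return False  # pragma: no cover - exhaustive enum


def step(state: Engine, ts: dt.datetime,
         readings: Sequence[PeriodicReading] = (),
         events: Sequence[SensorEvent] = ()) -> tuple[Engine, list[Alert]]:
    return state, state.step(ts, readings, events)


def run_day(state: Engine, trace: DailyTrace) -> tuple[Engine, list[Alert]]:
    return state, state.run_day(trace)
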