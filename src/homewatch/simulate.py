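"""Synthetic single-resident home simulator.

Generates per-minute ambient traces with the structure the rule engine
assumes: daytime motion blocks between wake and sleep, evening TV-remote
use, a diurnal temperature curve with heating episodes, and stepped
day/evening/night light levels.  Motion and TV events are Poisson
processes at configured hourly rates inside their activity windows and
silent outside them; away windows (per weekday) silence both.

Anomalies — gas/fire events, nocturnal motion, daytime absence, abrupt
temperature spikes, heating left on at night — are injected into an
otherwise normal trace, touching only the targeted channel and range.

Deterministic fixtures reproduce two worked alteration scenarios at
exact printed minutes: a day of fire/gas detections with three abrupt
temperature rises, and a multi-day bedtime-temperature scenario.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .core import (
    MINUTES_PER_DAY,
    DailyTrace,
    PeriodicReading,
    SensorEvent,
    SensorKind,
    TimeOfDay,
    TimeRange,
    in_range,
    make_time_range,
)

#: Stable channel indices for per-channel RNG streams: adding a channel
#: never perturbs the draws of existing ones.
_CHANNEL_IDX = {
    "temperature": 0, "humidity": 1, "pressure": 2, "light": 3,
    "gas_level": 4, "motion": 5, "tv_remote": 6,
}

#: Pre-built clock times for all 1440 minutes (hot path).
_TIMES = [dt.time(m // 60, m % 60) for m in range(MINUTES_PER_DAY)]

_DEFAULT_NOISE_SD = {
    "temperature": 0.05,  # small enough to never trip the 2 °C/min rule
    "humidity": 1.0,
    "pressure": 0.3,
    "light": 0.2,
    "gas_level": 1.0,
}


@dataclass
class ResidentConfig:
    """Behavioral and environmental parameters of the simulated home."""

    wake: TimeOfDay = TimeOfDay.from_hhmm(8)
    sleep: TimeOfDay = TimeOfDay.from_hhmm(23)
    away_windows: tuple[tuple[int, TimeRange], ...] = ()  # (weekday, range)
    motion_rate: float = 20.0  # events/hour while active
    tv_windows: tuple[TimeRange, ...] = (make_time_range(20 * 60, 23 * 60),)
    tv_rate: float = 30.0  # events/hour inside tv_windows
    temp_base: float = 20.0  # °C
    temp_amplitude: float = 2.0  # °C diurnal swing, peak mid-afternoon
    heating_windows: tuple[tuple[TimeRange, float], ...] = (
        (make_time_range(7 * 60, 9 * 60), 22.0),)  # (range, setpoint °C)
    light_day: float = 60.0  # % over 08:00-18:00
    light_evening: float = 40.0  # % over 18:00-23:00
    light_night: float = 0.5  # % otherwise
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wake >= self.sleep:
            raise ValueError("wake must precede sleep")
        if min(self.motion_rate, self.tv_rate) < 0:
            raise ValueError("event rates must be non-negative")
        if self.temp_amplitude < 0:
            raise ValueError("temperature amplitude must be non-negative")


class AnomalyKind(str, Enum):
    gas_event = "gas_event"
    fire_event = "fire_event"
    nocturnal_motion = "nocturnal_motion"
    daytime_absence = "daytime_absence"
    temp_spike = "temp_spike"
    heating_left_on = "heating_left_on"


@dataclass(frozen=True)
class AnomalySpec:
    kind: AnomalyKind
    at: dt.datetime | TimeRange
    magnitude: Optional[float] = None


def _rng(seed: int, channel: str, date: dt.date) -> np.random.Generator:
    return np.random.default_rng([int(seed), _CHANNEL_IDX[channel], date.toordinal()])


def _minute_mask(windows: Sequence[TimeRange]) -> np.ndarray:
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    for w in windows:
        mask[w.start:w.end_exclusive] = True
    return mask


def _light_profile(cfg: ResidentConfig) -> np.ndarray:
    prof = np.full(MINUTES_PER_DAY, cfg.light_night)
    prof[8 * 60:18 * 60] = cfg.light_day
    prof[18 * 60:23 * 60] = cfg.light_evening
    return prof


def _temperature_series(cfg: ResidentConfig, rng: np.random.Generator) -> np.ndarray:
    minutes = np.arange(MINUTES_PER_DAY)
    # Diurnal curve peaking around 16:00, trough around 04:00.
    target = cfg.temp_base + cfg.temp_amplitude * np.sin(
        2 * math.pi * (minutes - 600) / MINUTES_PER_DAY)
    for window, setpoint in cfg.heating_windows:
        target[window.start:window.end_exclusive] = setpoint
    noise = rng.normal(0.0, cfg.noise_sd.get("temperature", 0.0), MINUTES_PER_DAY)
    temp = np.empty(MINUTES_PER_DAY)
    temp[0] = target[0]
    # First-order lag toward the target: heating pulls, walls damp.
    for m in range(1, MINUTES_PER_DAY):
        temp[m] = temp[m - 1] + 0.15 * (target[m] - temp[m - 1])
    return np.round(temp + noise, 2)


def _poisson_events(rate_per_hour: float, mask: np.ndarray,
                    rng: np.random.Generator, date: dt.date,
                    sensor: SensorKind) -> list[SensorEvent]:
    counts = rng.poisson(rate_per_hour / 60.0, MINUTES_PER_DAY) * mask
    events = []
    for m in np.nonzero(counts)[0]:
        ts = dt.datetime.combine(date, _TIMES[int(m)])
        events.extend([SensorEvent(ts, sensor)] * int(counts[m]))
    return events


def simulate_day(cfg: ResidentConfig, date: dt.date,
                 seed: Optional[int] = None) -> DailyTrace:
    """One simulated day: 1440 samples per periodic channel plus motion
    and TV events.  Deterministic under ``(cfg, date, seed)``."""
    seed = cfg.seed if seed is None else seed
    weekday = date.weekday()
    away = [w for wd, w in cfg.away_windows if wd == weekday]
    away_mask = _minute_mask(away)

    readings: list[PeriodicReading] = []
    temp = _temperature_series(cfg, _rng(seed, "temperature", date))
    flat = {
        "humidity": 45.0,
        "pressure": 1013.0,
        "gas_level": 50.0,
    }
    series = {"temperature": temp}
    for name, level in flat.items():
        noise = _rng(seed, name, date).normal(
            0.0, cfg.noise_sd.get(name, 0.0), MINUTES_PER_DAY)
        series[name] = np.round(np.maximum(level + noise, 0.0), 2)
    light_noise = _rng(seed, "light", date).normal(
        0.0, cfg.noise_sd.get("light", 0.0), MINUTES_PER_DAY)
    series["light"] = np.round(
        np.clip(_light_profile(cfg) + light_noise, 0.0, 100.0), 2)

    for name, values in series.items():
        sensor = SensorKind(name)
        for m in range(MINUTES_PER_DAY):
            readings.append(PeriodicReading(
                dt.datetime.combine(date, _TIMES[m]), sensor, float(values[m])))

    active_mask = _minute_mask([make_time_range(cfg.wake.minute, cfg.sleep.minute)])
    active_mask &= ~away_mask
    events = _poisson_events(cfg.motion_rate, active_mask,
                             _rng(seed, "motion", date), date, SensorKind.motion)
    tv_mask = _minute_mask(cfg.tv_windows) & ~away_mask
    events += _poisson_events(cfg.tv_rate, tv_mask,
                              _rng(seed, "tv_remote", date), date, SensorKind.tv_remote)
    return DailyTrace(date=date, readings=readings, events=events)


def simulate_period(cfg: ResidentConfig, n_days: int,
                    seed: Optional[int] = None,
                    start: dt.date = dt.date(2021, 3, 1)) -> list[DailyTrace]:
    """``n_days`` consecutive traces; each day draws from its own
    per-(seed, channel, date) substream."""
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    return [simulate_day(cfg, start + dt.timedelta(days=i), seed)
            for i in range(n_days)]


# ---------------------------------------------------------------------------
# Anomaly injection


def inject_anomaly(trace: DailyTrace, spec: AnomalySpec) -> DailyTrace:
    """Return a new trace with the anomaly merged in.

    Only records inside the spec's channel and range are touched; event
    injection is idempotent (an identical event at the same minute is
    not duplicated).
    """
    readings = list(trace.readings)
    events = list(trace.events)

    if spec.kind in (AnomalyKind.gas_event, AnomalyKind.fire_event):
        sensor = (SensorKind.gas_presence if spec.kind == AnomalyKind.gas_event
                  else SensorKind.fire)
        for ts in _event_times(trace.date, spec.at, step=1440):
            ev = SensorEvent(ts, sensor)
            if ev not in events:
                events.append(ev)
    elif spec.kind == AnomalyKind.nocturnal_motion:
        for ts in _event_times(trace.date, spec.at, step=5):
            ev = SensorEvent(ts, SensorKind.motion)
            if ev not in events:
                events.append(ev)
    elif spec.kind == AnomalyKind.daytime_absence:
        r = _as_range(spec.at)
        events = [e for e in events
                  if not (e.sensor == SensorKind.motion and in_range(e.minute, r))]
    elif spec.kind == AnomalyKind.temp_spike:
        readings = _apply_temp_spike(trace, spec)
    elif spec.kind == AnomalyKind.heating_left_on:
        readings = _apply_heating_left_on(trace, spec)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(spec.kind)
    return DailyTrace(date=trace.date, readings=readings, events=events)


def _as_range(at: dt.datetime | TimeRange) -> TimeRange:
    if isinstance(at, TimeRange):
        return at
    m = at.hour * 60 + at.minute
    return make_time_range(m, m + 1)


def _event_times(date: dt.date, at: dt.datetime | TimeRange, step: int):
    if isinstance(at, dt.datetime):
        if at.date() != date:
            raise ValueError(f"anomaly timestamp {at} not on {date}")
        yield at.replace(second=0, microsecond=0)
        return
    for m in range(at.start, at.end_exclusive, step):
        yield dt.datetime.combine(date, _TIMES[m])


def _temp_values(trace: DailyTrace) -> dict[int, float]:
    return {r.minute: r.value for r in trace.readings_of(SensorKind.temperature)}


def _rebuild_temp(trace: DailyTrace, new_values: dict[int, float]
                  ) -> list[PeriodicReading]:
    out = []
    for r in trace.readings:
        if r.sensor == SensorKind.temperature and r.minute in new_values:
            out.append(PeriodicReading(r.timestamp, r.sensor,
                                       round(new_values[r.minute], 2)))
        else:
            out.append(r)
    return out


def _apply_temp_spike(trace: DailyTrace, spec: AnomalySpec) -> list[PeriodicReading]:
    """Rewrite the temperature series so a consecutive-minute rise of at
    least ``magnitude`` (default 2 °C) completes at the given minute,
    then decays back toward the original series."""
    if not isinstance(spec.at, dt.datetime):
        raise ValueError("temp_spike needs a completion timestamp")
    m0 = spec.at.hour * 60 + spec.at.minute
    jump = max(2.0, spec.magnitude or 2.0)
    orig = _temp_values(trace)
    if m0 - 1 not in orig or m0 not in orig:
        raise ValueError("temp_spike needs temperature samples around the spike")
    new: dict[int, float] = {m0: orig[m0 - 1] + jump}
    level = new[m0]
    for m in range(m0 + 1, MINUTES_PER_DAY):
        if m not in orig:
            break
        level -= 0.3
        if level <= orig[m]:
            break
        new[m] = level
    return _rebuild_temp(trace, new)


def _apply_heating_left_on(trace: DailyTrace, spec: AnomalySpec
                           ) -> list[PeriodicReading]:
    """Hold the temperature above the day's 09:00-16:00 maximum during
    the given night range."""
    r = _as_range(spec.at)
    orig = _temp_values(trace)
    day_window = make_time_range(9 * 60, 16 * 60)
    day_max = max(v for m, v in orig.items() if in_range(m, day_window))
    level = day_max + max(0.1, spec.magnitude or 0.1)
    new = {m: level for m in range(r.start, r.end_exclusive) if m in orig}
    return _rebuild_temp(trace, new)


# ---------------------------------------------------------------------------
# Deterministic worked-example fixtures


def _flat_temp_day(date: dt.date, values: np.ndarray) -> list[PeriodicReading]:
    return [PeriodicReading(dt.datetime.combine(date, _TIMES[m]),
                            SensorKind.temperature, round(float(values[m]), 2))
            for m in range(MINUTES_PER_DAY)]


def _events_at(date: dt.date, sensor: SensorKind,
               hhmm_list: Sequence[str]) -> list[SensorEvent]:
    out = []
    for text in hhmm_list:
        t = TimeOfDay.parse(text)
        out.append(SensorEvent(
            dt.datetime.combine(date, dt.time(t.minute // 60, t.minute % 60)),
            sensor))
    return out


#: Fire detections of the alteration-day scenario.  Printed minutes:
#: 13:39, 13:40 (no rise nearby → no alert) and 21:56 (coincides with the
#: 21:54-21:59 rise → one emergency).  The remaining times fill the
#: half-hour bin counts of the scenario's accounting table and are fixed
#: deterministic minutes placed more than a coincidence window away from
#: any temperature rise.
FIRE_SCHEDULE = (
    "11:45",
    "12:32", "12:33", "12:34", "12:35", "12:36", "12:37", "12:38", "12:39", "12:40",
    "13:05", "13:06", "13:07", "13:08", "13:09", "13:10",
    "13:39", "13:40",
    "14:20",
    "14:45",
    "21:35", "21:38", "21:56",
)

#: Gas detections.  Printed minutes: 13:56 (alert) and 14:29 (absorbed —
#: the 14:10 trigger keeps the episode open).  The rest fill the table's
#: bin counts so that the episode-throttled alert pattern matches the
#: printed accounting.
GAS_SCHEDULE = (
    "12:05", "12:10", "12:15",
    "13:05", "13:10", "13:15", "13:20",
    "13:56", "13:57", "13:58", "13:59",
    "14:10", "14:29",
    "14:45", "14:50",
    "15:40", "15:45",
    "17:10", "17:15", "17:20",
    "18:40", "18:45",
    "20:40", "20:45",
    "21:10", "21:20",
    "21:50", "21:55",
)


def fixture_fire_day(date: dt.date = dt.date(2021, 3, 30)) -> DailyTrace:
    """The intentional-alteration day: fire and gas detections plus three
    abrupt temperature rises completing at 14:00, 19:36 and 21:59.

    The 21:54-21:59 rise passes through a 1.0 °C consecutive-minute step
    at 21:57, so the fire detection at 21:56 triggers the
    fire+temperature meta-rule at 21:57; the 2 °C steps at 14:00, 19:36
    and 21:59 trigger the plain rise rule.  Zero noise by construction.
    """
    temp = np.full(MINUTES_PER_DAY, 21.0)

    def rise(ramp_start: int, ramp_step: float, jumps: Sequence[float]) -> None:
        """Gentle ramp followed by explicit per-minute jumps, then decay."""
        m = ramp_start
        level = 21.0
        while True:
            nxt = level + ramp_step
            end_ramp = ramp_start + _ramp_len
            if m >= end_ramp:
                break
            level = nxt
            temp[m] = level
            m += 1
        for j in jumps:
            level += j
            temp[m] = level
            m += 1
        while level > 21.0 and m < MINUTES_PER_DAY:
            level = max(21.0, level - 0.2)
            temp[m] = level
            m += 1

    # 13:51-13:59 ramp +0.1/min, 2.0 °C jump completing at 14:00.
    _ramp_len = 9
    rise(13 * 60 + 51, 0.1, [2.0])
    # 19:29-19:35 ramp, jump at 19:36.
    _ramp_len = 7
    rise(19 * 60 + 29, 0.1, [2.0])
    # 21:54-21:56 ramp, +1.0 at 21:57 (meta component), +0.1, +2.0 at 21:59.
    _ramp_len = 3
    rise(21 * 60 + 54, 0.1, [1.0, 0.1, 2.0])

    readings = _flat_temp_day(date, temp)
    events = (_events_at(date, SensorKind.fire, FIRE_SCHEDULE)
              + _events_at(date, SensorKind.gas_presence, GAS_SCHEDULE)
              + _events_at(date, SensorKind.motion,
                           ["10:00", "10:30", "11:00", "16:30", "17:00"]))
    return DailyTrace(date=date, readings=readings, events=events)


def fixture_night_temp(start: dt.date = dt.date(2021, 3, 3)) -> list[DailyTrace]:
    """Three consecutive days for the bedtime-temperature scenario.

    Day A: afternoon maximum 21.8 °C.  The following night (day B,
    00:00-07:00) holds 21.9 °C readings at 02:01 and 03:33 — at or above
    the stored maximum → two alerts.  Day C: afternoon maximum 23.8 °C,
    then 23.9 °C sustained 23:17-23:32 the same evening → one alert.
    All other night minutes sit below the stored maximum.
    """
    def bump_day(date: dt.date, peak: float,
                 spikes: dict[int, float] | None = None,
                 evening_hold: tuple[int, int, float] | None = None) -> DailyTrace:
        temp = np.full(MINUTES_PER_DAY, 21.0)
        # Smooth afternoon bump peaking at 14:00 (inside 09:00-16:00).
        for m in range(810, 871):
            temp[m] = 21.0 + (peak - 21.0) * math.sin(math.pi * (m - 810) / 60)
        if evening_hold:
            h_start, h_end, level = evening_hold
            # Ramp up beforehand so every consecutive step stays < 1 °C.
            ramp_start = h_start - 32
            for m in range(ramp_start, h_start):
                temp[m] = 21.0 + (level - 0.5 - 21.0) * (m - ramp_start) / 32
            for m in range(h_start, h_end):
                temp[m] = level
            m = h_end
            v = level
            while v > 21.0 and m < MINUTES_PER_DAY:
                v = max(21.0, v - 0.15)
                temp[m] = v
                m += 1
        if spikes:
            for m, v in spikes.items():
                temp[m] = v
        readings = _flat_temp_day(date, temp)
        events = _events_at(date, SensorKind.motion,
                            ["10:00", "11:00", "16:30", "17:00"])
        return DailyTrace(date=date, readings=readings, events=events)

    day_a = bump_day(start, peak=21.8)
    day_b = bump_day(start + dt.timedelta(days=1), peak=21.5,
                     spikes={2 * 60 + 1: 21.9, 3 * 60 + 33: 21.9})
    day_c = bump_day(start + dt.timedelta(days=2), peak=23.8,
                     evening_hold=(23 * 60 + 17, 23 * 60 + 33, 23.9))
    return [day_a, day_b, day_c]
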