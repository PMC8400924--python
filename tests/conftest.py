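import datetime as dt

import pytest

from homewatch import (
    DailyTrace,
    Engine,
    PeriodicReading,
    Phase,
    SensorEvent,
    SensorKind,
    default_ruleset,
)

DAY = dt.date(2021, 3, 30)


def ts(hhmm: str, date: dt.date = DAY) -> dt.datetime:
    h, m = map(int, hhmm.split(":"))
    return dt.datetime.combine(date, dt.time(h, m))


def temp(hhmm: str, value: float, date: dt.date = DAY) -> PeriodicReading:
    return PeriodicReading(ts(hhmm, date), SensorKind.temperature, value)


def ev(hhmm: str, sensor: SensorKind, date: dt.date = DAY) -> SensorEvent:
    return SensorEvent(ts(hhmm, date), sensor)


def flat_temp_day(date: dt.date = DAY, value: float = 21.0,
                  events=()) -> DailyTrace:
    """Quiet day: flat temperature except a mild 13:00-15:00 bump, so the
    stored daytime maximum sits above the night readings."""
    readings = [PeriodicReading(
        dt.datetime.combine(date, dt.time(m // 60, m % 60)),
        SensorKind.temperature, value + (0.5 if 780 <= m < 900 else 0.0))
        for m in range(1440)]
    return DailyTrace(date=date, readings=readings, events=list(events))


@pytest.fixture
def stable_engine() -> Engine:
    return Engine(default_ruleset(), phase=Phase.stable)
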