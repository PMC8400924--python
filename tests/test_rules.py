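"""Rule predicates, cooldown throttling, meta-rules, engine stepping."""

import datetime as dt

import numpy as np
import pytest

from homewatch import (
    DailyTrace,
    Engine,
    EngineConfig,
    MetaRule,
    Mutability,
    PeriodicReading,
    Phase,
    Rule,
    RuleKind,
    RuleParams,
    Ruleset,
    SensorEvent,
    SensorKind,
    Severity,
    cooldown_gate,
    default_ruleset,
    eval_delta,
    eval_meta,
    eval_presence,
    eval_threshold,
    make_time_range,
    update_day_max,
)
from homewatch.rules import MetaKind

from conftest import DAY, ev, flat_temp_day, temp, ts


class TestDefaultRuleset:
    def test_movement_and_tv_rules(self):
        rs = default_ruleset()
        motion_presence = rs.of_kind(RuleKind.presence_in_range, SensorKind.motion)
        assert sorted(r.params.ranges[0] for r in motion_presence) == [
            make_time_range(0, 480), make_time_range(1380, 1440)]
        tv = rs.of_kind(RuleKind.presence_in_range, SensorKind.tv_remote)
        assert len(tv) == 2
        absence = rs.of_kind(RuleKind.absence_in_range, SensorKind.motion)
        assert sorted(r.params.ranges[0] for r in absence) == [
            make_time_range(540, 720), make_time_range(960, 1080)]

    def test_temperature_defaults(self):
        rs = default_ruleset()
        assert rs.get("temp_low").params.threshold == 15.0
        assert rs.get("temp_high").params.threshold == 38.0
        assert rs.get("temp_delta").params.delta == 2.0

    def test_event_rules_are_permanent(self):
        rs = default_ruleset()
        assert rs.get("gas_any").mutability == Mutability.permanent
        assert rs.get("fire_any").mutability == Mutability.permanent

    def test_light_defaults(self):
        rs = default_ruleset()
        low = rs.get("light_low_1800_2100")
        assert low.params.threshold == 20.0
        assert low.params.ranges == (make_time_range(1080, 1260),)
        high = rs.get("light_high_night")
        assert high.params.threshold == 1.0
        assert set(high.params.ranges) == {make_time_range(1380, 1440),
                                           make_time_range(0, 300)}


class TestPredicates:
    @pytest.mark.parametrize("value,expected", [(14.9, True), (15.0, False)])
    def test_threshold_low_strict(self, value, expected):
        rule = default_ruleset().get("temp_low")
        assert eval_threshold(rule, temp("10:00", value)) is expected

    def test_threshold_high(self):
        rule = default_ruleset().get("temp_high")
        assert eval_threshold(rule, temp("10:00", 38.5)) is True
        with pytest.raises(ValueError):
            eval_threshold(rule, PeriodicReading(ts("10:00"), SensorKind.light, 50.0))

    @pytest.mark.parametrize("prev,cur,expected", [
        (20.0, 22.1, True), (20.0, 21.9, False), (20.0, 22.0, True)])
    def test_delta_rise(self, prev, cur, expected):
        rule = default_ruleset().get("temp_delta")
        assert eval_delta(rule, temp("10:00", prev), temp("10:01", cur)) is expected

    def test_delta_requires_consecutive_minutes(self):
        rule = default_ruleset().get("temp_delta")
        with pytest.raises(ValueError):
            eval_delta(rule, temp("10:00", 20.0), temp("10:05", 25.0))

    def test_one_degree_delta_variant(self):
        rule = Rule("t1", RuleKind.delta_rise, SensorKind.temperature,
                    params=RuleParams(delta=1.0))
        assert eval_delta(rule, temp("10:00", 20.0), temp("10:01", 21.0)) is True

    def test_presence_examples(self):
        rs = default_ruleset()
        late = rs.get("motion_presence_2300_2400")
        assert eval_presence(late, ev("23:30", SensorKind.motion)) is True
        assert eval_presence(late, ev("12:00", SensorKind.motion)) is False
        tv = rs.get("tv_presence_2200_2400")
        assert eval_presence(tv, ev("22:00", SensorKind.tv_remote)) is True


class TestDayMax:
    def test_tracks_maximum_in_window(self, stable_engine):
        update_day_max(stable_engine, temp("13:00", 21.5))
        update_day_max(stable_engine, temp("14:00", 21.8))
        assert stable_engine.day_max_temp == 21.8
        update_day_max(stable_engine, temp("15:00", 20.0))
        assert stable_engine.day_max_temp == 21.8

    def test_outside_window_ignored(self, stable_engine):
        update_day_max(stable_engine, temp("17:00", 30.0))
        assert stable_engine.day_max_temp is None

    def test_night_rule_inert_without_stored_max(self, stable_engine):
        alerts = stable_engine.step(ts("23:30"), [temp("23:30", 25.0)])
        assert alerts == []

    def test_night_rule_fires_at_or_above_max(self, stable_engine):
        stable_engine.day_max_temp = 21.8
        alerts = stable_engine.step(ts("02:01"), [temp("02:01", 21.8)])
        assert [a.rule_id for a in alerts] == ["temp_night_postmidnight"]
        # Below the maximum: silent.
        alerts = stable_engine.step(ts("02:40"), [temp("02:40", 21.7)])
        assert alerts == []


class TestCooldown:
    def test_first_trigger_emits(self, stable_engine):
        emit, _ = cooldown_gate(stable_engine, "gas_any", ts("13:56"))
        assert emit is True

    def test_quiet_gap_reopens(self, stable_engine):
        assert cooldown_gate(stable_engine, "gas_any", ts("13:56"))[0]
        assert cooldown_gate(stable_engine, "gas_any", ts("15:35"))[0] is True

    def test_absorbed_trigger_extends_episode(self, stable_engine):
        """A trigger during the quiet period is absorbed and restamps the
        clock, so a later trigger is measured from it, not from the last
        emitted alert."""
        assert cooldown_gate(stable_engine, "gas_any", ts("13:56"))[0]
        assert cooldown_gate(stable_engine, "gas_any", ts("14:10"))[0] is False
        # 14:29 is 33 min after the alert but only 19 after the absorbed
        # trigger: still inside the episode.
        assert cooldown_gate(stable_engine, "gas_any", ts("14:29"))[0] is False
        assert cooldown_gate(stable_engine, "gas_any", ts("14:59"))[0] is True

    def test_keys_are_independent(self, stable_engine):
        assert cooldown_gate(stable_engine, "motion_presence_2300_2400",
                             ts("23:10"))[0]
        assert cooldown_gate(stable_engine, "tv_presence_2200_2400",
                             ts("23:11"))[0] is True

    def test_spacing_invariant_random_streams(self):
        """Emitted same-key alerts are never closer than the cooldown."""
        rng = np.random.default_rng(7)
        gas_rules = Ruleset(rules=[default_ruleset().get("gas_any")])
        for _ in range(200):
            minutes = np.sort(rng.choice(1440, size=rng.integers(2, 60),
                                         replace=False))
            engine = Engine(gas_rules, phase=Phase.stable)
            emitted = []
            for m in minutes:
                t = dt.datetime.combine(DAY, dt.time(int(m) // 60, int(m) % 60))
                emitted += engine.step(t, events=[SensorEvent(t, SensorKind.gas_presence)])
            times = [a.timestamp for a in emitted]
            for a, b in zip(times, times[1:]):
                assert b - a >= dt.timedelta(minutes=30)


class TestMetaRules:
    def _fire_meta(self):
        return next(m for m in default_ruleset().metas
                    if m.kind == MetaKind.fire_temp_rise)

    def test_fire_coinciding_with_rise(self, stable_engine):
        stable_engine.step(ts("21:55"), [temp("21:55", 21.2)])
        stable_engine.step(ts("21:56"), [temp("21:56", 21.3)],
                           [ev("21:56", SensorKind.fire)])
        alerts = stable_engine.step(ts("21:57"), [temp("21:57", 22.3)])
        assert [(a.rule_id, a.severity) for a in alerts] == [
            ("meta_fire_temp", Severity.emergency)]
        assert eval_meta(self._fire_meta(), stable_engine, ts("21:57")) is True

    def test_fire_too_early_for_rise(self, stable_engine):
        """Fire at 13:39-13:40 but the rise completes at 14:00: outside
        the coincidence window, so no fire alert."""
        stable_engine.step(ts("13:39"), [temp("13:39", 21.0)],
                           [ev("13:39", SensorKind.fire)])
        stable_engine.step(ts("13:40"), [temp("13:40", 21.0)],
                           [ev("13:40", SensorKind.fire)])
        stable_engine.step(ts("13:59"), [temp("13:59", 21.9)])
        alerts = stable_engine.step(ts("14:00"), [temp("14:00", 23.9)])
        assert [a.rule_id for a in alerts] == ["temp_delta"]
        assert eval_meta(self._fire_meta(), stable_engine, ts("14:00")) is False

    def test_fire_alone_never_alerts(self, stable_engine):
        alerts = stable_engine.step(ts("12:30"), events=[ev("12:30", SensorKind.fire)])
        assert alerts == []

    def test_fire_plain_rule_can_be_restored(self):
        engine = Engine(default_ruleset(),
                        EngineConfig(fire_plain_rule_enabled=True),
                        phase=Phase.stable)
        alerts = engine.step(ts("12:30"), events=[ev("12:30", SensorKind.fire)])
        assert [a.rule_id for a in alerts] == ["fire_any"]

    def test_motion_tv_single_notification(self, stable_engine):
        stable_engine.step(ts("02:00"), events=[ev("02:00", SensorKind.motion)])
        alerts = stable_engine.step(ts("02:03"),
                                    events=[ev("02:03", SensorKind.tv_remote)])
        # One combined notification; the TV component is suppressed.
        assert [a.rule_id for a in alerts] == ["meta_motion_tv"]

    def test_motion_low_light(self, stable_engine):
        stable_engine.step(ts("03:00"), [PeriodicReading(
            ts("03:00"), SensorKind.light, 0.4)])
        alerts = stable_engine.step(ts("03:01"),
                                    events=[ev("03:01", SensorKind.motion)])
        assert "meta_motion_low_light" in [a.rule_id for a in alerts]

    def test_suppression_never_increases_alerts(self):
        from homewatch import fixture_fire_day
        def total(suppress):
            rs = default_ruleset()
            rs.metas = [MetaRule(m.meta_id, m.kind, m.severity, m.mutability,
                                 m.coincidence_window_min, suppress, m.delta)
                        for m in rs.metas]
            engine = Engine(rs, EngineConfig(fire_plain_rule_enabled=True),
                            phase=Phase.stable)
            return len(engine.run_day(fixture_fire_day()))
        assert total(True) <= total(False)


class TestStepAndRunDay:
    def test_gas_event_alerts_in_stable_phase(self, stable_engine):
        alerts = stable_engine.step(ts("12:30"),
                                    events=[ev("12:30", SensorKind.gas_presence)])
        assert [a.rule_id for a in alerts] == ["gas_any"]

    def test_calibration_emits_nothing(self):
        engine = Engine(default_ruleset(), phase=Phase.calibration)
        alerts = engine.step(ts("12:00"),
                             events=[ev("12:00", SensorKind.gas_presence)])
        assert alerts == []

    def test_time_going_backwards_rejected(self, stable_engine):
        stable_engine.step(ts("12:00"))
        with pytest.raises(ValueError):
            stable_engine.step(ts("11:59"))

    def test_absence_alerts_on_empty_day(self, stable_engine):
        alerts = stable_engine.run_day(flat_temp_day())
        assert [(str(a.timestamp.time()), a.rule_id) for a in alerts] == [
            ("12:00:00", "motion_absence_0900_1200"),
            ("18:00:00", "motion_absence_1600_1800")]

    def test_absence_silent_when_activity_seen(self, stable_engine):
        day = flat_temp_day(events=[ev("10:00", SensorKind.motion),
                                    ev("16:30", SensorKind.motion)])
        assert stable_engine.run_day(day) == []

    def test_absence_not_decided_before_range_end(self, stable_engine):
        for m in range(16 * 60, 18 * 60):
            alerts = stable_engine.step(
                dt.datetime.combine(DAY, dt.time(m // 60, m % 60)))
            assert alerts == []
        alerts = stable_engine.step(ts("18:00"))
        assert [a.rule_id for a in alerts] == ["motion_absence_1600_1800"]

    def test_absence_duality_motion_every_minute(self, stable_engine):
        day = flat_temp_day(events=[
            SensorEvent(dt.datetime.combine(DAY, dt.time(m // 60, m % 60)),
                        SensorKind.motion) for m in range(540, 720)] + [
            SensorEvent(dt.datetime.combine(DAY, dt.time(m // 60, m % 60)),
                        SensorKind.motion) for m in range(960, 1080)])
        # Activity throughout both usual ranges: zero absence alerts, but
        # no unusual-hours motion either.
        assert stable_engine.run_day(day) == []

    def test_run_day_calibration_always_silent(self):
        engine = Engine(default_ruleset(), phase=Phase.calibration)
        day = flat_temp_day(events=[ev("02:00", SensorKind.motion),
                                    ev("12:30", SensorKind.gas_presence)])
        assert engine.run_day(day) == []

    def test_out_of_order_trace_rejected(self, stable_engine):
        stable_engine.run_day(flat_temp_day())
        with pytest.raises(ValueError):
            stable_engine.run_day(flat_temp_day())


class TestThresholdOracle:
    def test_threshold_and_delta_match_brute_force(self):
        """Engine alert minutes (with throttling disabled) equal a direct
        per-minute comparison on random temperature traces."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            values = np.round(rng.uniform(5.0, 45.0, 1440), 2)
            readings = [PeriodicReading(
                dt.datetime.combine(DAY, dt.time(m // 60, m % 60)),
                SensorKind.temperature, float(values[m])) for m in range(1440)]
            day = DailyTrace(date=DAY, readings=readings)
            rs = Ruleset(rules=[default_ruleset().get(r)
                                for r in ("temp_low", "temp_high", "temp_delta")])
            engine = Engine(rs, EngineConfig(cooldown_min=0), phase=Phase.stable)
            got = {}
            for a in engine.run_day(day):
                got.setdefault(a.rule_id, []).append(
                    a.timestamp.hour * 60 + a.timestamp.minute)
            expected = {
                "temp_low": np.nonzero(values < 15.0)[0].tolist(),
                "temp_high": np.nonzero(values > 38.0)[0].tolist(),
                "temp_delta": (np.nonzero(np.diff(values) >= 2.0)[0] + 1).tolist(),
            }
            for rule_id, minutes in expected.items():
                assert got.get(rule_id, []) == minutes
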