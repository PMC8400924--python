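"""Adaptive rule life-cycle: calibration, readjustment, stable review.

The system learns which hours of the day are *usual* for each activity
channel (motion, TV-remote use) by accumulating, per time bin, the
number of observed days with at least one qualifying event.  A bin is
usual once it was active on at least ``usual_fraction`` of observed
days.  Maximal runs of usual bins become absence-in-range rules (alert
if the activity is missing), maximal runs of unusual bins become
presence-in-range rules (alert if the activity appears); for the TV
remote only presence rules are built.

Life-cycle phases over consecutive days:

* calibration (first ``calibration_days``): accumulate and re-derive
  rules daily, emit no alerts;
* readjustment (next ``readjustment_days``): keep adapting daily, with
  alerting enabled;
* stable: rules change only through :func:`stable_review`, which looks
  for alert groups repeating in the same context (same time bin, or
  same weekday and time bin) and shrinks the offending ranges.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    MINUTES_PER_DAY,
    Alert,
    DailyTrace,
    SensorKind,
    TimeRange,
    make_time_range,
    normalize_ranges,
    subtract_range,
)
from .rules import (
    Engine,
    Mutability,
    Phase,
    Rule,
    RuleKind,
    RuleParams,
    Ruleset,
)

#: Channels whose daily activity drives learned time-range rules.
LEARNED_SENSORS = (SensorKind.motion, SensorKind.tv_remote)


@dataclass
class LearningConfig:
    calibration_days: int = 14
    readjustment_days: int = 14
    usual_fraction: float = 0.5
    repeat_threshold: int = 3
    review_window_days: int = 28
    bin_width: int = 60

    def __post_init__(self) -> None:
        if min(self.calibration_days, self.readjustment_days,
               self.repeat_threshold, self.review_window_days, self.bin_width) < 1:
            raise ValueError("all learning parameters must be positive")
        if not 0 < self.usual_fraction <= 1:
            raise ValueError("usual_fraction must lie in (0, 1]")
        if MINUTES_PER_DAY % self.bin_width:
            raise ValueError("bin_width must divide 1440")


def binarize_day(trace: DailyTrace, sensor: SensorKind, bin_width: int = 60,
                 threshold: Optional[float] = None) -> np.ndarray:
    """Boolean activity vector: bin b is true iff it holds ≥1 qualifying
    record.  Event channels qualify by occurrence; periodic channels need
    an explicit ``threshold`` (value ≥ threshold counts as active)."""
    if MINUTES_PER_DAY % bin_width:
        raise ValueError("bin_width must divide 1440")
    n_bins = MINUTES_PER_DAY // bin_width
    active = np.zeros(n_bins, dtype=bool)
    if sensor.is_event:
        for ev in trace.events_of(sensor):
            active[ev.minute // bin_width] = True
    elif threshold is not None:
        for r in trace.readings_of(sensor):
            if r.value >= threshold:
                active[r.minute // bin_width] = True
    else:
        raise ValueError(f"periodic channel {sensor.value} needs a threshold")
    return active


@dataclass
class BehaviorProfile:
    """Per-bin counts of active days for one channel."""

    sensor: SensorKind
    bin_width: int = 60
    days_observed: int = 0
    counts: np.ndarray = None  # type: ignore[assignment]
    per_weekday_counts: np.ndarray = None  # type: ignore[assignment]
    dates_seen: set[dt.date] = field(default_factory=set)

    def __post_init__(self) -> None:
        n_bins = MINUTES_PER_DAY // self.bin_width
        if self.counts is None:
            self.counts = np.zeros(n_bins, dtype=int)
        if self.per_weekday_counts is None:
            self.per_weekday_counts = np.zeros((7, n_bins), dtype=int)

    @property
    def n_bins(self) -> int:
        return MINUTES_PER_DAY // self.bin_width

    def usual_bins(self, usual_fraction: float) -> np.ndarray:
        if self.days_observed == 0:
            return np.zeros(self.n_bins, dtype=bool)
        return self.counts / self.days_observed >= usual_fraction


def accumulate_profile(profile: BehaviorProfile, trace: DailyTrace) -> BehaviorProfile:
    """Fold one day's activity into the profile (in place; returned for
    chaining).  A date may be accumulated only once."""
    if trace.date in profile.dates_seen:
        raise ValueError(f"{trace.date} already accumulated")
    active = binarize_day(trace, profile.sensor, profile.bin_width)
    profile.counts += active
    profile.per_weekday_counts[trace.date.weekday()] += active
    profile.days_observed += 1
    profile.dates_seen.add(trace.date)
    return profile


def _runs_of(mask: np.ndarray, bin_width: int) -> list[TimeRange]:
    """Maximal runs of true bins as time ranges."""
    ranges: list[TimeRange] = []
    start = None
    for b, on in enumerate(mask):
        if on and start is None:
            start = b
        elif not on and start is not None:
            ranges.append(make_time_range(start * bin_width, b * bin_width))
            start = None
    if start is not None:
        ranges.append(make_time_range(start * bin_width, len(mask) * bin_width))
    return ranges


def _range_rule(sensor: SensorKind, kind: RuleKind, r: TimeRange) -> Rule:
    tag = "absence" if kind == RuleKind.absence_in_range else "presence"
    rule_id = f"{sensor.value}_{tag}_{r.start:04d}_{r.end_exclusive:04d}"
    return Rule(rule_id, kind, sensor, params=RuleParams(ranges=(r,)))


def derive_range_rules(profile: BehaviorProfile, cfg: LearningConfig) -> list[Rule]:
    """Turn the profile into presence/absence time-range rules.

    Usual runs → absence rules, unusual runs → presence rules; for the
    TV remote only presence rules (single structure) are built.
    """
    if profile.days_observed < 1:
        raise ValueError("profile has no observed days")
    usual = profile.usual_bins(cfg.usual_fraction)
    rules: list[Rule] = []
    for r in _runs_of(~usual, profile.bin_width):
        rules.append(_range_rule(profile.sensor, RuleKind.presence_in_range, r))
    if profile.sensor != SensorKind.tv_remote:
        for r in _runs_of(usual, profile.bin_width):
            rules.append(_range_rule(profile.sensor, RuleKind.absence_in_range, r))
    return rules


def reconcile_rules(old: Ruleset | Sequence[Rule], derived: Sequence[Rule],
                    cfg: LearningConfig) -> Ruleset:
    """Replace the learned-sensor range rules with the freshly derived
    set; everything else passes through.

    The profile is cumulative, so "expanding or decreasing the hour
    ranges" is realized as re-derivation: the derived rules already
    embody the reconciled ranges.  Permanent rules are never touched.
    """
    if isinstance(old, Ruleset):
        old_rules, metas = old.rules, old.metas
    else:
        old_rules, metas = list(old), []
    for rule in derived:
        if rule.mutability == Mutability.permanent:
            raise ValueError(f"cannot re-derive permanent rule {rule.rule_id}")
        if rule.sensor not in LEARNED_SENSORS:
            raise ValueError(f"derived rule for unlearned sensor {rule.sensor}")
    learned_kinds = {RuleKind.presence_in_range, RuleKind.absence_in_range}
    kept = [r for r in old_rules
            if not (r.sensor in LEARNED_SENSORS and r.kind in learned_kinds
                    and r.mutability == Mutability.modifiable)]
    merged: list[Rule] = kept + _merge_derived(derived)
    return Ruleset(rules=merged, metas=metas)


def _merge_derived(derived: Sequence[Rule]) -> list[Rule]:
    """Normalize the ranges of derived rules per (sensor, kind)."""
    grouped: dict[tuple[SensorKind, RuleKind], list[TimeRange]] = {}
    for rule in derived:
        grouped.setdefault((rule.sensor, rule.kind), []).extend(rule.params.ranges)
    out: list[Rule] = []
    for (sensor, kind), ranges in grouped.items():
        for r in normalize_ranges(ranges):
            out.append(_range_rule(sensor, kind, r))
    return out


@dataclass
class AlertLog:
    """Append-only alert history with weekday/time-bin annotations."""

    alerts: list[Alert] = field(default_factory=list)
    bin_width: int = 60

    def append(self, alerts: Sequence[Alert]) -> None:
        self.alerts.extend(alerts)

    def annotated(self) -> list[tuple[Alert, int, int]]:
        """(alert, weekday, bin) triples, both derivable from timestamps."""
        return [(a, a.timestamp.weekday(),
                 (a.timestamp.hour * 60 + a.timestamp.minute) // self.bin_width)
                for a in self.alerts]


def phase_for_day(day_index: int, cfg: LearningConfig) -> Phase:
    if day_index < cfg.calibration_days:
        return Phase.calibration
    if day_index < cfg.calibration_days + cfg.readjustment_days:
        return Phase.readjustment
    return Phase.stable


def advance_day(state: Engine, profiles: dict[SensorKind, BehaviorProfile],
                trace: DailyTrace, cfg: LearningConfig,
                log: AlertLog | None = None,
                ) -> tuple[Engine, dict[SensorKind, BehaviorProfile], list[Alert]]:
    """Run one day through the engine and apply the phase's adaptation.

    Calibration and readjustment both accumulate the day into the
    profiles, re-derive the range rules and reconcile them into the
    ruleset; calibration additionally suppresses all alerts.  The stable
    phase only logs alerts (rule changes go through review).
    """
    for sensor in LEARNED_SENSORS:
        profiles.setdefault(sensor, BehaviorProfile(sensor, bin_width=cfg.bin_width))
    state.phase = phase_for_day(state.day_index, cfg)
    alerts = state.run_day(trace)
    if state.phase in (Phase.calibration, Phase.readjustment):
        derived: list[Rule] = []
        for sensor in LEARNED_SENSORS:
            accumulate_profile(profiles[sensor], trace)
            derived.extend(derive_range_rules(profiles[sensor], cfg))
        state.ruleset = reconcile_rules(state.ruleset, derived, cfg)
    if log is not None:
        log.append(alerts)
    state.day_index += 1
    return state, profiles, alerts


@dataclass(frozen=True)
class RuleChange:
    rule_id: str
    action: str  # "shrink_range" | "remove_range" | "weekday_split"
    weekday: Optional[int]
    range: TimeRange
    occurrences: int


@dataclass
class ReviewReport:
    changes: list[RuleChange] = field(default_factory=list)

    def __str__(self) -> str:
        if not self.changes:
            return "review: no repeated alert pattern; ruleset unchanged"
        days = "Mon Tue Wed Thu Fri Sat Sun".split()
        lines = ["review: repeated alert patterns found"]
        for c in self.changes:
            ctx = "all days" if c.weekday is None else days[c.weekday]
            lines.append(f"  {c.rule_id}: {c.action} {c.range} "
                         f"({ctx}, {c.occurrences} repeats)")
        return "\n".join(lines)


def stable_review(log: AlertLog, ruleset: Ruleset, cfg: LearningConfig,
                  now: Optional[dt.datetime] = None) -> tuple[Ruleset, ReviewReport]:
    """Shrink rules whose alerts repeat in the same context.

    Within the trailing ``review_window_days``, alerts are grouped by
    (rule, time bin) across all days and by (rule, weekday, time bin).
    A group reaching ``repeat_threshold`` shrinks the offending range:
    for presence rules the alert's bin is cut out of the ranges; for
    absence rules the whole range containing the bin is dropped.  When
    only the weekday-specific group crosses the threshold, the rule is
    split: the original keeps the other weekdays and a weekday-specific
    variant carries the shrunken ranges.  Permanent rules are never
    modified.
    """
    report = ReviewReport()
    if not log.alerts:
        return ruleset, report
    if now is None:
        now = max(a.timestamp for a in log.alerts)
    horizon = now - dt.timedelta(days=cfg.review_window_days)
    recent = [(a, wd, b) for a, wd, b in log.annotated() if a.timestamp >= horizon]

    all_day_groups: dict[tuple[str, int], int] = {}
    all_day_weekdays: dict[tuple[str, int], set[int]] = {}
    weekday_groups: dict[tuple[str, int, int], int] = {}
    for a, wd, b in recent:
        all_day_groups[(a.rule_id, b)] = all_day_groups.get((a.rule_id, b), 0) + 1
        all_day_weekdays.setdefault((a.rule_id, b), set()).add(wd)
        weekday_groups[(a.rule_id, wd, b)] = weekday_groups.get((a.rule_id, wd, b), 0) + 1

    # A pattern is weekday-independent only if its repeats span more
    # than one weekday; otherwise it belongs to the weekday grouping
    # (which is always a subset of the all-days one).
    def _all_days_crossed(key: tuple[str, int]) -> bool:
        return (all_day_groups[key] >= cfg.repeat_threshold
                and len(all_day_weekdays[key]) >= 2)

    rules = list(ruleset.rules)
    for (rule_id, b), n in sorted(all_day_groups.items()):
        if not _all_days_crossed((rule_id, b)):
            continue
        rules = _apply_shrink(rules, rule_id, b, cfg, weekday=None,
                              occurrences=n, report=report)
    for (rule_id, wd, b), n in sorted(weekday_groups.items()):
        if n < cfg.repeat_threshold:
            continue
        if _all_days_crossed((rule_id, b)):
            continue  # already handled for all days
        rules = _apply_shrink(rules, rule_id, b, cfg, weekday=wd,
                              occurrences=n, report=report)
    return Ruleset(rules=rules, metas=ruleset.metas), report


def _apply_shrink(rules: list[Rule], rule_id: str, b: int, cfg: LearningConfig,
                  weekday: Optional[int], occurrences: int,
                  report: ReviewReport) -> list[Rule]:
    bin_range = make_time_range(b * cfg.bin_width, (b + 1) * cfg.bin_width)
    out: list[Rule] = []
    for rule in rules:
        if rule.rule_id != rule_id:
            out.append(rule)
            continue
        if rule.mutability == Mutability.permanent:
            out.append(rule)
            continue
        if rule.kind == RuleKind.absence_in_range:
            # An absence alert fires at range end; drop the range whose
            # end falls in the offending bin (a range closing exactly at
            # the bin start alerts in that bin, hence <=).
            keep = tuple(r for r in rule.params.ranges
                         if not (bin_range.start <= r.end_exclusive
                                 <= bin_range.end_exclusive))
            dropped = tuple(r for r in rule.params.ranges if r not in keep)
            if not dropped:
                out.append(rule)
                continue
            action = "remove_range"
            new_ranges = keep
            changed_range = dropped[0]
        else:
            new_ranges = tuple(subtract_range(rule.params.ranges, bin_range))
            if new_ranges == rule.params.ranges:
                out.append(rule)
                continue
            action = "shrink_range"
            changed_range = bin_range
        if weekday is None:
            if new_ranges:
                out.append(Rule(rule.rule_id, rule.kind, rule.sensor,
                                rule.mutability,
                                RuleParams(ranges=new_ranges,
                                           threshold=rule.params.threshold,
                                           delta=rule.params.delta,
                                           day_window=rule.params.day_window,
                                           weekdays=rule.params.weekdays)))
            report.changes.append(
                RuleChange(rule.rule_id, action, None, changed_range, occurrences))
        else:
            others = (rule.params.weekdays or frozenset(range(7))) - {weekday}
            out.append(Rule(rule.rule_id, rule.kind, rule.sensor, rule.mutability,
                            RuleParams(ranges=rule.params.ranges,
                                       threshold=rule.params.threshold,
                                       delta=rule.params.delta,
                                       day_window=rule.params.day_window,
                                       weekdays=frozenset(others))))
            if new_ranges:
                out.append(Rule(f"{rule.rule_id}_wd{weekday}", rule.kind,
                                rule.sensor, rule.mutability,
                                RuleParams(ranges=new_ranges,
                                           threshold=rule.params.threshold,
                                           delta=rule.params.delta,
                                           day_window=rule.params.day_window,
                                           weekdays=frozenset({weekday}))))
            report.changes.append(
                RuleChange(rule.rule_id, "weekday_split", weekday,
                           changed_range, occurrences))
    return out
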