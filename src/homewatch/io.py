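"""File formats: trace CSV/JSONL, ruleset JSON, profiles, alert logs.

Trace dialect: header ``timestamp,sensor,record_type,value`` with
ISO-8601 timestamps, ``record_type`` in {periodic, event}, and an empty
``value`` field for events.  The JSONL alternative carries one record
per line with the same fields.
"""

from __future__ import annotations

import datetime as dt
import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    Alert,
    DailyTrace,
    PeriodicReading,
    SensorEvent,
    SensorKind,
    Severity,
    TimeRange,
    make_time_range,
    validate_trace,
)
from .learning import BehaviorProfile, LearningConfig
from .rules import (
    EngineConfig,
    MetaKind,
    MetaRule,
    Mutability,
    Rule,
    RuleKind,
    RuleParams,
    Ruleset,
)
from .simulate import AnomalyKind, AnomalySpec, ResidentConfig

TRACE_HEADER = ["timestamp", "sensor", "record_type", "value"]


class TraceFormatError(ValueError):
    """A malformed row, with file/line context."""


def _parse_row(row: dict, where: str) -> PeriodicReading | SensorEvent:
    try:
        sensor = SensorKind(row["sensor"])
    except ValueError as exc:
        raise TraceFormatError(f"{where}: unknown sensor {row['sensor']!r}") from exc
    ts = dt.datetime.fromisoformat(str(row["timestamp"]))
    kind = row["record_type"]
    value = row.get("value")
    empty = value is None or (isinstance(value, float) and np.isnan(value)) or value == ""
    if kind == "periodic":
        if empty:
            raise TraceFormatError(f"{where}: periodic record without value")
        return PeriodicReading(ts, sensor, float(value))
    if kind == "event":
        if not empty:
            raise TraceFormatError(f"{where}: event record must have empty value")
        return SensorEvent(ts, sensor)
    raise TraceFormatError(f"{where}: bad record_type {kind!r}")


def _group_records(records: Iterable[PeriodicReading | SensorEvent]
                   ) -> list[DailyTrace]:
    by_date: dict[dt.date, tuple[list, list]] = {}
    for rec in records:
        bucket = by_date.setdefault(rec.timestamp.date(), ([], []))
        if isinstance(rec, PeriodicReading):
            bucket[0].append(rec)
        else:
            bucket[1].append(rec)
    return [DailyTrace(date=d, readings=r, events=e)
            for d, (r, e) in sorted(by_date.items())]


def read_traces(path: str | Path, validate: bool = True) -> list[DailyTrace]:
    """Read trace CSV/JSONL file(s); a directory reads every trace file.

    Records from multiple files are merged and grouped by date.
    Validation diagnostics are attached to the module logger.
    """
    path = Path(path)
    files = (sorted(p for p in path.iterdir()
                    if p.suffix in (".csv", ".jsonl"))
             if path.is_dir() else [path])
    records: list[PeriodicReading | SensorEvent] = []
    for f in files:
        if f.suffix == ".jsonl":
            for i, line in enumerate(f.read_text().splitlines(), start=1):
                if line.strip():
                    records.append(_parse_row(json.loads(line), f"{f}:{i}"))
        else:
            frame = pd.read_csv(f, dtype={"value": "object"})
            missing = set(TRACE_HEADER) - set(frame.columns)
            if missing:
                raise TraceFormatError(f"{f}: missing columns {sorted(missing)}")
            for i, row in enumerate(frame.to_dict("records"), start=2):
                records.append(_parse_row(row, f"{f}:{i}"))
    traces = _group_records(records)
    if validate:
        import logging
        log = logging.getLogger(__name__)
        for trace in traces:
            for diag in validate_trace(trace):
                log.warning("%s %s: %s", trace.date, diag.kind, diag.detail)
    return traces


def write_traces(traces: Sequence[DailyTrace], out_dir: str | Path,
                 fmt: str = "csv") -> list[Path]:
    """One file per day, named ``trace_YYYY-MM-DD.{csv,jsonl}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trace in traces:
        rows = [{"timestamp": r.timestamp.isoformat(), "sensor": r.sensor.value,
                 "record_type": "periodic", "value": r.value}
                for r in trace.readings]
        rows += [{"timestamp": e.timestamp.isoformat(), "sensor": e.sensor.value,
                  "record_type": "event", "value": ""}
                 for e in trace.events]
        rows.sort(key=lambda r: (r["timestamp"], r["sensor"]))
        p = out_dir / f"trace_{trace.date.isoformat()}.{fmt}"
        if fmt == "csv":
            pd.DataFrame(rows, columns=TRACE_HEADER).to_csv(p, index=False)
        elif fmt == "jsonl":
            with open(p, "w") as fh:
                for row in rows:
                    fh.write(json.dumps(row) + "\n")
        else:
            raise ValueError(f"unknown trace format {fmt!r}")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Ruleset JSON


def _range_to_json(r: TimeRange) -> list[int]:
    return [r.start, r.end_exclusive]


def ruleset_to_json(ruleset: Ruleset) -> dict:
    rules = []
    for r in ruleset.rules:
        rules.append({
            "rule_id": r.rule_id,
            "kind": r.kind.value,
            "sensor": r.sensor.value,
            "mutability": r.mutability.value,
            "params": {
                "threshold": r.params.threshold,
                "delta": r.params.delta,
                "ranges": [_range_to_json(x) for x in r.params.ranges],
                "day_window": _range_to_json(r.params.day_window),
                "weekdays": (sorted(r.params.weekdays)
                             if r.params.weekdays is not None else None),
            },
        })
    metas = [{
        "meta_id": m.meta_id,
        "kind": m.kind.value,
        "severity": m.severity.value,
        "mutability": m.mutability.value,
        "coincidence_window_min": m.coincidence_window_min,
        "suppress_components": m.suppress_components,
        "delta": m.delta,
    } for m in ruleset.metas]
    return {"rules": rules, "metas": metas}


def ruleset_from_json(doc: dict) -> Ruleset:
    rules = []
    for r in doc.get("rules", []):
        p = r.get("params", {})
        weekdays = p.get("weekdays")
        rules.append(Rule(
            r["rule_id"], RuleKind(r["kind"]), SensorKind(r["sensor"]),
            Mutability(r.get("mutability", "modifiable")),
            RuleParams(
                threshold=p.get("threshold"),
                delta=p.get("delta"),
                ranges=tuple(make_time_range(a, b) for a, b in p.get("ranges", [])),
                day_window=(make_time_range(*p["day_window"])
                            if p.get("day_window") else make_time_range(540, 960)),
                weekdays=frozenset(weekdays) if weekdays is not None else None,
            )))
    metas = [MetaRule(
        m["meta_id"], MetaKind(m["kind"]),
        Severity(m.get("severity", "alert")),
        Mutability(m.get("mutability", "modifiable")),
        m.get("coincidence_window_min"),
        m.get("suppress_components", True),
        m.get("delta"),
    ) for m in doc.get("metas", [])]
    return Ruleset(rules=rules, metas=metas)


def write_ruleset(ruleset: Ruleset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ruleset_to_json(ruleset), indent=2) + "\n")


def read_ruleset(path: str | Path) -> Ruleset:
    return ruleset_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Profile snapshots


def profile_to_json(profile: BehaviorProfile) -> dict:
    return {
        "sensor": profile.sensor.value,
        "bin_width": profile.bin_width,
        "days_observed": profile.days_observed,
        "counts": profile.counts.tolist(),
        "per_weekday_counts": profile.per_weekday_counts.tolist(),
        "dates_seen": sorted(d.isoformat() for d in profile.dates_seen),
    }


def profile_from_json(doc: dict) -> BehaviorProfile:
    return BehaviorProfile(
        sensor=SensorKind(doc["sensor"]),
        bin_width=doc["bin_width"],
        days_observed=doc["days_observed"],
        counts=np.asarray(doc["counts"], dtype=int),
        per_weekday_counts=np.asarray(doc["per_weekday_counts"], dtype=int),
        dates_seen={dt.date.fromisoformat(d) for d in doc["dates_seen"]},
    )


def write_profiles(profiles: dict[SensorKind, BehaviorProfile],
                   path: str | Path) -> None:
    doc = {s.value: profile_to_json(p) for s, p in profiles.items()}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_profiles(path: str | Path) -> dict[SensorKind, BehaviorProfile]:
    doc = json.loads(Path(path).read_text())
    return {SensorKind(k): profile_from_json(v) for k, v in doc.items()}


# ---------------------------------------------------------------------------
# Alert log CSV

ALERT_HEADER = "timestamp,rule_id,severity,message"


def write_alert_log(alerts: Sequence[Alert], path: str | Path) -> int:
    """Append alerts to a CSV log; idempotent across re-runs.

    Alerts at or before the last logged timestamp are skipped, so
    re-running the same day does not duplicate rows.  The file is
    written atomically (temp file + rename).  Returns rows appended.
    """
    path = Path(path)
    last: dt.datetime | None = None
    existing = ""
    if path.exists():
        existing = path.read_text()
        lines = [l for l in existing.strip().splitlines()[1:] if l]
        if lines:
            last = dt.datetime.fromisoformat(lines[-1].split(",")[0])
    new = [a for a in sorted(alerts, key=lambda a: a.timestamp)
           if last is None or a.timestamp > last]
    body = existing if existing else ALERT_HEADER + "\n"
    for a in new:
        msg = a.message.replace(",", ";")
        body += f"{a.timestamp.isoformat()},{a.rule_id},{a.severity.value},{msg}\n"
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(body)
    os.replace(tmp, path)
    return len(new)


def read_alert_log(path: str | Path) -> list[Alert]:
    frame = pd.read_csv(path)
    return [Alert(dt.datetime.fromisoformat(r["timestamp"]), r["rule_id"],
                  Severity(r["severity"]), r["message"])
            for r in frame.to_dict("records")]


# ---------------------------------------------------------------------------
# Run / scenario configuration


def load_engine_config(doc: dict) -> EngineConfig:
    cfg = EngineConfig()
    for key in ("cooldown_min", "coincidence_window_min",
                "fire_plain_rule_enabled", "low_light_threshold"):
        if key in doc:
            setattr(cfg, key, doc[key])
    return cfg


def load_learning_config(doc: dict) -> LearningConfig:
    kwargs = {k: doc[k] for k in (
        "calibration_days", "readjustment_days", "usual_fraction",
        "repeat_threshold", "review_window_days", "bin_width") if k in doc}
    return LearningConfig(**kwargs)


def load_scenario(path: str | Path) -> tuple[ResidentConfig, list[AnomalySpec]]:
    """Scenario YAML: a ``resident`` mapping plus a list of anomalies."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    res = doc.get("resident", {})
    kwargs = {}
    for key in ("motion_rate", "tv_rate", "temp_base", "temp_amplitude",
                "light_day", "light_evening", "light_night", "seed"):
        if key in res:
            kwargs[key] = res[key]
    for key in ("wake", "sleep"):
        if key in res:
            from .core import TimeOfDay
            kwargs[key] = TimeOfDay.parse(res[key])
    if "tv_windows" in res:
        kwargs["tv_windows"] = tuple(make_time_range(a, b)
                                     for a, b in res["tv_windows"])
    if "away_windows" in res:
        kwargs["away_windows"] = tuple((wd, make_time_range(a, b))
                                       for wd, a, b in res["away_windows"])
    if "heating_windows" in res:
        kwargs["heating_windows"] = tuple((make_time_range(a, b), sp)
                                          for a, b, sp in res["heating_windows"])
    cfg = ResidentConfig(**kwargs)
    anomalies = []
    for a in doc.get("anomalies", []):
        at = a["at"]
        if isinstance(at, str):
            at = dt.datetime.fromisoformat(at)
        else:
            at = make_time_range(at[0], at[1])
        anomalies.append(AnomalySpec(AnomalyKind(a["kind"]), at,
                                     a.get("magnitude")))
    return cfg, anomalies
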