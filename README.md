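# homewatch

A rule-based anomaly-alert engine for a single-occupant home instrumented
with one multi-sensor ambient device, plus a synthetic resident simulator
that stands in for the hardware.

Many older adults live alone, and an accident or a sudden change in
routine can go unnoticed for hours or days. `homewatch` watches a stream
of non-intrusive ambient measurements — per-minute temperature, humidity,
pressure, light and gas-level samples, and event-triggered detections
(PIR motion, fire, gas presence, TV-remote IR, shock) — and sends alert
messages to a caregiver when behavior departs from the resident's own
learned routine. The "expert" behind the expert system is the resident:
the IF-THEN rules are parameterized by the activity pattern observed in
the home itself.

## The model

**Rules.** Alerts come from a catalogue of per-minute rules over the
sensor channels:

- temperature thresholds: alert if `T < 15 °C` or `T > 38 °C` (strict);
- temperature rise: alert if `T(t) − T(t−1) ≥ 2 °C` for consecutive
  minutes;
- bedtime heating: the engine stores `T_max = max{T(t) : t ∈ [09:00,
  16:00)}` each day; during the night ranges `[23:00, 24:00)` and
  `[00:00, 07:00)` an alert fires when `T(t) ≥ T_max` (the stored
  maximum persists overnight, so an 02:00 reading is compared against
  the previous afternoon);
- presence-in-range: motion or TV-remote activity inside an *unusual*
  time-of-day range alerts immediately;
- absence-in-range: a *usual* range with no activity alerts once, at the
  minute the range closes;
- light level out of band inside evening/night ranges (< 20 % over
  18:00–21:00, > 1 % over 23:00–05:00);
- gas presence: permanent, alerts on any detection;
- meta-rules over the coincidence of two conditions within a 10-minute
  window, which take priority and send a single notification: motion +
  TV use at an unusual hour, motion in the dark at an unusual hour, and
  fire presence + a ≥ 1 °C/min temperature rise — the only path to a
  fire alert by default (a bare fire detection is a likely false
  positive) and the only emergency-severity message.

**Throttling.** Alerts are deduplicated per rule with an episode model:
an alert opens a 30-minute quiet period, and any further trigger of the
same rule during it is absorbed *and extends the episode*. A second
message for the same rule is only sent after 30 quiet minutes.

**Learning.** Activity channels (motion, TV remote) are binned into
24 one-hour slots per day; a bin is *usual* once it was active on at
least half of the observed days. Maximal runs of usual bins become
absence rules, runs of unusual bins become presence rules. The
life-cycle has three phases: two weeks of silent *calibration*, two
weeks of *readjustment* (daily re-derivation with alerting on), then a
*stable* phase in which rules only change when an alert repeats in the
same context (same hour bin — or same weekday and hour bin, which
produces weekday-specific rules).

## Worked example

The bundled `fixture_fire_day()` reproduces a day of deliberate
environmental alterations: fire and gas detections through the
afternoon and evening, and three abrupt temperature rises completing at
14:00, 19:36 and 21:59.

```python
from homewatch import Engine, Phase, default_ruleset, fixture_fire_day

engine = Engine(default_ruleset(), phase=Phase.stable)
for a in engine.run_day(fixture_fire_day()):
    print(a.timestamp.time(), a.rule_id, a.severity.value)
```

```
12:05:00 gas_any alert
13:05:00 gas_any alert
13:56:00 gas_any alert
14:00:00 temp_delta alert
15:40:00 gas_any alert
17:10:00 gas_any alert
18:40:00 gas_any alert
19:36:00 temp_delta alert
20:40:00 gas_any alert
21:50:00 gas_any alert
21:57:00 meta_fire_temp emergency
21:59:00 temp_delta alert
```

Reading the output: every 2 °C/min rise alerts (`temp_delta` at 14:00,
19:36, 21:59). Of the 23 fire detections only one produces a message —
the 21:56 detection coincides with the 21:54–21:59 temperature rise, so
the fire meta-rule sends a single emergency at 21:57; the detections
around 13:39 are 11+ minutes away from any rise and stay silent. Gas
alerts are episode-throttled: the detection at 14:29 arrives while the
episode opened at 13:56 (and refreshed at 14:10) is still quiet, so no
gas alert falls in 14:00–14:30.

The same flow is available from the shell:

```
homewatch simulate --days 14 --seed 1 --out traces/
homewatch calibrate traces/ --ruleset ruleset.json --profiles profiles.json
homewatch run traces/ --ruleset ruleset.json --alert-log alerts.csv
homewatch review --alert-log alerts.csv --ruleset ruleset.json
homewatch report traces/ --alert-log alerts.csv
```

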