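# Methods

## Scope and data model

`homewatch` operates on a naive local minute clock. Periodic channels
(temperature °C, humidity %, pressure hPa, light %, gas level) carry one
sample per minute; binary channels (motion, fire, gas presence,
TV-remote IR, shock) emit time-stamped events truncated to the minute.
Time-of-day ranges are half-open `[start, end)` in minutes since
midnight and never wrap midnight — a schedule crossing midnight is two
ranges (e.g. the bedtime window is `[23:00, 24:00)` plus
`[00:00, 07:00)`, handled by two independent rules). Trace validation
reports cadence gaps, duplicate minutes and out-of-bound values
(temperature plausibility −20…60 °C) but never repairs: repair policy
belongs to callers. Minutes absent from a trace advance the clock
without evaluating readings, and the consecutive-minute rise rules are
inert across gaps.

## Rule evaluation order and severity

Within each minute, meta-rules are evaluated before single rules, so
their component-suppression stamps take effect first. Threshold
comparisons are strict (`<` / `>`); the bedtime comparison uses `≥`
because a bedtime temperature *equal* to the stored daytime maximum
already indicates the heating is on. Absence rules are only decidable
when their range closes, so they fire exactly once, at the end minute
(ranges ending at midnight are settled during the day-boundary flush).
All messages carry `alert` severity except the fire + temperature-rise
meta-rule, which is the sole source of `emergency`.

Bare fire detections are disabled by default: low-cost flame sensors
false-positive on sunlight and room lighting, so a fire message
requires the corroborating ≥ 1 °C/min temperature rise within the
coincidence window. `EngineConfig.fire_plain_rule_enabled` restores the
literal always-alert behavior.

## Alert throttling: the episode model

The cooldown registry stores, per rule key, the time of the *last
qualifying trigger* — emitted or absorbed. A trigger emits iff the key
is unseen or at least `cooldown_min` (default 30) minutes have passed
since that stamp; either way the stamp moves to now. Consequences:

- consecutive emitted alerts of one rule are always ≥ 30 min apart
  (property-tested over random event streams);
- a continuing condition (gas still present, temperature still above
  the maximum) is treated as **one episode with one message** until a
  full quiet interval elapses, rather than re-alerting every 30 minutes.

The alternative — stamping only on emission — re-alerts a persisting
condition on a fixed 30-minute cycle, which floods the caregiver during
a single long incident. The episode model matches how alert
deduplication is usually done in monitoring systems; its trade-off
(documented under limitations) is that an uninterrupted hours-long
condition produces only the opening message. Meta-rules use their own
key and, when they fire, also stamp the keys of the component rules
whose conditions they consumed — this is the "single notification"
guarantee, and it never increases the total alert count.

## Coincidence window

Meta-rules require both component conditions within a trailing window,
10 minutes by default (configurable per meta-rule). The window is
inclusive at its left edge; the deterministic fire-day fixture places
its unprinted fire detections more than one window away from every
temperature rise so that exactly one coincidence occurs.

## Learning

- **Bin width 60 min.** Routines are described in whole hours; finer
  bins would need more than two weeks of evidence per bin.
- **`usual_fraction` 0.5.** An hour is usual if active on ≥ half of
  observed days. This is the natural majority threshold given no
  stronger prior; it makes the derived ranges a median behavior.
- Profiles are cumulative, and "expanding or decreasing" learned ranges
  is realized as re-derivation from the updated profile: deterministic,
  order-independent, and idempotent under identical days (the ruleset
  reaches a fixed point by the end of calibration). Incremental
  edge-nudging is an extension point, not implemented.
- Phases: 14 silent calibration days, 14 readjustment days with daily
  re-derivation and alerting on, then stable. Only motion and TV-remote
  profiles drive learned range rules; temperature and light thresholds
  stay at their defaults unless configured — no principled adaptation
  procedure exists for them, so they are deliberately manual.
- Weekday stratification exists only in stable review: 14 calibration
  days yield just two samples per weekday, too few to learn from.

## Stable review

Alerts in the trailing 28-day window are grouped by (rule, hour bin)
and by (rule, weekday, hour bin); a group of ≥ 3 repeats triggers a
modification (3 repeats in a month operationalizes "constantly
repeated"). Because the weekday group is a subset of the all-days
group, a single threshold would make weekday splits unreachable: the
all-days grouping therefore only counts as weekday-independent if its
repeats span **at least two distinct weekdays**. Modifications shrink,
never grow: presence rules have the offending hour bin cut out of their
ranges; absence rules drop the range that closes in the offending bin
(a range ending exactly at the bin boundary alerts in that bin, hence
the inclusive edge). A weekday-specific repeat splits the rule into a
general variant excluding that weekday plus a weekday variant with the
shrunken ranges. Permanent rules (gas, fire) are never modified.

## Simulator

The generator emulates the structure the engine assumes, per channel
with an independent RNG substream keyed by `(seed, channel, date)` —
adding a channel never perturbs the others, and traces are
byte-reproducible under `(config, seed)`.

- Motion: Poisson process at 20 events/h between wake (08:00) and sleep
  (23:00), zero outside; per-weekday away windows silence motion and TV.
- TV remote: Poisson at 30 events/h inside the evening window
  (20:00–23:00).
- Temperature: first-order lag (rate 0.15/min) toward a diurnal target
  (base 20 °C, ±2 °C, peak ≈ 16:00) overridden by heating setpoints
  (07:00–09:00 at 22 °C), plus Gaussian noise with SD 0.05 °C — small
  enough that noise alone can never produce a 2 °C/min step.
- Light: stepped day/evening/night levels (60 / 40 / 0.5 %) with 0.2 %
  noise; humidity, pressure and gas level are constant-plus-noise
  filler channels.

Anomaly injection touches only the targeted channel and range:
gas/fire events are merged idempotently; `temp_spike` rewrites the
temperature so a ≥ 2 °C consecutive rise completes at the requested
minute and then decays back; `heating_left_on` holds the night
temperature above the day's 09:00–16:00 maximum; `daytime_absence`
deletes motion in a range; `nocturnal_motion` adds events every five
minutes.

What the simulator does **not** capture: physically accurate thermal
dynamics, multi-occupant homes, visitors, sensor faults and dropouts,
or correlated channel noise. Passing tests therefore demonstrate the
engine's contract on well-formed single-resident data, not robustness
to real-world sensor pathologies.

The deterministic fixtures are hand-constructed, zero-noise traces.
`fixture_fire_day` encodes a printed alteration-day schedule: fire
detections (including 13:39, 13:40, 21:56), gas detections (including
13:56 and 14:29) and three temperature rises completing at 14:00, 19:36
and 21:59, with the 21:54–21:59 rise passing a 1 °C step at 21:57 so
the fire meta-rule fires then. Unprinted event times are fixed minutes
chosen so the alert pattern depends only on the printed times plus
cooldown arithmetic. `fixture_night_temp` uses three consecutive days
(afternoon maxima 21.8 / 21.5 / 23.8 °C) with night exceedances at
02:01, 03:33 and 23:17–23:32; the two early-morning exceedances are
discrete instants, since under episode throttling a continuous
exceedance would collapse into one message.

## Problem sizes and numerics

The randomized checks run at: 1,000 random gas-event streams (2–49
events each) for cooldown spacing; 10 anomaly-salted random days for
calibration silence; 50 random residents × 14 days for schedule
recovery (wake drawn from 05:00–10:00, sleep from 20:00–23:00 on hour
boundaries, matching the hour-bin resolution of the learner); 10 random
temperature days for brute-force rule equivalence (throttling disabled
by setting the cooldown to zero). Simulated values are rounded to two
decimals at generation, so serialized traces round-trip exactly and
rule comparisons are reproducible across platforms.

## Known limitations

- An uninterrupted condition yields a single alert per episode; there
  is no escalation path for long incidents besides the emergency
  severity of the fire meta-rule.
- Ranges cannot wrap midnight; overnight behavior is expressed as two
  ranges with independent cooldown keys, so an episode spanning
  midnight may message twice.
- Threshold-type rules (temperature, light) do not adapt from data.
- Device outages are only diagnosed, not compensated: absence rules
  still fire if an outage swallowed the activity evidence.
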