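# smscare

An offline-testable rule engine for SMS telemonitoring of patients recently
hospitalized for **acute decompensated heart failure (ADHF)**. Readmissions
cluster in the first weeks after discharge, usually heralded by congestion:
nocturnal dyspnea, rapid weight gain from fluid retention, and worsening
fatigue. `smscare` re-creates, as a testable library and CLI, the logic of a
deployed SMS monitoring system: it plans the outbound messages for each
patient's follow-up week, parses the YES/NO and weight replies, and raises
alarms when congestion-like day patterns appear — without any modem, server
or database.

Intended users: digital-health researchers and engineers who need the
*decision logic* of an SMS telemonitoring programme as a reproducible,
simulatable artifact — for protocol design, power analysis of alarm rules, or
regression-testing a production deployment.

## The monitoring model

Each enrolled patient has a follow-up window of `n` days (default 7, the
first post-discharge week). Every day the system sends four **feedback
questions** — two in the morning, two in the evening:

| id         | question                                                         | reply | slot    |
|------------|------------------------------------------------------------------|-------|---------|
| DYSPNEA    | During last night, did you wake up with shortness of breath once? | YES/NO | morning |
| WEIGHT     | What's your weight today?                                         | kg    | morning |
| MEDICATION | Have you taken all your medications today?                        | YES/NO | evening |
| FATIGUE    | Have you felt more tired today than you did yesterday?            | YES/NO | evening |

plus, every other day, a one-way **educational** self-care message (salt
avoidance, symptom awareness, daily weighing). Replies are matched to
questions by shape and arrival order within the calendar day (SMS replies
carry no question reference).

The alarm engine scans each patient's day grid and fires on:

* `DYSPNEA_STREAK` — YES to the dyspnea question on *k* consecutive days (*k* = 2);
* `FATIGUE_STREAK` — YES to the fatigue question on *k* consecutive days;
* `MEDICATION_STREAK` — NO to the medication question on *k* consecutive days;
* `NON_RESPONSE` — zero answers to all four questions on *k* consecutive days;
* `WEIGHT_GAIN` — over a *w*-day window (*w* = 3) of observed weights,
  last − min(window) ≥ 2.0 kg (an endpoint-only last − first variant and a
  symmetric loss rule are available by config).

Every rule is **debounced**: one alarm per uninterrupted qualifying run,
re-arming only after a day on which the condition breaks. Each alarm
notifies both the patient and the hospital manager.

## Worked example

Replay the canonical 10-patient prototype cohort (nine 7-day windows plus
one 3-day window for a patient re-hospitalized with acute coronary
syndrome), shipped with the package:

```bash
smscare replay --fixture prototype --out-dir out/
```

prints

```json
{
  "alarms_by_rule": {
    "DYSPNEA_STREAK": 3,
    "FATIGUE_STREAK": 4,
    "MEDICATION_STREAK": 0,
    "NON_RESPONSE": 0,
    "WEIGHT_GAIN": 0,
    "WEIGHT_LOSS": 0
  },
  "feedback_answered": 247,
  "feedback_sent": 264,
  "feedback_unanswered": 17,
  "n_patients": 10,
  "per_question": {
    "DYSPNEA":    {"answered": 61, "sent": 66},
    "FATIGUE":    {"answered": 63, "sent": 66},
    "MEDICATION": {"answered": 61, "sent": 66},
    "WEIGHT":     {"answered": 62, "sent": 66}
  },
  "unanswered_by_reason": {
    "FORGOT": 3,
    "NOT_SEEN": 4,
    "POWER_OUTAGE": 10
  }
}
```

Reading: 264 feedback questions were due across the cohort (9×7×4 + 1×3×4);
247 drew a reply and 17 did not (10 lost to a power outage, 4 unseen, 3
forgotten). The engine fired 7 alarms — three patients with two consecutive
nights of dyspnea, four with two consecutive days of worsening fatigue —
and none for weight gain, missed medication or silence. `out/` additionally
holds the session grid, resolved schedule and alarm CSVs, notification and
transport JSONL logs, and this summary as `summary.json`.

Other subcommands:

```bash
smscare simulate --seed 1 --patients 10 --days 7 --out-dir out/   # synthetic cohort
smscare report --inbound log.csv --profiles patients.csv --out-dir out/
smscare validate-config config.yaml
```

`simulate` is seed-deterministic (same seed, byte-identical artifacts).
Inbound logs are CSV (`patient_id,date,time,raw_text`) or JSON lines;
enrollment CSVs are `patient_id,follow_up_start,follow_up_days` plus
arbitrary metadata columns (`site` enables per-hospital scoping via
`--site`). The full system configuration — question and educational
catalogs, schedule times, alarm thresholds — round-trips through one YAML
file; see `smscare.core_model.save_config` for the schema.

## Library surface

```python
from smscare import (
    prototype_cohort, generate_cohort, SimConfig,      # cohorts
    build_schedule, apply_responses,                   # scheduling
    parse_binary, parse_weight, attach, replay_log,    # inbound parsing
    evaluate, dispatch, AlarmRuleConfig,               # alarm engine
    summarize, run_pipeline,                           # aggregation
)
```

`docs/methods.md` describes the model, its assumptions, every tunable
parameter, and what the simulator does and does not emulate.

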