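# Methods

## The monitoring procedure

One patient's follow-up is a grid: `follow_up_days` rows (day 1 = the first
post-discharge monitoring day, a local calendar date) by four feedback
questions. The scheduler emits all four questions every day — two per slot —
and an educational message on days `educational_first_day`,
`+educational_period_days`, … cycling the educational catalog in order.
Messages, replies and alarms are all day-granular: the configured clock
times (08:00 / 20:00 by default) order the batches and stamp the logs but
never enter any rule. A feedback message is ANSWERED exactly when the day's
record holds any parsed answer for its question — including an INVALID one,
because an unparseable reply is still a responding patient; the distinction
matters only to the alarm predicates.

## Reply parsing and attachment

Binary replies are matched case-insensitively after Unicode NFC
normalization against configurable affirmative/negative token sets
(defaults: yes/sim, no/não/nao — the deployment language was Portuguese).
Weight replies accept one decimal number with dot or comma separator and an
optional trailing `kg`, bounded to the open interval (0, 500) kg as a data
plausibility guard.

SMS replies carry no reference to the question they answer, so attachment is
a deterministic convention: within the calendar day of receipt, a binary
reply fills the oldest unanswered binary question in slot order (morning
first, catalog order within a slot); a numeric reply fills the weight
question; an invalid reply fills the oldest unanswered question of any kind
(recording that the patient responded). A reply that finds no open question
that day is logged and discarded — first answer wins — and replies never
cross the local-midnight day boundary. Exact duplicates (same date, time and
text) are discarded via a per-session fingerprint set, which makes replaying
a whole inbound log idempotent. The cost of order-based matching is that a
day with one of two same-slot binary questions unanswered cannot be
reconstructed unambiguously from a raw log; the session-grid CSV (which
carries question ids) is therefore the lossless interchange format, and the
raw-log round trip is exact only for fully-answered days.

## Alarm rules

All five checks share one debounced-streak core. Scanning days in order,
a rule's day-level predicate either extends the current qualifying run or
breaks it; the rule fires once when a run first reaches its threshold and
cannot fire again until a predicate-breaking day re-arms it. Hence a 7-day
YES run produces exactly one alarm (on day 2 under the default threshold),
and YES,YES,NO,YES,YES produces two. Runs never extend before day 1 — there
is no pre-enrollment history.

Predicates:

* symptom streaks — DYSPNEA = YES, FATIGUE = YES, MEDICATION = NO on
  `symptom_streak_days` consecutive days. Missing *and* INVALID answers
  break these runs: only an explicit symptomatic answer extends a streak.
* non-response — a day with zero answers across all four questions,
  `nonresponse_streak_days` in a row. Partial responders are not
  non-responders, and an INVALID reply defeats the silent day.
* weight — over the `weight_window_days` most recent days, *all* carrying a
  numeric weight, gain = last − min(window) ≥ `weight_gain_kg`. The
  min-in-window form is the clinically conservative reading of "2 kg in 3
  days": it catches a dip-then-surge trajectory whose endpoints differ by
  less than the threshold. `weight_endpoint_only=True` switches to
  last − first for the strict endpoint reading. A symmetric loss rule
  (max(window) − last ≥ `weight_loss_kg`) exists because weight *loss*
  tendency is also clinically monitored, but no loss threshold was ever
  specified for the deployed flowchart, so it ships disabled
  (`weight_loss_kg=None`). A day lacking a numeric weight yields no
  complete window and also re-arms the rule.

Every alarm is dispatched as one notification addressed to both the patient
and the hospital manager; escalation and acknowledgment are out of scope.

### Parameters

| parameter | unit | default | why |
|---|---|---|---|
| `symptom_streak_days` | days | 2 | deployed flowchart: "two consecutive days" |
| `nonresponse_streak_days` | days | 2 | deployed flowchart |
| `weight_gain_kg` | kg | 2.0 | deployed flowchart: 2 kg threshold |
| `weight_window_days` | days | 3 | deployed flowchart: 3-day window |
| `weight_loss_kg` | kg | disabled | no published loss threshold |
| `weight_endpoint_only` | — | false | min-in-window is the conservative default |
| `educational_period_days` / `educational_first_day` | days | 2 / 2 | "every two days"; the day-2 anchor is a convention (no anchor was published), giving 3 educational messages in a 7-day window |
| `morning_time` / `evening_time` | clock | 08:00 / 20:00 | ordering/labels only |

## The canonical prototype cohort

The original prototype test enrolled 10 patients (LVEF ≤ 45 %, first week
after discharge); published are only the marginal counts: 264 feedback
messages sent, 247 answered; per-question answered counts 61 (dyspnea),
61 (medication), 62 (weight), 63 (fatigue); 17 unanswered messages tagged
10 power-outage / 4 not-seen / 3 forgotten; 7 alarms (3 two-day dyspnea
streaks, 4 two-day fatigue streaks, no weight/medication/non-response
alarms); one patient stopped at day 3 after readmission for acute coronary
syndrome.

Those marginals do not determine the day-by-day grid, so the shipped
fixture (`src/smscare/data/prototype_cohort.csv`, a synthetic
reconstruction) fixes the remaining freedom by documented convention:

* one low-adherence patient (P08) concentrates {dyspnea 2/7, medication 3/7,
  weight 3/7, fatigue 5/7} and a second (P09) holds {medication 6/7, fatigue
  6/7} — the fewest irregular patients consistent with the marginals;
* P08's answered cells are spread so that no day is completely silent
  (the published alarms include no non-response alarm);
* the seven alarm-bearing patients (P01–P03 dyspnea, P04–P07 fatigue) are
  fully adherent, pairwise distinct and distinct from the low-adherence
  patients, with YES-runs of exactly length 2 on days 4–5;
* all medication answers are YES and every patient's weight is constant,
  so neither of those rules can fire.

`prototype_cohort()` re-validates every one of these constraints (plus the
totals) each time it loads the file and refuses to return a drifted grid.
An alternative allocation of the low-adherence counts across more patients
would reproduce the same published totals; the summary statistics are
invariant to that choice, only per-patient narratives differ.

## The simulator

`generate_cohort(SimConfig(...))` draws each answer independently: present
with probability `response_prob`; present binary answers are YES with the
daily symptom probabilities (dyspnea, fatigue) or NO with the
medication-miss probability; weights follow baseline + drift·day + Gaussian
noise, rounded to 0.1 kg (SMS precision). An optional outage window blanks
a contiguous run of days for one patient and tags the cells POWER_OUTAGE.
All draws come from one `numpy.random.default_rng(seed)` stream with a
fixed draw layout, so equal seed and config give bit-identical cohorts.

Defaults describe the prototype-test conditions: 10 patients × 7 days,
response probability 0.94 (the observed 247/264 rate), medication-miss 0
and weight drift 0 (both behaviours absent in the test), symptom
probabilities 0.12 (dyspnea) and 0.18 (fatigue) — chosen once so that a
minority of patients accrue a 2-day streak within a week, matching the
3-of-10 / 4-of-10 orders of magnitude.

What the simulator does **not** emulate: within-patient correlation of
symptoms over days (answers are i.i.d. given the rates), correlation
between questions, behavioural drift in adherence, reply-text noise
(misspellings, multi-token replies), delivery failures and carrier
blocking, or clock-time behaviour. Passing tests on simulated cohorts
therefore demonstrate the *engine's* correctness and invariants
(conservation, determinism, oracle equivalence), not that real patients
behave like the generator.

## Numerical and design notes

* Thresholds compare with `>=` on floats; weights are rounded to 0.1 kg at
  generation/parse time, so comparisons sit well away from float noise.
* The default catalog uses the medication question (the one the alarm
  flowchart and the published results table reference); the meals question
  from the original feedback list is provided as an optional catalog entry
  (`meals_question()`) since the two sources disagree and no alarm rule
  watches meals.
* Degenerate inputs: a 0-question catalog is a configuration error; a
  streak threshold longer than the window can never fire (tested); an empty
  cohort summarizes to all zeros; INVALID weight replies break weight
  windows exactly like missing ones.
* Ties/ordering: alarms are reported sorted by (day, rule declaration
  order); schedule rows by (day, slot).
* The transport layer is a protocol with a single in-memory implementation
  that records an append-only message log; a real GSM modem driver is a
  plug-in point, deliberately not shipped.

## Problem sizes

The shipped grids and tests are small by nature of the domain: the
canonical cohort is 10 patients × ≤ 7 days; property tests run hundreds of
hypothesis cases plus a 1 000-session seeded sweep against brute-force
oracles on windows up to 14 days. The whole suite completes in a few
seconds on one CPU.
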