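"""Synthetic cohorts and the canonical prototype-test cohort.

``generate_cohort`` draws day grids with configurable adherence, symptom
and weight structure (seeded, bit-reproducible) for stress-testing the
scheduler and alarm engine.  ``prototype_cohort`` loads the versioned
10-patient grid that reproduces the published prototype test: 264 feedback
messages sent, 247 answered, 17 unanswered (10 during a power outage,
4 not seen, 3 forgotten), and exactly 7 alarms — 3 two-day nocturnal
dyspnea streaks and 4 two-day fatigue streaks — with no weight-gain,
medication or non-response alarms.  Only marginal counts were published;
the exact day placement in the shipped grid is a documented convention
validated by the loader.

Both kinds of cohort serialize to the same long-format session CSV
(one row per patient-day-question cell) and can be flattened to the
inbound-log format the response parser consumes.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import (
    AnswerValue,
    ConfigurationError,
    MissingReason,
    MonitoringSession,
    ParsedAnswer,
    PatientProfile,
    Question,
    QuestionId,
    ScheduleConfig,
    Slot,
    default_question_catalog,
    validate_session,
)
from .response_parser import InboundRaw

__all__ = [
    "OutageWindow",
    "SimConfig",
    "FixtureError",
    "generate_cohort",
    "prototype_cohort",
    "sessions_to_frame",
    "sessions_to_csv",
    "sessions_from_frame",
    "sessions_from_csv",
    "cohort_to_inbound_log",
    "DEFAULT_START_DATE",
]

# Anchor date for simulated enrollments (the prototype test period).
DEFAULT_START_DATE = dt.date(2017, 9, 4)

_QUESTION_ORDER = (
    QuestionId.DYSPNEA,
    QuestionId.WEIGHT,
    QuestionId.MEDICATION,
    QuestionId.FATIGUE,
)


class FixtureError(RuntimeError):
    """The shipped prototype grid violates one of its published constraints."""


@dataclass(frozen=True)
class OutageWindow:
    """A contiguous run of fully-missed days for one patient (0-based index),
    emulating e.g. a storm-induced power outage."""

    patient_index: int
    start_day: int
    n_days: int


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator settings.

    Defaults mirror the prototype test conditions: 10 patients followed for
    7 days, ~94% per-message response probability, perfect medication
    adherence and weight stability; daily symptom probabilities are set so a
    minority of patients accrue a 2-day streak within the week.
    """

    n_patients: int = 10
    follow_up_days: int = 7
    response_prob: float = 0.94
    dyspnea_prob: float = 0.12
    fatigue_prob: float = 0.18
    medication_miss_prob: float = 0.0
    weight_baseline_kg: float = 75.0
    weight_drift_kg_per_day: float = 0.0
    weight_noise_sd_kg: float = 0.3
    outage: OutageWindow | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("response_prob", "dyspnea_prob", "fatigue_prob", "medication_miss_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.follow_up_days < 1 or self.n_patients < 0:
            raise ConfigurationError("n_patients >= 0 and follow_up_days >= 1 required")
        if self.weight_noise_sd_kg < 0:
            raise ConfigurationError("weight_noise_sd_kg must be >= 0")


def _binary(value: AnswerValue) -> ParsedAnswer:
    return ParsedAnswer(value, "YES" if value is AnswerValue.YES else "NO")


def _weight(kg: float) -> ParsedAnswer:
    return ParsedAnswer(AnswerValue.NUMERIC, f"{kg:.1f}", numeric_value=round(kg, 1))


def generate_cohort(cfg: SimConfig) -> list[MonitoringSession]:
    """Draw a cohort; identical (cfg, seed) gives a bit-identical cohort.

    Each answer is present independently with ``response_prob``; present
    binary answers follow the symptom/medication probabilities; weights are
    baseline + drift x day + Gaussian noise, rounded to 0.1 kg.  Outage days
    drop all four answers and are tagged POWER_OUTAGE.
    """
    rng = np.random.default_rng(cfg.seed)
    sessions: list[MonitoringSession] = []
    for p in range(cfg.n_patients):
        profile = PatientProfile(
            patient_id=f"SIM-{p + 1:03d}",
            follow_up_start=DEFAULT_START_DATE,
            follow_up_days=cfg.follow_up_days,
        )
        session = MonitoringSession.empty(profile)
        for rec in session.records:
            d = rec.day_index
            # draw every variate unconditionally: the stream layout is stable
            responded = rng.random(4) < cfg.response_prob
            dysp = rng.random() < cfg.dyspnea_prob
            fat = rng.random() < cfg.fatigue_prob
            miss = rng.random() < cfg.medication_miss_prob
            noise = rng.normal(0.0, 1.0) * cfg.weight_noise_sd_kg
            kg = cfg.weight_baseline_kg + cfg.weight_drift_kg_per_day * d + noise
            kg = float(np.clip(round(kg, 1), 0.1, 499.9))
            values = {
                QuestionId.DYSPNEA: _binary(AnswerValue.YES if dysp else AnswerValue.NO),
                QuestionId.WEIGHT: _weight(kg),
                QuestionId.MEDICATION: _binary(AnswerValue.NO if miss else AnswerValue.YES),
                QuestionId.FATIGUE: _binary(AnswerValue.YES if fat else AnswerValue.NO),
            }
            outage_day = (
                cfg.outage is not None
                and p == cfg.outage.patient_index
                and cfg.outage.start_day <= d < cfg.outage.start_day + cfg.outage.n_days
            )
            for i, qid in enumerate(_QUESTION_ORDER):
                if outage_day:
                    session.missing_reasons[(d, qid)] = MissingReason.POWER_OUTAGE
                elif responded[i]:
                    rec.answers[qid] = values[qid]
                else:
                    session.missing_reasons[(d, qid)] = MissingReason.UNSPECIFIED
        sessions.append(session)
    return sessions


# ---------------------------------------------------------------------------
# Long-format session CSV (one row per patient-day-question cell)
# ---------------------------------------------------------------------------

SESSION_COLUMNS = [
    "patient_id",
    "follow_up_start",
    "follow_up_days",
    "day_index",
    "question_id",
    "answer_kind",
    "numeric_value",
    "raw_text",
    "reason",
]


def sessions_to_frame(sessions: Sequence[MonitoringSession]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for rec in sorted(s.records, key=lambda r: r.day_index):
            for qid in _QUESTION_ORDER:
                ans = rec.answers.get(qid)
                reason = s.missing_reasons.get((rec.day_index, qid))
                rows.append(
                    {
                        "patient_id": s.profile.patient_id,
                        "follow_up_start": s.profile.follow_up_start.isoformat(),
                        "follow_up_days": s.profile.follow_up_days,
                        "day_index": rec.day_index,
                        "question_id": qid.value,
                        "answer_kind": "" if ans is None else ans.kind.value,
                        "numeric_value": (
                            "" if ans is None or ans.numeric_value is None
                            else f"{ans.numeric_value:g}"
                        ),
                        "raw_text": "" if ans is None else ans.raw_text,
                        "reason": "" if reason is None else reason.value,
                    }
                )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def sessions_to_csv(sessions: Sequence[MonitoringSession], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def sessions_from_frame(df: pd.DataFrame) -> list[MonitoringSession]:
    sessions: list[MonitoringSession] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        first = grp.iloc[0]
        profile = PatientProfile(
            patient_id=str(pid),
            follow_up_start=dt.date.fromisoformat(str(first["follow_up_start"])),
            follow_up_days=int(first["follow_up_days"]),
        )
        session = MonitoringSession.empty(profile)
        for row in grp.itertuples(index=False):
            rec = session.record_for_day(int(row.day_index))
            if rec is None:
                raise ValueError(f"{pid}: day {row.day_index} outside window")
            qid = QuestionId(row.question_id)
            kind = str(row.answer_kind)
            if kind:
                value = AnswerValue(kind)
                num = (
                    float(row.numeric_value)
                    if value is AnswerValue.NUMERIC
                    else None
                )
                rec.answers[qid] = ParsedAnswer(value, str(row.raw_text), numeric_value=num)
            reason = str(row.reason)
            if reason:
                session.missing_reasons[(int(row.day_index), qid)] = MissingReason(reason)
        sessions.append(session)
    return sessions


def sessions_from_csv(path: str | Path) -> list[MonitoringSession]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV {path} missing columns {sorted(missing)}")
    return sessions_from_frame(df)


def cohort_to_inbound_log(
    sessions: Sequence[MonitoringSession],
    catalog: Sequence[Question] | None = None,
    schedule_cfg: ScheduleConfig | None = None,
) -> list[InboundRaw]:
    """Flatten sessions to the raw inbound-log format the parser consumes.

    Replies are emitted per day in slot order with distinct minute offsets,
    so order-based re-attachment reconstructs fully-answered days exactly.
    Because raw SMS replies carry no question reference, days with a missing
    binary answer in a two-binary slot cannot be reconstructed unambiguously.
    """
    catalog = list(catalog) if catalog is not None else default_question_catalog()
    cfg = schedule_cfg or ScheduleConfig()
    slot_time = {Slot.MORNING: cfg.morning_time, Slot.EVENING: cfg.evening_time}
    order = {Slot.MORNING: 0, Slot.EVENING: 1}
    ordered = sorted(enumerate(catalog), key=lambda t: (order[t[1].slot], t[0]))
    log: list[InboundRaw] = []
    for s in sessions:
        for rec in sorted(s.records, key=lambda r: r.day_index):
            for offset, (_, q) in enumerate(ordered):
                ans = rec.answers.get(q.id)
                if ans is None:
                    continue
                date = s.profile.date_for_day(rec.day_index)
                stamp = dt.datetime.combine(date, slot_time[q.slot]) + dt.timedelta(
                    minutes=5 + offset
                )
                log.append(
                    InboundRaw(
                        patient_id=s.profile.patient_id,
                        received_at=date,
                        received_time=stamp.time(),
                        raw_text=ans.raw_text,
                    )
                )
    return log


# ---------------------------------------------------------------------------
# Canonical prototype-test cohort
# ---------------------------------------------------------------------------

_FIXTURE_RESOURCE = "prototype_cohort.csv"

# Published marginals: answered counts per question across the ten patients.
_EXPECTED_ANSWERED = {
    QuestionId.DYSPNEA: sorted([7] * 8 + [2] + [3]),
    QuestionId.MEDICATION: sorted([7] * 7 + [6, 3] + [3]),
    QuestionId.WEIGHT: sorted([7] * 8 + [3] + [3]),
    QuestionId.FATIGUE: sorted([7] * 7 + [6, 5] + [3]),
}
_EXPECTED_REASONS = {
    MissingReason.POWER_OUTAGE: 10,
    MissingReason.NOT_SEEN: 4,
    MissingReason.FORGOT: 3,
}


def _yes_run_lengths(session: MonitoringSession, qid: QuestionId) -> list[int]:
    runs, run = [], 0
    for rec in sorted(session.records, key=lambda r: r.day_index):
        ans = rec.answers.get(qid)
        if ans is not None and ans.kind is AnswerValue.YES:
            run += 1
        else:
            if run:
                runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise FixtureError(message)


def prototype_cohort() -> list[MonitoringSession]:
    """Load and validate the canonical 10-patient prototype grid.

    Raises :class:`FixtureError` if the shipped file drifts from any
    published constraint (window lengths, per-question answered marginals,
    alarm-run placement, reason tallies, medication all-YES, constant
    weights, no two consecutive fully-missed days).
    """
    with resources.files("smscare.data").joinpath(_FIXTURE_RESOURCE).open("r") as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    sessions = sessions_from_frame(df)

    _check(len(sessions) == 10, "expected 10 patients")
    windows = sorted(s.profile.follow_up_days for s in sessions)
    _check(windows == [3] + [7] * 9, f"window lengths {windows} != one 3-day + nine 7-day")
    for s in sessions:
        problems = validate_session(s)
        _check(not problems, f"{s.profile.patient_id}: {problems}")

    # Per-question answered marginals and the 264/247/17 totals.
    total_sent = total_answered = 0
    for qid, expected in _EXPECTED_ANSWERED.items():
        counts = sorted(
            sum(1 for rec in s.records if qid in rec.answers) for s in sessions
        )
        _check(counts == expected, f"{qid.value} answered counts {counts} != {expected}")
    for s in sessions:
        total_sent += 4 * s.profile.follow_up_days
        total_answered += sum(len(rec.answers) for rec in s.records)
    _check(total_sent == 264, f"sent {total_sent} != 264")
    _check(total_answered == 247, f"answered {total_answered} != 247")

    # Medication adherence was perfect.
    for s in sessions:
        for rec in s.records:
            med = rec.answers.get(QuestionId.MEDICATION)
            _check(
                med is None or med.kind is AnswerValue.YES,
                f"{s.profile.patient_id} day {rec.day_index}: medication answer not YES",
            )

    # Alarm placement: 3 dyspnea-run patients, 4 fatigue-run patients,
    # every run exactly length 2, all seven patients distinct and fully
    # adherent (disjoint from the low-adherence patients).
    dysp = {s.profile.patient_id: _yes_run_lengths(s, QuestionId.DYSPNEA) for s in sessions}
    fat = {s.profile.patient_id: _yes_run_lengths(s, QuestionId.FATIGUE) for s in sessions}
    dysp_patients = {p for p, runs in dysp.items() if runs}
    fat_patients = {p for p, runs in fat.items() if runs}
    _check(all(runs == [2] for p, runs in dysp.items() if runs), "dyspnea runs must be single length-2 runs")
    _check(all(runs == [2] for p, runs in fat.items() if runs), "fatigue runs must be single length-2 runs")
    _check(len(dysp_patients) == 3, f"{len(dysp_patients)} dyspnea-run patients != 3")
    _check(len(fat_patients) == 4, f"{len(fat_patients)} fatigue-run patients != 4")
    _check(not dysp_patients & fat_patients, "alarm patients must be disjoint")
    low_adherence = {
        s.profile.patient_id
        for s in sessions
        if sum(len(rec.answers) for rec in s.records) < 4 * s.profile.follow_up_days
    }
    _check(
        not (dysp_patients | fat_patients) & low_adherence,
        "alarm patients must be fully adherent",
    )

    # Constant weights per patient (no weight-gain alarm possible).
    for s in sessions:
        weights = {
            rec.answers[QuestionId.WEIGHT].numeric_value
            for rec in s.records
            if QuestionId.WEIGHT in rec.answers
        }
        _check(len(weights) <= 1, f"{s.profile.patient_id}: weight not constant")

    # No two consecutive fully-missed days (no non-response alarm possible).
    for s in sessions:
        empty_prev = False
        for rec in sorted(s.records, key=lambda r: r.day_index):
            empty = len(rec.answers) == 0
            _check(not (empty and empty_prev), f"{s.profile.patient_id}: consecutive empty days")
            empty_prev = empty

    # Unanswered-reason audit tags.
    tally = Counter(s.missing_reasons.get((rec.day_index, qid))
                    for s in sessions
                    for rec in s.records
                    for qid in _QUESTION_ORDER
                    if qid not in rec.answers)
    _check(None not in tally, "every missing cell must carry a reason tag")
    _check(
        {k: v for k, v in tally.items()} == _EXPECTED_REASONS,
        f"reason tally {dict(tally)} != {_EXPECTED_REASONS}",
    )
    return sessions
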