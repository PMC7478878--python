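"""Domain types and default catalogs for the SMS telemonitoring engine.

The system monitors patients discharged after an episode of acute
decompensated heart failure (ADHF) during their first post-discharge week.
It exchanges two kinds of SMS messages:

* **feedback questions** — four per day (two in the morning, two in the
  evening) asking about nocturnal dyspnea, body weight, medication intake
  and fatigue; the patient replies YES/NO or with a weight in kg;
* **educational reinforcements** — one-way self-care messages sent on a
  fixed cadence (every other day by default) that expect no reply.

Replies feed a rule engine (:mod:`smscare.alarm_engine`) that raises an
alarm when congestion-like patterns appear: consecutive symptomatic days,
consecutive missed medications, multi-day weight gain, or consecutive days
of complete silence.

This module holds the shared value types, the default question and
educational catalogs, the schedule/alarm configuration objects, session
validation, and YAML (de)serialization of the whole configuration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "QuestionId",
    "AnswerKind",
    "Slot",
    "Question",
    "EducationalMessage",
    "ScheduleConfig",
    "AlarmRuleConfig",
    "SystemConfig",
    "PatientProfile",
    "AnswerValue",
    "ParsedAnswer",
    "DailyRecord",
    "MonitoringSession",
    "MissingReason",
    "ConfigurationError",
    "default_question_catalog",
    "default_educational_catalog",
    "meals_question",
    "default_system_config",
    "validate_catalog",
    "validate_session",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
]

MAX_PLAUSIBLE_WEIGHT_KG = 500.0


class ConfigurationError(ValueError):
    """Raised when a catalog or config file violates its invariants."""


class QuestionId(str, Enum):
    """Identity of a daily feedback question."""

    DYSPNEA = "DYSPNEA"
    WEIGHT = "WEIGHT"
    MEDICATION = "MEDICATION"
    FATIGUE = "FATIGUE"
    # Alternate question printed in the deployed system's feedback list;
    # not part of the default catalog (no alarm rule is attached to it).
    MEALS = "MEALS"


class AnswerKind(str, Enum):
    BINARY = "BINARY"
    NUMERIC_KG = "NUMERIC_KG"


class Slot(str, Enum):
    MORNING = "MORNING"
    EVENING = "EVENING"


@dataclass(frozen=True)
class Question:
    """One daily feedback question.

    Parameters
    ----------
    id:
        Stable identity used by the alarm rules.
    text:
        Message body sent to the patient.
    answer_kind:
        BINARY (YES/NO reply) or NUMERIC_KG (weight in kilograms).
    slot:
        Whether the question goes out in the morning or evening batch.
    """

    id: QuestionId
    text: str
    answer_kind: AnswerKind
    slot: Slot


@dataclass(frozen=True)
class EducationalMessage:
    """One-way self-care reinforcement; never expects (or matches) a reply."""

    id: str
    text: str


@dataclass(frozen=True)
class ScheduleConfig:
    """Outbound cadence.

    The engine is day-granular: the clock times order the two daily batches
    and decorate logs, they never enter alarm logic.
    """

    morning_time: dt.time = dt.time(8, 0)
    evening_time: dt.time = dt.time(20, 0)
    educational_period_days: int = 2
    educational_first_day: int = 2
    follow_up_days_default: int = 7

    def __post_init__(self) -> None:
        if self.morning_time >= self.evening_time:
            raise ConfigurationError("morning_time must precede evening_time")
        for name in ("educational_period_days", "educational_first_day", "follow_up_days_default"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


@dataclass(frozen=True)
class AlarmRuleConfig:
    """Thresholds for the five automatic checks.

    Defaults reproduce the deployed flowchart: symptom/medication/non-response
    streaks of 2 consecutive days, and a 2.0 kg weight gain inside a 3-day
    fully-observed window.  ``weight_loss_kg`` enables a symmetric loss check
    (disabled by default).  ``weight_endpoint_only`` switches the gain from
    last-minus-minimum to last-minus-first inside the window.
    """

    symptom_streak_days: int = 2
    nonresponse_streak_days: int = 2
    weight_gain_kg: float = 2.0
    weight_window_days: int = 3
    weight_loss_kg: float | None = None
    weight_endpoint_only: bool = False

    def __post_init__(self) -> None:
        if self.symptom_streak_days < 1 or self.nonresponse_streak_days < 1:
            raise ConfigurationError("streak lengths must be >= 1")
        if self.weight_gain_kg <= 0:
            raise ConfigurationError("weight_gain_kg must be positive")
        if self.weight_window_days < 2:
            raise ConfigurationError("weight_window_days must be >= 2")
        if self.weight_loss_kg is not None and self.weight_loss_kg <= 0:
            raise ConfigurationError("weight_loss_kg must be positive when set")


@dataclass(frozen=True)
class SystemConfig:
    """Everything the pipeline needs: catalogs + schedule + alarm thresholds."""

    questions: tuple[Question, ...]
    educational: tuple[EducationalMessage, ...]
    schedule: ScheduleConfig
    alarms: AlarmRuleConfig


@dataclass(frozen=True)
class PatientProfile:
    """Enrollment record: a follow-up window anchored at a start date.

    ``metadata`` carries inert descriptors (age, sex, LVEF, site); the
    engine only ever reads ``site`` for optional per-hospital filtering.
    """

    patient_id: str
    follow_up_start: dt.date
    follow_up_days: int
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.follow_up_days < 1:
            raise ConfigurationError("follow_up_days must be >= 1")

    def date_for_day(self, day_index: int) -> dt.date:
        return self.follow_up_start + dt.timedelta(days=day_index - 1)

    def day_for_date(self, date: dt.date) -> int | None:
        """1-based day index for a calendar date, or None outside the window."""
        day = (date - self.follow_up_start).days + 1
        return day if 1 <= day <= self.follow_up_days else None


class AnswerValue(str, Enum):
    YES = "YES"
    NO = "NO"
    NUMERIC = "NUMERIC"
    INVALID = "INVALID"


@dataclass(frozen=True)
class ParsedAnswer:
    """A parsed inbound reply.

    INVALID answers count as "the patient responded" (they defeat the
    non-response rule) but never satisfy a symptom predicate and break
    weight windows.
    """

    kind: AnswerValue
    raw_text: str
    numeric_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind is AnswerValue.NUMERIC:
            if self.numeric_value is None or not (0 < self.numeric_value < MAX_PLAUSIBLE_WEIGHT_KG):
                raise ValueError("NUMERIC answer requires a value in (0, 500) kg")
        elif self.numeric_value is not None:
            raise ValueError("numeric_value only valid for NUMERIC answers")


class MissingReason(str, Enum):
    """Audit tag for an unanswered feedback message."""

    POWER_OUTAGE = "POWER_OUTAGE"
    NOT_SEEN = "NOT_SEEN"
    FORGOT = "FORGOT"
    UNSPECIFIED = "UNSPECIFIED"


@dataclass
class DailyRecord:
    """Answers observed on one follow-up day; absent key = no reply."""

    day_index: int
    answers: dict[QuestionId, ParsedAnswer] = field(default_factory=dict)


@dataclass
class MonitoringSession:
    """One patient's follow-up: the day grid plus derived alarms.

    ``missing_reasons`` optionally tags unanswered (day, question) cells for
    adherence reporting; ``seen_inbound`` fingerprints already-processed raw
    messages so replaying an inbound log is idempotent.
    """

    profile: PatientProfile
    records: list[DailyRecord]
    alarms: list = field(default_factory=list)
    missing_reasons: dict[tuple[int, QuestionId], MissingReason] = field(default_factory=dict)
    seen_inbound: set[tuple[str, str, str]] = field(default_factory=set, repr=False)

    def record_for_day(self, day_index: int) -> DailyRecord | None:
        for rec in self.records:
            if rec.day_index == day_index:
                return rec
        return None

    @classmethod
    def empty(cls, profile: PatientProfile) -> "MonitoringSession":
        return cls(
            profile=profile,
            records=[DailyRecord(day_index=d) for d in range(1, profile.follow_up_days + 1)],
        )


# ---------------------------------------------------------------------------
# Default catalogs
# ---------------------------------------------------------------------------

def default_question_catalog() -> list[Question]:
    """The four deployed feedback questions.

    Morning: nocturnal dyspnea and first-thing weight (both reference
    overnight / fasting measurement); evening: medication intake and fatigue
    (both summarize the day).  The slot split is a configurable convention —
    only "two messages in the morning and two at night" is fixed.
    """
    return [
        Question(
            QuestionId.DYSPNEA,
            "During last night, did you wake up with shortness of breath once?",
            AnswerKind.BINARY,
            Slot.MORNING,
        ),
        Question(
            QuestionId.WEIGHT,
            "What's your weight today?",
            AnswerKind.NUMERIC_KG,
            Slot.MORNING,
        ),
        Question(
            QuestionId.MEDICATION,
            "Have you taken all your medications today?",
            AnswerKind.BINARY,
            Slot.EVENING,
        ),
        Question(
            QuestionId.FATIGUE,
            "Have you felt more tired today than you did yesterday?",
            AnswerKind.BINARY,
            Slot.EVENING,
        ),
    ]


def meals_question(slot: Slot = Slot.EVENING) -> Question:
    """Alternate catalog entry: the meals question from the deployed feedback
    list.  Not in the default catalog because no alarm rule watches it."""
    return Question(
        QuestionId.MEALS,
        "Have you eaten all your meals today?",
        AnswerKind.BINARY,
        slot,
    )


def default_educational_catalog() -> list[EducationalMessage]:
    """Self-care reinforcements, cycled in this fixed order by the scheduler."""
    return [
        EducationalMessage(
            "EDU_SALT",
            "Avoid processed meats because they all contain a lot of salt.",
        ),
        EducationalMessage(
            "EDU_DYSPNEA",
            "Shortness of breath is one of the symptoms caused by the "
            "accumulation of fluid in the body.",
        ),
        EducationalMessage(
            "EDU_WEIGHING",
            "It is important for patients with heart failure to weigh "
            "themselves regularly at the same time each day and record "
            "their weight.",
        ),
    ]


def default_system_config() -> SystemConfig:
    return SystemConfig(
        questions=tuple(default_question_catalog()),
        educational=tuple(default_educational_catalog()),
        schedule=ScheduleConfig(),
        alarms=AlarmRuleConfig(),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_catalog(questions: Iterable[Question]) -> list[str]:
    """Invariants: unique ids, exactly two questions per slot, WEIGHT is the
    only NUMERIC_KG question.  Returns human-readable violations."""
    qs = list(questions)
    problems: list[str] = []
    if not qs:
        problems.append("catalog is empty")
        return problems
    ids = [q.id for q in qs]
    for qid in set(ids):
        if ids.count(qid) > 1:
            problems.append(f"question id {qid.value} appears {ids.count(qid)} times")
    for slot in Slot:
        n = sum(1 for q in qs if q.slot is slot)
        if n != 2:
            problems.append(f"slot {slot.value} has {n} questions, expected 2")
    for q in qs:
        if q.answer_kind is AnswerKind.NUMERIC_KG and q.id is not QuestionId.WEIGHT:
            problems.append(f"{q.id.value} is NUMERIC_KG but only WEIGHT may be")
        if q.id is QuestionId.WEIGHT and q.answer_kind is not AnswerKind.NUMERIC_KG:
            problems.append("WEIGHT must be NUMERIC_KG")
        if not q.text.strip():
            problems.append(f"{q.id.value} has empty text")
    return problems


def validate_session(session: MonitoringSession) -> list[str]:
    """Check the session grid invariants; violations are returned, not raised.

    Checks: record count equals the window length, day indices are the
    contiguous run 1..n with no duplicates, every answer's question id is
    known and every NUMERIC value is a plausible weight.
    """
    problems: list[str] = []
    n = session.profile.follow_up_days
    days = [rec.day_index for rec in session.records]
    if len(session.records) != n:
        problems.append(
            f"session has {len(session.records)} records for a {n}-day window"
        )
    seen: set[int] = set()
    for d in days:
        if d in seen:
            problems.append(f"duplicate day_index {d}")
        seen.add(d)
        if not 1 <= d <= n:
            problems.append(f"day_index {d} outside 1..{n}")
    if days != sorted(set(days)) and len(days) == len(set(days)):
        problems.append("records are not sorted by day_index")
    missing_days = set(range(1, n + 1)) - seen
    for d in sorted(missing_days):
        if len(session.records) == n:  # same count but a gap: report the hole
            problems.append(f"no record for day {d}")
    for rec in session.records:
        for qid, ans in rec.answers.items():
            if not isinstance(qid, QuestionId):
                problems.append(f"day {rec.day_index}: unknown question id {qid!r}")
            if ans.kind is AnswerValue.NUMERIC and not (
                ans.numeric_value is not None and 0 < ans.numeric_value < MAX_PLAUSIBLE_WEIGHT_KG
            ):
                problems.append(
                    f"day {rec.day_index}: implausible weight {ans.numeric_value!r}"
                )
    return problems


# ---------------------------------------------------------------------------
# YAML configuration round trip
# ---------------------------------------------------------------------------

def config_to_dict(cfg: SystemConfig) -> dict[str, Any]:
    return {
        "questions": [
            {
                "id": q.id.value,
                "text": q.text,
                "answer_kind": q.answer_kind.value,
                "slot": q.slot.value,
            }
            for q in cfg.questions
        ],
        "educational": [{"id": m.id, "text": m.text} for m in cfg.educational],
        "schedule": {
            "morning_time": cfg.schedule.morning_time.strftime("%H:%M"),
            "evening_time": cfg.schedule.evening_time.strftime("%H:%M"),
            "educational_period_days": cfg.schedule.educational_period_days,
            "educational_first_day": cfg.schedule.educational_first_day,
            "follow_up_days_default": cfg.schedule.follow_up_days_default,
        },
        "alarms": {
            "symptom_streak_days": cfg.alarms.symptom_streak_days,
            "nonresponse_streak_days": cfg.alarms.nonresponse_streak_days,
            "weight_gain_kg": cfg.alarms.weight_gain_kg,
            "weight_window_days": cfg.alarms.weight_window_days,
            "weight_loss_kg": cfg.alarms.weight_loss_kg,
            "weight_endpoint_only": cfg.alarms.weight_endpoint_only,
        },
    }


def config_from_dict(data: Mapping[str, Any]) -> SystemConfig:
    try:
        questions = tuple(
            Question(
                QuestionId(q["id"]),
                q["text"],
                AnswerKind(q["answer_kind"]),
                Slot(q["slot"]),
            )
            for q in data["questions"]
        )
        educational = tuple(
            EducationalMessage(m["id"], m["text"]) for m in data["educational"]
        )
        s = data["schedule"]
        schedule = ScheduleConfig(
            morning_time=_parse_clock(s["morning_time"]),
            evening_time=_parse_clock(s["evening_time"]),
            educational_period_days=int(s["educational_period_days"]),
            educational_first_day=int(s["educational_first_day"]),
            follow_up_days_default=int(s["follow_up_days_default"]),
        )
        a = data["alarms"]
        alarms = AlarmRuleConfig(
            symptom_streak_days=int(a["symptom_streak_days"]),
            nonresponse_streak_days=int(a["nonresponse_streak_days"]),
            weight_gain_kg=float(a["weight_gain_kg"]),
            weight_window_days=int(a["weight_window_days"]),
            weight_loss_kg=(None if a.get("weight_loss_kg") is None else float(a["weight_loss_kg"])),
            weight_endpoint_only=bool(a.get("weight_endpoint_only", False)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed config: {exc}") from exc
    problems = validate_catalog(questions)
    for m in educational:
        if not m.text.strip():
            problems.append(f"educational message {m.id} has empty text")
    if problems:
        raise ConfigurationError("; ".join(problems))
    return SystemConfig(questions, educational, schedule, alarms)


def _parse_clock(text: str) -> dt.time:
    hh, mm = str(text).split(":")
    return dt.time(int(hh), int(mm))


def save_config(cfg: SystemConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> SystemConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: not a mapping document")
    return config_from_dict(data)
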