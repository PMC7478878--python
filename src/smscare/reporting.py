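"""Cohort aggregation, pipeline orchestration and the mock SMS transport.

``summarize`` reduces resolved schedules, sessions and alarms to the
headline counts (messages sent / answered / unanswered, unanswered by
reason, alarms by rule, per-question breakdown).  ``run_pipeline`` wires
the whole system — schedule, attach, evaluate, dispatch, summarize — and
writes the artifact files (session CSV, schedule CSV, alarm CSV,
notification JSONL, transport JSONL, summary JSON).

The transport is a plug-in point: the engine only needs ``send``; the
shipped implementation is an in-memory mock that appends
:class:`TransportRecord` entries, standing where a GSM modem would sit in
a deployment.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import pandas as pd

from .alarm_engine import (
    Alarm,
    AlarmRule,
    alarms_to_csv,
    dispatch,
    evaluate,
    notifications_to_jsonl,
)
from .cohort_simulator import (
    SimConfig,
    generate_cohort,
    prototype_cohort,
    sessions_from_csv,
    sessions_to_csv,
)
from .core_model import (
    MissingReason,
    MonitoringSession,
    PatientProfile,
    QuestionId,
    SystemConfig,
    default_system_config,
    load_config,
    validate_session,
)
from .response_parser import read_inbound_csv, read_inbound_jsonl, replay_log
from .scheduler import (
    MessageKind,
    MessageSlot,
    MessageStatus,
    OutboundMessage,
    apply_responses,
    build_schedule,
    schedule_to_csv,
)

__all__ = [
    "CohortSummary",
    "TransportRecord",
    "Transport",
    "MemoryTransport",
    "PipelineError",
    "summarize",
    "run_pipeline",
    "read_profiles_csv",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Unreadable or inconsistent pipeline inputs."""


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate counts over one cohort run."""

    n_patients: int
    feedback_sent: int
    feedback_answered: int
    feedback_unanswered: int
    unanswered_by_reason: dict[str, int]
    alarms_by_rule: dict[str, int]
    per_question: dict[str, tuple[int, int]]  # question -> (answered, sent)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "feedback_sent": self.feedback_sent,
            "feedback_answered": self.feedback_answered,
            "feedback_unanswered": self.feedback_unanswered,
            "unanswered_by_reason": dict(sorted(self.unanswered_by_reason.items())),
            "alarms_by_rule": dict(sorted(self.alarms_by_rule.items())),
            "per_question": {
                q: {"answered": a, "sent": s}
                for q, (a, s) in sorted(self.per_question.items())
            },
        }


def summarize(
    sessions: Sequence[MonitoringSession],
    schedules: Mapping[str, Sequence[OutboundMessage]],
    alarms: Sequence[Alarm],
) -> CohortSummary:
    """Aggregate resolved schedules into the cohort summary.

    Conservation holds by construction: answered + unanswered = sent,
    globally and per question.  Raises :class:`PipelineError` on misaligned
    inputs or unresolved (PLANNED) feedback messages.
    """
    session_ids = {s.profile.patient_id for s in sessions}
    if session_ids != set(schedules):
        raise PipelineError(
            f"sessions {sorted(session_ids)} and schedules {sorted(schedules)} misaligned"
        )
    by_pid = {s.profile.patient_id: s for s in sessions}
    sent = answered = 0
    per_question: dict[str, list[int]] = {}
    reasons: dict[str, int] = {}
    for pid, schedule in schedules.items():
        session = by_pid[pid]
        for msg in schedule:
            if msg.kind is not MessageKind.FEEDBACK:
                continue
            if msg.status in (MessageStatus.PLANNED,):
                raise PipelineError(
                    f"{pid} day {msg.day_index}: feedback message still PLANNED; "
                    "run apply_responses first"
                )
            sent += 1
            q = per_question.setdefault(msg.payload, [0, 0])
            q[1] += 1
            if msg.status is MessageStatus.ANSWERED:
                answered += 1
                q[0] += 1
            else:
                reason = session.missing_reasons.get(
                    (msg.day_index, QuestionId(msg.payload)), MissingReason.UNSPECIFIED
                )
                reasons[reason.value] = reasons.get(reason.value, 0) + 1
    alarms_by_rule = {rule.value: 0 for rule in AlarmRule}
    for a in alarms:
        alarms_by_rule[a.rule.value] += 1
    return CohortSummary(
        n_patients=len(sessions),
        feedback_sent=sent,
        feedback_answered=answered,
        feedback_unanswered=sent - answered,
        unanswered_by_reason=reasons,
        alarms_by_rule=alarms_by_rule,
        per_question={q: (a, s) for q, (a, s) in per_question.items()},
    )


# ---------------------------------------------------------------------------
# Transport abstraction (mock in place of the GSM modem)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportRecord:
    direction: str  # "OUT" | "IN"
    patient_id: str
    day_index: int
    payload: str
    timestamp: str  # ISO datetime


class Transport(Protocol):
    def send(self, record: TransportRecord) -> None: ...


@dataclass
class MemoryTransport:
    """Append-only in-memory message log."""

    records: list[TransportRecord] = field(default_factory=list)

    def send(self, record: TransportRecord) -> None:
        self.records.append(record)

    def to_jsonl(self, path: str | Path) -> None:
        lines = [json.dumps(r.__dict__) for r in self.records]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Profiles input
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["patient_id", "follow_up_start", "follow_up_days"]


def read_profiles_csv(path: str | Path) -> list[PatientProfile]:
    """Columns patient_id, follow_up_start (ISO date), follow_up_days; any
    extra columns (age, sex, lvef, site, ...) become inert metadata."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineError(f"profiles CSV {path} missing columns {sorted(missing)}")
    extra = [c for c in df.columns if c not in PROFILE_COLUMNS]
    profiles = []
    for row in df.to_dict(orient="records"):
        profiles.append(
            PatientProfile(
                patient_id=str(row["patient_id"]),
                follow_up_start=dt.date.fromisoformat(str(row["follow_up_start"])),
                follow_up_days=int(row["follow_up_days"]),
                metadata={c: row[c] for c in extra if str(row[c]) != ""},
            )
        )
    if len({p.patient_id for p in profiles}) != len(profiles):
        raise PipelineError(f"duplicate patient ids in {path}")
    return profiles


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _slot_timestamp(profile: PatientProfile, msg: OutboundMessage, cfg: SystemConfig) -> str:
    times = {
        MessageSlot.MORNING: cfg.schedule.morning_time,
        MessageSlot.EVENING: cfg.schedule.evening_time,
        MessageSlot.EDUCATIONAL: cfg.schedule.morning_time,
    }
    return dt.datetime.combine(
        profile.date_for_day(msg.day_index), times[msg.slot]
    ).isoformat()


def run_pipeline(
    out_dir: str | Path,
    config: SystemConfig | str | Path | None = None,
    sessions: Sequence[MonitoringSession] | None = None,
    fixture: str | None = None,
    sessions_csv: str | Path | None = None,
    sim: SimConfig | None = None,
    inbound_path: str | Path | None = None,
    profiles_path: str | Path | None = None,
    site: str | None = None,
    transport: Transport | None = None,
) -> CohortSummary:
    """Execute schedule -> attach -> evaluate -> dispatch -> summarize.

    Exactly one session source must be given: in-memory ``sessions``, the
    named ``fixture`` ("prototype"), a ``sessions_csv`` grid, a simulator
    ``sim`` config, or an ``inbound_path`` log together with
    ``profiles_path``.  ``site`` keeps only patients whose profile metadata
    carries that site tag (per-hospital scoping).  Writes sessions.csv,
    schedule.csv, alarms.csv, notifications.jsonl, transport.jsonl and
    summary.json under ``out_dir`` and returns the summary.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = config or default_system_config()

    sources = [sessions is not None, fixture is not None, sessions_csv is not None,
               sim is not None, inbound_path is not None]
    if sum(sources) != 1:
        raise PipelineError("exactly one session source must be provided")

    if fixture is not None:
        if fixture != "prototype":
            raise PipelineError(f"unknown fixture {fixture!r} (expected 'prototype')")
        cohort = prototype_cohort()
    elif sessions is not None:
        cohort = list(sessions)
    elif sessions_csv is not None:
        cohort = sessions_from_csv(sessions_csv)
    elif sim is not None:
        cohort = generate_cohort(sim)
    else:
        if profiles_path is None:
            raise PipelineError("an inbound log needs a profiles CSV")
        profiles = read_profiles_csv(profiles_path)
        cohort = [MonitoringSession.empty(p) for p in profiles]
        path = Path(inbound_path)
        if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
            log = read_inbound_jsonl(path)
        else:
            log = read_inbound_csv(path)
        replay_log(log, {s.profile.patient_id: s for s in cohort}, list(cfg.questions))

    if site is not None:
        cohort = [s for s in cohort if s.profile.metadata.get("site") == site]

    for s in cohort:
        problems = validate_session(s)
        if problems:
            raise PipelineError(f"{s.profile.patient_id}: invalid session: {problems}")

    tx = transport if transport is not None else MemoryTransport()
    schedules: dict[str, list[OutboundMessage]] = {}
    all_alarms: list[Alarm] = []
    for s in cohort:
        plan = build_schedule(s.profile, list(cfg.questions), list(cfg.educational), cfg.schedule)
        resolved = apply_responses(plan, s)
        schedules[s.profile.patient_id] = resolved
        for msg in resolved:
            tx.send(
                TransportRecord(
                    "OUT", msg.patient_id, msg.day_index, msg.payload,
                    _slot_timestamp(s.profile, msg, cfg),
                )
            )
        s.alarms = evaluate(s, cfg.alarms)
        all_alarms.extend(s.alarms)

    order = {r: i for i, r in enumerate(AlarmRule)}
    all_alarms.sort(key=lambda a: (a.patient_id, a.day_index, order[a.rule]))
    notifications = dispatch(all_alarms)
    summary = summarize(cohort, schedules, all_alarms)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions_to_csv(cohort, out / "sessions.csv")
    flat = [m for pid in sorted(schedules) for m in schedules[pid]]
    schedule_to_csv(flat, out / "schedule.csv")
    alarms_to_csv(all_alarms, out / "alarms.csv")
    notifications_to_jsonl(notifications, out / "notifications.jsonl")
    if isinstance(tx, MemoryTransport):
        tx.to_jsonl(out / "transport.jsonl")
    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    logger.info(
        "pipeline complete: %d patients, %d sent, %d answered, %d alarms",
        summary.n_patients, summary.feedback_sent, summary.feedback_answered,
        sum(summary.alarms_by_rule.values()),
    )
    return summary
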