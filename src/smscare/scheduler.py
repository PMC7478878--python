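"""Outbound message planning and answered/unanswered bookkeeping.

Every follow-up day each patient receives the four feedback questions
(two per slot) and, on a fixed cadence, one educational reinforcement.
``build_schedule`` produces the full plan for one patient window;
``apply_responses`` marks each feedback message ANSWERED or UNANSWERED
against a session's day grid.  The engine is day-granular: conservation
(ANSWERED + UNANSWERED = 4 x follow_up_days) holds for every patient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_model import (
    ConfigurationError,
    EducationalMessage,
    MonitoringSession,
    PatientProfile,
    Question,
    QuestionId,
    ScheduleConfig,
    Slot,
    validate_catalog,
)

__all__ = [
    "MessageKind",
    "MessageStatus",
    "MessageSlot",
    "OutboundMessage",
    "build_schedule",
    "cohort_feedback_count",
    "apply_responses",
    "schedule_to_frame",
    "schedule_to_csv",
    "schedule_from_csv",
]


class MessageKind(str, Enum):
    FEEDBACK = "FEEDBACK"
    EDUCATIONAL = "EDUCATIONAL"


class MessageStatus(str, Enum):
    PLANNED = "PLANNED"
    SENT = "SENT"
    ANSWERED = "ANSWERED"
    UNANSWERED = "UNANSWERED"


class MessageSlot(str, Enum):
    MORNING = "MORNING"
    EVENING = "EVENING"
    EDUCATIONAL = "EDUCATIONAL"


# Sorting: morning batch, evening batch, then the educational extra.
_SLOT_ORDER = {MessageSlot.MORNING: 0, MessageSlot.EVENING: 1, MessageSlot.EDUCATIONAL: 2}


@dataclass(frozen=True)
class OutboundMessage:
    """One planned SMS: a feedback question or an educational reinforcement.

    FEEDBACK messages carry a :class:`QuestionId` payload and end up
    ANSWERED or UNANSWERED; EDUCATIONAL carry an educational-message id and
    never progress past SENT.
    """

    patient_id: str
    day_index: int
    slot: MessageSlot
    kind: MessageKind
    payload: str
    status: MessageStatus = MessageStatus.PLANNED


def _educational_days(cfg: ScheduleConfig, follow_up_days: int) -> list[int]:
    return list(
        range(cfg.educational_first_day, follow_up_days + 1, cfg.educational_period_days)
    )


def build_schedule(
    profile: PatientProfile,
    catalog: Sequence[Question],
    edu: Sequence[EducationalMessage],
    cfg: ScheduleConfig,
) -> list[OutboundMessage]:
    """Plan one patient's outbound messages for the whole window.

    For each day: all four feedback questions (two per slot, catalog slot
    order), plus an educational message on days ``educational_first_day``,
    ``+period``, ... cycling through the educational catalog in order.
    Pure and deterministic; output sorted by (day_index, slot).
    """
    problems = validate_catalog(catalog)
    if problems:
        raise ConfigurationError("invalid question catalog: " + "; ".join(problems))

    by_slot = {
        Slot.MORNING: [q for q in catalog if q.slot is Slot.MORNING],
        Slot.EVENING: [q for q in catalog if q.slot is Slot.EVENING],
    }
    edu_days = _educational_days(cfg, profile.follow_up_days)
    edu_for_day = {
        day: edu[i % len(edu)].id for i, day in enumerate(edu_days)
    } if edu else {}

    plan: list[OutboundMessage] = []
    for day in range(1, profile.follow_up_days + 1):
        for slot in (Slot.MORNING, Slot.EVENING):
            for q in by_slot[slot]:
                plan.append(
                    OutboundMessage(
                        patient_id=profile.patient_id,
                        day_index=day,
                        slot=MessageSlot(slot.value),
                        kind=MessageKind.FEEDBACK,
                        payload=q.id.value,
                        status=MessageStatus.PLANNED,
                    )
                )
        if day in edu_for_day:
            plan.append(
                OutboundMessage(
                    patient_id=profile.patient_id,
                    day_index=day,
                    slot=MessageSlot.EDUCATIONAL,
                    kind=MessageKind.EDUCATIONAL,
                    payload=edu_for_day[day],
                    status=MessageStatus.PLANNED,
                )
            )
    plan.sort(key=lambda m: (m.day_index, _SLOT_ORDER[m.slot]))
    return plan


def cohort_feedback_count(
    profiles: Iterable[PatientProfile], cfg: ScheduleConfig | None = None
) -> int:
    """Total feedback messages for a cohort: 4 questions/day x window days."""
    return sum(4 * p.follow_up_days for p in profiles)


def apply_responses(
    schedule: Sequence[OutboundMessage], session: MonitoringSession
) -> list[OutboundMessage]:
    """Resolve each feedback message's status against the session grid.

    ANSWERED iff the day's record holds any answer (INVALID included — the
    patient responded) for that question; otherwise UNANSWERED.  Educational
    messages become SENT.
    """
    pids = {m.patient_id for m in schedule}
    if pids and pids != {session.profile.patient_id}:
        raise ValueError(
            f"schedule is for {sorted(pids)} but session is for "
            f"{session.profile.patient_id!r}"
        )
    by_day = {rec.day_index: rec for rec in session.records}
    out: list[OutboundMessage] = []
    for msg in schedule:
        if msg.kind is MessageKind.EDUCATIONAL:
            out.append(replace(msg, status=MessageStatus.SENT))
            continue
        rec = by_day.get(msg.day_index)
        answered = rec is not None and QuestionId(msg.payload) in rec.answers
        out.append(
            replace(
                msg,
                status=MessageStatus.ANSWERED if answered else MessageStatus.UNANSWERED,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV export (column order is part of the interface)
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = ["patient_id", "day_index", "slot", "kind", "payload", "status"]


def schedule_to_frame(schedule: Sequence[OutboundMessage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "day_index": m.day_index,
                "slot": m.slot.value,
                "kind": m.kind.value,
                "payload": m.payload,
                "status": m.status.value,
            }
            for m in schedule
        ],
        columns=SCHEDULE_COLUMNS,
    )


def schedule_to_csv(schedule: Sequence[OutboundMessage], path: str | Path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def schedule_from_csv(path: str | Path) -> list[OutboundMessage]:
    df = pd.read_csv(path, dtype={"patient_id": str, "payload": str})
    return [
        OutboundMessage(
            patient_id=row.patient_id,
            day_index=int(row.day_index),
            slot=MessageSlot(row.slot),
            kind=MessageKind(row.kind),
            payload=row.payload,
            status=MessageStatus(row.status),
        )
        for row in df.itertuples(index=False)
    ]
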