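"""Inbound SMS parsing and attachment to the day grid.

SMS replies carry no reference to the question they answer, so matching is
by shape and arrival order within the calendar day of receipt: a binary
token goes to the oldest unanswered BINARY question of that day (morning
slot first), a number goes to the WEIGHT question, and anything else is
INVALID and goes to the oldest unanswered question of any kind (it still
counts as "the patient responded").  Replies never cross day boundaries
and a (day, question) cell is written at most once — first wins.

Binary token sets default to English and Portuguese (yes/sim, no/não/nao)
and are configurable.  Weight replies accept dot or comma decimals with an
optional trailing "kg".
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_model import (
    AnswerKind,
    AnswerValue,
    MAX_PLAUSIBLE_WEIGHT_KG,
    MonitoringSession,
    ParsedAnswer,
    Question,
    Slot,
)

__all__ = [
    "InboundRaw",
    "DEFAULT_AFFIRMATIVE_TOKENS",
    "DEFAULT_NEGATIVE_TOKENS",
    "parse_binary",
    "parse_weight",
    "attach",
    "replay_log",
    "read_inbound_csv",
    "read_inbound_jsonl",
]

logger = logging.getLogger(__name__)

DEFAULT_AFFIRMATIVE_TOKENS = frozenset({"yes", "sim"})
DEFAULT_NEGATIVE_TOKENS = frozenset({"no", "nao", "não"})

_WEIGHT_RE = re.compile(
    r"^\s*(\d{1,3}(?:[.,]\d+)?)\s*(?:kg\.?)?\s*$", re.IGNORECASE
)


@dataclass(frozen=True)
class InboundRaw:
    """One raw inbound SMS; ``raw_text`` is preserved verbatim for audit."""

    patient_id: str
    received_at: dt.date
    raw_text: str
    received_time: dt.time | None = None

    def fingerprint(self) -> tuple[str, str, str]:
        t = self.received_time.isoformat() if self.received_time else ""
        return (self.received_at.isoformat(), t, self.raw_text)


def _normalize_token(text: str) -> str:
    # casefold + NFC so "nÃo"/"NÃO"/"não" all compare equal
    return unicodedata.normalize("NFC", text.strip().casefold())


def parse_binary(
    raw_text: str,
    affirmative: Iterable[str] = DEFAULT_AFFIRMATIVE_TOKENS,
    negative: Iterable[str] = DEFAULT_NEGATIVE_TOKENS,
) -> ParsedAnswer:
    """Classify a YES/NO reply; anything outside both token sets is INVALID."""
    token = _normalize_token(raw_text)
    if token in {_normalize_token(t) for t in affirmative}:
        return ParsedAnswer(AnswerValue.YES, raw_text)
    if token in {_normalize_token(t) for t in negative}:
        return ParsedAnswer(AnswerValue.NO, raw_text)
    return ParsedAnswer(AnswerValue.INVALID, raw_text)


def parse_weight(raw_text: str) -> ParsedAnswer:
    """Extract a single weight in kg; plausibility bounds (0, 500) kg."""
    m = _WEIGHT_RE.match(raw_text)
    if not m:
        return ParsedAnswer(AnswerValue.INVALID, raw_text)
    value = float(m.group(1).replace(",", "."))
    if not 0 < value < MAX_PLAUSIBLE_WEIGHT_KG:
        return ParsedAnswer(AnswerValue.INVALID, raw_text)
    return ParsedAnswer(AnswerValue.NUMERIC, raw_text, numeric_value=value)


def _slot_ordered(catalog: Sequence[Question]) -> list[Question]:
    # morning questions first, catalog order within a slot
    order = {Slot.MORNING: 0, Slot.EVENING: 1}
    indexed = sorted(enumerate(catalog), key=lambda t: (order[t[1].slot], t[0]))
    return [q for _, q in indexed]


def _classify(raw_text: str, affirmative, negative) -> ParsedAnswer:
    """Shape detection: binary token first, then number, else INVALID."""
    ans = parse_binary(raw_text, affirmative, negative)
    if ans.kind is not AnswerValue.INVALID:
        return ans
    ans = parse_weight(raw_text)
    return ans  # NUMERIC or INVALID


def attach(
    inbound: InboundRaw,
    session: MonitoringSession,
    catalog: Sequence[Question],
    affirmative: Iterable[str] = DEFAULT_AFFIRMATIVE_TOKENS,
    negative: Iterable[str] = DEFAULT_NEGATIVE_TOKENS,
) -> MonitoringSession:
    """Attach one inbound reply to the session (mutates and returns it).

    Discards, with a log line: replies for dates outside the window, exact
    duplicates (same date, time and text) already processed, and replies for
    which no unanswered question of the matching shape remains that day.
    """
    if inbound.patient_id != session.profile.patient_id:
        raise ValueError(
            f"inbound for {inbound.patient_id!r} does not belong to session "
            f"{session.profile.patient_id!r}"
        )
    fp = inbound.fingerprint()
    if fp in session.seen_inbound:
        logger.warning("duplicate inbound discarded: %s %r", inbound.received_at, inbound.raw_text)
        return session
    session.seen_inbound.add(fp)

    day = session.profile.day_for_date(inbound.received_at)
    if day is None:
        logger.warning(
            "reply on %s outside %s's window, discarded", inbound.received_at,
            inbound.patient_id,
        )
        return session
    rec = session.record_for_day(day)
    if rec is None:  # malformed session; validate_session will flag it
        return session

    answer = _classify(inbound.raw_text, affirmative, negative)
    ordered = _slot_ordered(catalog)
    if answer.kind in (AnswerValue.YES, AnswerValue.NO):
        candidates = [
            q for q in ordered
            if q.answer_kind is AnswerKind.BINARY and q.id not in rec.answers
        ]
    elif answer.kind is AnswerValue.NUMERIC:
        candidates = [
            q for q in ordered
            if q.answer_kind is AnswerKind.NUMERIC_KG and q.id not in rec.answers
        ]
    else:  # INVALID: counts as a response; oldest open question of any kind
        candidates = [q for q in ordered if q.id not in rec.answers]

    if not candidates:
        logger.warning(
            "no open question on day %d accepts %r, discarded", day, inbound.raw_text
        )
        return session
    target = candidates[0]
    rec.answers[target.id] = answer
    session.missing_reasons.pop((day, target.id), None)
    return session


def replay_log(
    log: Iterable[InboundRaw],
    sessions: dict[str, MonitoringSession],
    catalog: Sequence[Question],
    **token_sets,
) -> dict[str, MonitoringSession]:
    """Attach a whole inbound log; unknown patient ids raise.  Idempotent:
    replaying the same log a second time leaves every session unchanged."""
    for inbound in log:
        if inbound.patient_id not in sessions:
            raise KeyError(f"unknown patient id {inbound.patient_id!r} in inbound log")
        attach(inbound, sessions[inbound.patient_id], catalog, **token_sets)
    return sessions


# ---------------------------------------------------------------------------
# Inbound log file formats
# ---------------------------------------------------------------------------

INBOUND_COLUMNS = ["patient_id", "date", "time", "raw_text"]


def _row_to_inbound(pid: str, date_s: str, time_s: str | None, text: str) -> InboundRaw:
    t = None
    if time_s not in (None, "") and not (isinstance(time_s, float) and pd.isna(time_s)):
        t = dt.time.fromisoformat(str(time_s))
    return InboundRaw(
        patient_id=str(pid),
        received_at=dt.date.fromisoformat(str(date_s)),
        received_time=t,
        raw_text=str(text),
    )


def read_inbound_csv(path: str | Path) -> list[InboundRaw]:
    """Columns: patient_id, date (ISO), time (HH:MM[:SS], optional), raw_text."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(INBOUND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"inbound CSV {path} missing columns {sorted(missing)}")
    return [
        _row_to_inbound(r.patient_id, r.date, r.time or None, r.raw_text)
        for r in df.itertuples(index=False)
    ]


def read_inbound_jsonl(path: str | Path) -> list[InboundRaw]:
    """JSON lines with keys patient_id, date, raw_text and optional time."""
    out: list[InboundRaw] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append(
            _row_to_inbound(obj["patient_id"], obj["date"], obj.get("time"), obj["raw_text"])
        )
    return out
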