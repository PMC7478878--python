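from __future__ import annotations

import datetime as dt

import pytest

from smscare.core_model import (
    AnswerValue,
    MonitoringSession,
    ParsedAnswer,
    PatientProfile,
    QuestionId,
    default_system_config,
)

START = dt.date(2017, 9, 4)

_BINARY_MARKS = {
    "Y": AnswerValue.YES,
    "N": AnswerValue.NO,
    "I": AnswerValue.INVALID,
}


def make_session(
    pid: str = "T01",
    n: int | None = None,
    dyspnea: str = "",
    fatigue: str = "",
    medication: str = "",
    weights: list[float | None] | None = None,
    start: dt.date = START,
) -> MonitoringSession:
    """Build a session from compact per-question mark strings.

    Marks: 'Y' yes, 'N' no, 'I' invalid reply, '.' absent.  ``weights`` is a
    list of kg values with None for absent and the string 'I' for an invalid
    weight reply.  The window length defaults to the longest series given.
    """
    series = [dyspnea, fatigue, medication, weights or []]
    days = n if n is not None else max((len(s) for s in series), default=0) or 1
    profile = PatientProfile(pid, start, days)
    session = MonitoringSession.empty(profile)
    binary_map = {
        QuestionId.DYSPNEA: dyspnea,
        QuestionId.FATIGUE: fatigue,
        QuestionId.MEDICATION: medication,
    }
    for rec in session.records:
        d = rec.day_index
        for qid, marks in binary_map.items():
            if d <= len(marks) and marks[d - 1] != ".":
                value = _BINARY_MARKS[marks[d - 1]]
                raw = {"Y": "YES", "N": "NO", "I": "maybe"}[marks[d - 1]]
                rec.answers[qid] = ParsedAnswer(value, raw)
        if weights is not None and d <= len(weights) and weights[d - 1] is not None:
            w = weights[d - 1]
            if w == "I":
                rec.answers[QuestionId.WEIGHT] = ParsedAnswer(AnswerValue.INVALID, "heavy")
            else:
                rec.answers[QuestionId.WEIGHT] = ParsedAnswer(
                    AnswerValue.NUMERIC, f"{w:g}", numeric_value=float(w)
                )
    return session


@pytest.fixture
def system_config():
    return default_system_config()


@pytest.fixture
def alarm_config(system_config):
    return system_config.alarms
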