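"""The five automatic congestion checks, with once-per-streak firing.

Scanning a patient's day grid in order, the engine raises an alarm when

* DYSPNEA was answered YES on ``symptom_streak_days`` consecutive days
  (nocturnal dyspnea — orthopnea/PND — is an early congestion sign);
* FATIGUE was answered YES likewise;
* MEDICATION was answered NO likewise (missed doses precipitate
  decompensation);
* the patient produced zero answers to all four questions on
  ``nonresponse_streak_days`` consecutive days;
* over ``weight_window_days`` consecutive days that all carry a numeric
  weight, the last weight exceeds the window minimum by ``weight_gain_kg``
  (rapid weight gain = fluid retention).  A symmetric loss rule is
  available but disabled by default.

Each rule is *debounced*: it fires at most once per uninterrupted
qualifying run and re-arms only after a day on which its condition breaks.
Missing or INVALID answers break symptom/medication streaks and weight
windows; INVALID answers nevertheless count as "responded" for the
non-response rule.  Streaks never extend before day 1 (no pre-enrollment
history).

Every alarm notifies both the patient and the hospital manager.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .core_model import (
    AlarmRuleConfig,
    AnswerValue,
    DailyRecord,
    MonitoringSession,
    QuestionId,
)

__all__ = [
    "AlarmRule",
    "Alarm",
    "Recipient",
    "Notification",
    "evaluate",
    "dispatch",
    "alarms_to_frame",
    "alarms_to_csv",
    "notifications_to_jsonl",
]


class AlarmRule(str, Enum):
    NON_RESPONSE = "NON_RESPONSE"
    DYSPNEA_STREAK = "DYSPNEA_STREAK"
    WEIGHT_GAIN = "WEIGHT_GAIN"
    WEIGHT_LOSS = "WEIGHT_LOSS"
    MEDICATION_STREAK = "MEDICATION_STREAK"
    FATIGUE_STREAK = "FATIGUE_STREAK"


@dataclass(frozen=True)
class Alarm:
    """A fired rule instance; ``day_index`` is the day the condition completed."""

    patient_id: str
    rule: AlarmRule
    day_index: int
    detail: str = ""


class Recipient(str, Enum):
    PATIENT = "PATIENT"
    MANAGER = "MANAGER"


@dataclass(frozen=True)
class Notification:
    alarm: Alarm
    recipients: frozenset[Recipient] = frozenset({Recipient.PATIENT, Recipient.MANAGER})


def _answer_is(rec: DailyRecord, qid: QuestionId, value: AnswerValue) -> bool:
    ans = rec.answers.get(qid)
    return ans is not None and ans.kind is value


def _numeric_weight(rec: DailyRecord) -> float | None:
    ans = rec.answers.get(QuestionId.WEIGHT)
    if ans is not None and ans.kind is AnswerValue.NUMERIC:
        return ans.numeric_value
    return None


def _debounced_streak(
    records: Sequence[DailyRecord],
    predicate: Callable[[DailyRecord], bool],
    threshold: int,
    make_alarm: Callable[[int, int], Alarm],
) -> list[Alarm]:
    """Fire once per maximal run of predicate-days of length >= threshold.

    The alarm day is the day the run reaches the threshold; the rule then
    stays silent until a predicate-breaking day re-arms it.
    """
    alarms: list[Alarm] = []
    run = 0
    armed = True
    for rec in records:
        if predicate(rec):
            run += 1
            if armed and run >= threshold:
                alarms.append(make_alarm(rec.day_index, run))
                armed = False
        else:
            run = 0
            armed = True
    return alarms


def evaluate(session: MonitoringSession, cfg: AlarmRuleConfig) -> list[Alarm]:
    """Run all checks over the session grid.  Pure: returns a new list,
    sorted by (day_index, rule declaration order)."""
    records = sorted(session.records, key=lambda r: r.day_index)
    pid = session.profile.patient_id
    alarms: list[Alarm] = []

    symptom_specs = [
        (AlarmRule.DYSPNEA_STREAK, QuestionId.DYSPNEA, AnswerValue.YES),
        (AlarmRule.FATIGUE_STREAK, QuestionId.FATIGUE, AnswerValue.YES),
        (AlarmRule.MEDICATION_STREAK, QuestionId.MEDICATION, AnswerValue.NO),
    ]
    for rule, qid, value in symptom_specs:
        alarms.extend(
            _debounced_streak(
                records,
                lambda rec, qid=qid, value=value: _answer_is(rec, qid, value),
                cfg.symptom_streak_days,
                lambda day, run, rule=rule, qid=qid, value=value: Alarm(
                    pid, rule, day,
                    f"{qid.value}={value.value} on {run} consecutive days ending day {day}",
                ),
            )
        )

    alarms.extend(
        _debounced_streak(
            records,
            lambda rec: len(rec.answers) == 0,
            cfg.nonresponse_streak_days,
            lambda day, run: Alarm(
                pid, AlarmRule.NON_RESPONSE, day,
                f"no response on {run} consecutive days ending day {day}",
            ),
        )
    )

    alarms.extend(_weight_alarms(records, cfg, pid))
    order = {r: i for i, r in enumerate(AlarmRule)}
    alarms.sort(key=lambda a: (a.day_index, order[a.rule]))
    return alarms


def _weight_alarms(
    records: Sequence[DailyRecord], cfg: AlarmRuleConfig, pid: str
) -> list[Alarm]:
    """Sliding fully-observed window; gain = last - min (or last - first when
    ``weight_endpoint_only``), debounced like the streak rules."""
    w = cfg.weight_window_days
    weights = [_numeric_weight(rec) for rec in records]
    days = [rec.day_index for rec in records]

    def window_stats(i: int) -> tuple[float, float] | None:
        """(gain, loss) for the window ending at position i, or None if any
        day lacks a numeric weight."""
        if i + 1 < w:
            return None
        window = weights[i - w + 1 : i + 1]
        if any(v is None for v in window):
            return None
        last = window[-1]
        if cfg.weight_endpoint_only:
            return last - window[0], window[0] - last
        return last - min(window), max(window) - last

    alarms: list[Alarm] = []
    for rule, threshold, which in (
        (AlarmRule.WEIGHT_GAIN, cfg.weight_gain_kg, 0),
        (AlarmRule.WEIGHT_LOSS, cfg.weight_loss_kg, 1),
    ):
        if threshold is None:
            continue
        armed = True
        for i in range(len(records)):
            stats = window_stats(i)
            qualifies = stats is not None and stats[which] >= threshold
            if qualifies:
                if armed:
                    delta = stats[which]
                    verb = "gain" if which == 0 else "loss"
                    alarms.append(
                        Alarm(
                            pid, rule, days[i],
                            f"weight {verb} {delta:.1f} kg over {w} days ending day {days[i]}",
                        )
                    )
                    armed = False
            else:
                armed = True
    return alarms


def dispatch(alarms: Sequence[Alarm]) -> list[Notification]:
    """One notification per alarm, to the patient and the hospital manager."""
    return [Notification(alarm=a) for a in alarms]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

ALARM_COLUMNS = ["patient_id", "rule", "day_index", "detail"]


def alarms_to_frame(alarms: Sequence[Alarm]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": a.patient_id, "rule": a.rule.value,
             "day_index": a.day_index, "detail": a.detail}
            for a in alarms
        ],
        columns=ALARM_COLUMNS,
    )


def alarms_to_csv(alarms: Sequence[Alarm], path: str | Path) -> None:
    alarms_to_frame(alarms).to_csv(path, index=False)


def notifications_to_jsonl(notifications: Sequence[Notification], path: str | Path) -> None:
    lines = [
        json.dumps(
            {
                "patient_id": n.alarm.patient_id,
                "rule": n.alarm.rule.value,
                "day_index": n.alarm.day_index,
                "detail": n.alarm.detail,
                "recipients": sorted(r.value for r in n.recipients),
            }
        )
        for n in notifications
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
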