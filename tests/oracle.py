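"""Independent brute-force oracles for the alarm rules.

These enumerate maximal runs of a day-level predicate directly and are
deliberately written without reference to the engine's scan-and-debounce
implementation: one alarm per maximal qualifying run.
"""

from __future__ import annotations


def maximal_runs(flags: list[bool]) -> list[tuple[int, int]]:
    """All maximal runs of True as (start_day, length), days 1-based."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(flags, start=1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(flags) - start + 1))
    return runs


def streak_alarm_days(flags: list[bool], threshold: int) -> list[int]:
    """One alarm per maximal True-run of length >= threshold, on the day
    the run first reaches the threshold."""
    return [
        start + threshold - 1
        for start, length in maximal_runs(flags)
        if length >= threshold
    ]


def weight_alarm_days(
    weights: list[float | None],
    window: int,
    threshold: float,
    endpoint_only: bool = False,
) -> list[int]:
    """Scan every complete (fully-observed) window; a day qualifies when the
    window's gain meets the threshold; one alarm per maximal qualifying run."""
    n = len(weights)

    def qualifies(day: int) -> bool:  # 1-based day = window end
        if day < window:
            return False
        segment = weights[day - window : day]
        if any(w is None for w in segment):
            return False
        gain = segment[-1] - (segment[0] if endpoint_only else min(segment))
        return gain >= threshold

    flags = [qualifies(d) for d in range(1, n + 1)]
    return [start for start, _ in maximal_runs(flags)]
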