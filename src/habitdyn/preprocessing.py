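"""Day-level preprocessing of timestamped brushing episodes.

Upstream device software turns raw accelerometer traces into discrete
brushing episodes with start timestamps; this module takes over from there.
Episodes are binned by start time into six categories, two context-specific
day-level indicators (morning / evening brushing) are derived by a
priority search, and the study-specific binary outcome is computed.

Bins (half-open intervals, [start, end)):

====================  ==============
morning               05:00 - 12:00
early_afternoon       12:00 - 15:00
late_afternoon        15:00 - 19:00
early_evening         19:00 - 21:00
late_evening          21:00 - 24:00
midnight              00:00 - 05:00
====================  ==============

Morning brushing: a *morning* episode, else an *early_afternoon* one.
Evening brushing: a *late_evening* or *midnight* episode, else an
*early_evening* one.  Mid-day (*late_afternoon*) episodes never count; they
are unrelated to the context-specific target behaviors.  A midnight episode
is attributed to the evening of the **previous** calendar day (a 00:30 brush
belongs to the prior bedtime routine).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

__all__ = [
    "TimeBin",
    "StudyMode",
    "Episode",
    "DayRecord",
    "bin_episode",
    "classify_day",
    "day_outcome",
    "episodes_to_day_records",
]


class TimeBin(str, Enum):
    MORNING = "morning"
    EARLY_AFTERNOON = "early_afternoon"
    LATE_AFTERNOON = "late_afternoon"
    EARLY_EVENING = "early_evening"
    LATE_EVENING = "late_evening"
    MIDNIGHT = "midnight"


class StudyMode(str, Enum):
    """Which day-level outcome a study predicts."""

    TARGET_MORNING = "target_morning"
    TARGET_EVENING = "target_evening"
    BRUSH_TWICE = "brush_twice"


@dataclass(frozen=True)
class Episode:
    participant_id: str
    start: dt.datetime


@dataclass(frozen=True)
class DayRecord:
    participant_id: str
    date: dt.date
    morning: int | None
    evening: int | None
    outcome: int | None


# bin lower bounds in minutes-of-day, ordered; searched with a linear scan
_BIN_EDGES = [
    (0, TimeBin.MIDNIGHT),
    (5 * 60, TimeBin.MORNING),
    (12 * 60, TimeBin.EARLY_AFTERNOON),
    (15 * 60, TimeBin.LATE_AFTERNOON),
    (19 * 60, TimeBin.EARLY_EVENING),
    (21 * 60, TimeBin.LATE_EVENING),
]


def bin_episode(start_time: dt.time) -> TimeBin:
    """Map an episode start time-of-day to its category (total function)."""
    minutes = start_time.hour * 60 + start_time.minute
    result = _BIN_EDGES[0][1]
    for lower, label in _BIN_EDGES:
        if minutes >= lower:
            result = label
    return result


def classify_day(episodes: Iterable[Episode | dt.datetime]) -> tuple[int, int]:
    """Derive (morning, evening) indicators for one participant-date.

    The caller groups episodes by attributed date beforehand (midnight
    episodes belong to the previous date; see module docstring).  Order and
    duplication of episodes are irrelevant.
    """
    bins = set()
    for ep in episodes:
        start = ep.start if isinstance(ep, Episode) else ep
        bins.add(bin_episode(start.time()))
    morning = 1 if TimeBin.MORNING in bins or TimeBin.EARLY_AFTERNOON in bins else 0
    if TimeBin.LATE_EVENING in bins or TimeBin.MIDNIGHT in bins:
        evening = 1
    elif TimeBin.EARLY_EVENING in bins:
        evening = 1
    else:
        evening = 0
    return morning, evening


def day_outcome(
    morning: int | None, evening: int | None, mode: StudyMode | str
) -> int | None:
    """Collapse the two session indicators into the study outcome.

    ``brush_twice`` requires both sessions; the target-session modes return
    the indicator of the session the participant did not perform before the
    intervention.  Missingness propagates.
    """
    mode = StudyMode(mode)
    if mode is StudyMode.TARGET_MORNING:
        return None if morning is None else int(morning)
    if mode is StudyMode.TARGET_EVENING:
        return None if evening is None else int(evening)
    if morning is None or evening is None:
        return None
    return int(morning and evening)


def _attributed_date(start: dt.datetime) -> dt.date:
    if bin_episode(start.time()) is TimeBin.MIDNIGHT:
        return (start - dt.timedelta(days=1)).date()
    return start.date()


def episodes_to_day_records(
    episodes: Iterable[Episode],
    mode: StudyMode | str,
    date_range: tuple[dt.date, dt.date] | None = None,
    missing_days: set[tuple[str, dt.date]] | None = None,
) -> list[DayRecord]:
    """Roll episode timestamps up to day-level records.

    ``date_range`` (inclusive) fixes the calendar span per participant; by
    default it spans each participant's first to last attributed date.  Days
    listed in ``missing_days`` (noise windows flagged upstream by human
    judgment) get all-missing indicators.
    """
    mode = StudyMode(mode)
    missing_days = missing_days or set()
    by_pid: dict[str, dict[dt.date, list[Episode]]] = {}
    for ep in episodes:
        by_pid.setdefault(ep.participant_id, {}).setdefault(
            _attributed_date(ep.start), []
        ).append(ep)

    records: list[DayRecord] = []
    for pid in sorted(by_pid):
        days = by_pid[pid]
        if date_range is not None:
            first, last = date_range
        else:
            first, last = min(days), max(days)
        d = first
        while d <= last:
            if (pid, d) in missing_days:
                records.append(DayRecord(pid, d, None, None, None))
            else:
                morning, evening = classify_day(days.get(d, []))
                records.append(
                    DayRecord(pid, d, morning, evening, day_outcome(morning, evening, mode))
                )
            d += dt.timedelta(days=1)
    return records


def day_records_to_frame(records: Iterable[DayRecord]) -> pd.DataFrame:
    """Tabular view with ``participant_id, date, morning, evening, outcome``."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "date": r.date.isoformat(),
                "morning": r.morning,
                "evening": r.evening,
                "outcome": r.outcome,
            }
            for r in records
        ],
        columns=["participant_id", "date", "morning", "evening", "outcome"],
    )
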