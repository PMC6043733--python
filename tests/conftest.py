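"""Shared builders for diary fixtures (generated programmatically)."""

from __future__ import annotations

import datetime as dt

import pytest

from badiary.diary import ActivityEntry, Diary
from badiary.taxonomy import ActivityCategory

MONDAY = dt.date(2017, 1, 2)  # a Monday


def entry(
    pid: str = "P1",
    date: dt.date = MONDAY,
    slot: int = 0,
    category: ActivityCategory = ActivityCategory.Other,
    pleasure: float | None = None,
    text: str = "activity",
) -> ActivityEntry:
    return ActivityEntry(pid, date, slot, text, category, pleasure)


def make_day(
    pid: str,
    date: dt.date,
    categories: list[ActivityCategory],
    pleasure: float | None = None,
) -> list[ActivityEntry]:
    """Entries filling slots 0..len(categories)-1, one shared pleasure."""
    return [
        entry(pid, date, slot, cat, pleasure)
        for slot, cat in enumerate(categories)
    ]


def make_diary(entries: list[ActivityEntry], pid: str = "P1", **kwargs) -> Diary:
    return Diary(patient_id=pid, entries=entries, **kwargs)


@pytest.fixture
def monday() -> dt.date:
    return MONDAY


def weekdays_from(start: dt.date, n: int) -> list[dt.date]:
    """The first n weekdays on or after start."""
    days = []
    d = start
    while len(days) < n:
        if d.weekday() < 5:
            days.append(d)
        d += dt.timedelta(days=1)
    return days
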