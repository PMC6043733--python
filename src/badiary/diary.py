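"""Core diary containers: hourly activity entries and per-patient diaries.

A BA diary covers 16 hourly slots per day, 07:00-22:59; slot ``k`` covers
clock hour ``7 + k``.  Each slot holds one primary activity; additional
activities recorded in the same slot are kept in an overflow list (they
count toward activity totals but not toward slot occupancy or category
hours).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .taxonomy import ActivityCategory

__all__ = [
    "N_SLOTS",
    "FIRST_HOUR",
    "ActivityEntry",
    "Diary",
    "compliance_rate",
    "slot_from_hour",
]

N_SLOTS = 16
FIRST_HOUR = 7  # slot 0 covers 07:00-07:59


def slot_from_hour(hour: int) -> int:
    """Map a clock hour (7..22) to a slot index (0..15)."""
    slot = int(hour) - FIRST_HOUR
    if not 0 <= slot < N_SLOTS:
        raise ValueError(f"hour {hour} outside the 7 am-10 pm diary grid")
    return slot


@dataclass(slots=True)
class ActivityEntry:
    """One hour-slot record of a patient diary."""

    patient_id: str
    date: dt.date
    slot: int
    raw_text: str
    category: ActivityCategory
    pleasure: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.slot < N_SLOTS:
            raise ValueError(f"slot {self.slot} outside 0..{N_SLOTS - 1}")

    @property
    def clock_hour(self) -> int:
        return FIRST_HOUR + self.slot

    @property
    def is_weekday(self) -> bool:
        return self.date.weekday() < 5


@dataclass
class Diary:
    """All entries of one patient plus the reporting calendar.

    ``entries`` holds at most one primary entry per (date, slot);
    ``overflow`` holds further activities reported in already-occupied
    slots.  ``reporting_days`` is the ordered list of dates the patient was
    enrolled; it may exceed the dates with entries (missed days still count
    in the compliance denominator).
    """

    patient_id: str
    entries: list[ActivityEntry] = field(default_factory=list)
    overflow: list[ActivityEntry] = field(default_factory=list)
    pleasure_scale: tuple[float, float] = (1.0, 10.0)
    reporting_days: list[dt.date] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in list(self.entries) + list(self.overflow):
            if e.patient_id != self.patient_id:
                raise ValueError(
                    f"entry patient {e.patient_id!r} != diary {self.patient_id!r}"
                )
        seen: set[tuple[dt.date, int]] = set()
        for e in self.entries:
            key = (e.date, e.slot)
            if key in seen:
                raise ValueError(f"duplicate primary entry at {key}")
            seen.add(key)
        if not self.reporting_days:
            self.reporting_days = sorted({e.date for e in self.all_entries()})
        else:
            self.reporting_days = sorted(set(self.reporting_days))

    def all_entries(self) -> list[ActivityEntry]:
        """Primary plus overflow entries (activity totals use both)."""
        return list(self.entries) + list(self.overflow)

    @property
    def n_activities(self) -> int:
        return len(self.entries) + len(self.overflow)

    @property
    def dates(self) -> list[dt.date]:
        return sorted({e.date for e in self.entries})

    def slot_grid(self) -> dict[dt.date, dict[int, ActivityEntry]]:
        """Primary entries indexed by date then slot."""
        grid: dict[dt.date, dict[int, ActivityEntry]] = {}
        for e in self.entries:
            grid.setdefault(e.date, {})[e.slot] = e
        return grid

    def has_pleasure_scores(self) -> bool:
        return any(e.pleasure is not None for e in self.all_entries())

    def rescale_pleasure(
        self, target: tuple[float, float] = (1.0, 10.0)
    ) -> "Diary":
        """Return a copy with pleasure scores linearly mapped to ``target``.

        Supports diaries recorded on a different numeric scale (e.g. a
        1-5 paper form) so cohorts can be pooled on a common 1-10 scale.
        """
        lo, hi = self.pleasure_scale
        t_lo, t_hi = target
        if hi <= lo or t_hi <= t_lo:
            raise ValueError("pleasure scales must have max > min")
        scale = (t_hi - t_lo) / (hi - lo)

        def _map(e: ActivityEntry) -> ActivityEntry:
            ps = None if e.pleasure is None else t_lo + (e.pleasure - lo) * scale
            return ActivityEntry(
                e.patient_id, e.date, e.slot, e.raw_text, e.category, ps
            )

        return Diary(
            patient_id=self.patient_id,
            entries=[_map(e) for e in self.entries],
            overflow=[_map(e) for e in self.overflow],
            pleasure_scale=target,
            reporting_days=list(self.reporting_days),
        )


def compliance_rate(diary: Diary) -> float:
    """Hourly compliance: filled (date, slot) cells / (16 x reporting days).

    Duplicate activities in one slot count once (slot occupancy, not
    activity count).  Displayed values are conventionally rounded to whole
    percent.
    """
    if not diary.reporting_days:
        raise ValueError("compliance_rate requires at least one reporting day")
    filled = {(e.date, e.slot) for e in diary.entries}
    return len(filled) / (N_SLOTS * len(diary.reporting_days))
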