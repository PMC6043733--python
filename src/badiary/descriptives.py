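"""Per-patient and pooled diary descriptives.

Covers the summary layer of the pipeline: daily average pleasure (dPS),
per-category hour distributions, pooled category shares across a cohort,
and pleasure-by-category summaries.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .diary import Diary, N_SLOTS
from .taxonomy import ActivityCategory, DISPLAY_NAMES

__all__ = [
    "DaySummary",
    "CategoryDistribution",
    "daily_summaries",
    "category_distribution",
    "pooled_category_distribution",
    "ps_by_category",
    "summaries_frame",
]


@dataclass(slots=True)
class DaySummary:
    """One reporting day of one patient.

    ``avg_ps`` is the mean pleasure over the day's scored entries and is
    absent (None) when no entry carries a score.  ``category_hours`` counts
    primary slots per category (overflow activities do not occupy slots).
    """

    patient_id: str
    date: dt.date
    avg_ps: float | None
    category_hours: dict[ActivityCategory, int]
    n_scored: int
    is_weekday: bool

    @property
    def total_hours(self) -> int:
        return sum(self.category_hours.values())


def daily_summaries(diary: Diary) -> list[DaySummary]:
    """One :class:`DaySummary` per reporting day, in date order.

    Days with entries but no pleasure scores get ``avg_ps = None``
    (rendered as gaps in time-series views); days with no entries at all
    still appear with empty category hours, so missed days remain visible.
    """
    grid = diary.slot_grid()
    scored: dict[dt.date, list[float]] = {}
    for e in diary.all_entries():
        if e.pleasure is not None:
            scored.setdefault(e.date, []).append(e.pleasure)

    out: list[DaySummary] = []
    for date in diary.reporting_days:
        hours: dict[ActivityCategory, int] = {}
        for entry in grid.get(date, {}).values():
            hours[entry.category] = hours.get(entry.category, 0) + 1
        ps = scored.get(date, [])
        out.append(
            DaySummary(
                patient_id=diary.patient_id,
                date=date,
                avg_ps=float(np.mean(ps)) if ps else None,
                category_hours=hours,
                n_scored=len(ps),
                is_weekday=date.weekday() < 5,
            )
        )
    return out


def summaries_frame(summaries: Iterable[DaySummary]) -> pd.DataFrame:
    """Tabular view of day summaries (one row per day)."""
    rows = []
    for s in summaries:
        row = {
            "patient_id": s.patient_id,
            "date": s.date,
            "avg_ps": s.avg_ps,
            "n_scored": s.n_scored,
            "is_weekday": s.is_weekday,
        }
        for cat in ActivityCategory:
            row[cat.name] = s.category_hours.get(cat, 0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CategoryDistribution:
    """Percentage of classified hours per category (sums to 100)."""

    percentages: dict[ActivityCategory, float]
    total_hours: int

    def __post_init__(self) -> None:
        for cat in ActivityCategory:
            self.percentages.setdefault(cat, 0.0)
        if any(v < 0 for v in self.percentages.values()):
            raise ValueError("category percentages must be non-negative")
        total = sum(self.percentages.values())
        if self.total_hours > 0 and not math.isclose(total, 100.0, abs_tol=0.35):
            raise ValueError(f"percentages sum to {total}, expected 100")

    def rounded(self, ndigits: int = 2) -> dict[ActivityCategory, float]:
        """Display form: 2 decimals, mirroring published distribution tables."""
        return {c: round(v, ndigits) for c, v in self.percentages.items()}

    def as_series(self) -> pd.Series:
        return pd.Series(
            {DISPLAY_NAMES[c]: self.percentages[c] for c in ActivityCategory},
            name="percent",
        )


def _distribution_from_counts(
    counts: dict[ActivityCategory, int]
) -> CategoryDistribution:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified entries to distribute")
    return CategoryDistribution(
        percentages={c: 100.0 * counts.get(c, 0) / total for c in ActivityCategory},
        total_hours=total,
    )


def category_distribution(diary: Diary) -> CategoryDistribution:
    """Share of each activity category among a patient's reported activities."""
    counts: dict[ActivityCategory, int] = {}
    entries = diary.all_entries()
    if not entries:
        raise ValueError(f"diary {diary.patient_id} has no entries")
    for e in entries:
        counts[e.category] = counts.get(e.category, 0) + 1
    return _distribution_from_counts(counts)


def pooled_category_distribution(
    diaries: Iterable[Diary],
    weighting: Literal["by_activity_count", "by_hours"] = "by_activity_count",
) -> CategoryDistribution:
    """Cohort-level category shares pooled over raw entries.

    ``by_activity_count`` pools every reported activity (overflow
    included); ``by_hours`` pools occupied slots only, so multi-activity
    hours count once.  Pooling raw entries makes the result the
    entry-count-weighted mean of the per-patient distributions.
    """
    diaries = list(diaries)
    if not diaries:
        raise ValueError("need at least one diary to pool")
    counts: dict[ActivityCategory, int] = {}
    for diary in diaries:
        entries = diary.all_entries() if weighting == "by_activity_count" else diary.entries
        for e in entries:
            counts[e.category] = counts.get(e.category, 0) + 1
    return _distribution_from_counts(counts)


def ps_by_category(
    diaries: Iterable[Diary],
) -> pd.DataFrame:
    """Mean, sample SD and n of pleasure per category across patients.

    Categories with no scored entries get NaN mean/SD and ``n = 0``;
    single-observation categories have an undefined (NaN) SD.  SD uses the
    n-1 denominator.
    """
    values: dict[ActivityCategory, list[float]] = {c: [] for c in ActivityCategory}
    any_scored = False
    for diary in diaries:
        for e in diary.all_entries():
            if e.pleasure is not None:
                values[e.category].append(e.pleasure)
                any_scored = True
    if not any_scored:
        raise ValueError("no scored entries in any category")
    rows = []
    for cat in ActivityCategory:
        vals = np.asarray(values[cat], dtype=float)
        rows.append(
            {
                "category": cat.name,
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sd": float(vals.std(ddof=1)) if vals.size >= 2 else float("nan"),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("category")
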