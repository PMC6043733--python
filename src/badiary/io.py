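"""Reading and writing hourly activity-diary tables.

The diary CSV dialect is UTF-8, comma-separated, with a header row and
ISO-8601 dates.  Expected columns (case-insensitive, common aliases
accepted):

``patient_id, date, slot (or hour), raw_text, category?, pleasure?``

Rows lacking a category are categorized through the keyword lexicon.
Malformed rows never abort a parse; they are collected per-row in a
:class:`ParseReport` with a machine-readable error kind.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .diary import N_SLOTS, ActivityEntry, Diary, slot_from_hour
from .taxonomy import ActivityCategory, CategoryLexicon, DEFAULT_LEXICON

__all__ = ["ParseReport", "RowError", "parse_diary_table", "write_diary_csv"]

_COLUMN_ALIASES = {
    "patient_id": {"patient_id", "patient", "id", "subject", "subject_id"},
    "date": {"date", "day"},
    "slot": {"slot", "slot_index", "timeslot"},
    "hour": {"hour", "clock_hour", "time"},
    "raw_text": {"raw_text", "activity", "activity_text", "text"},
    "category": {"category", "ac", "activity_category"},
    "pleasure": {"pleasure", "ps", "pleasure_score"},
}


@dataclass(slots=True)
class RowError:
    row: int
    kind: str  # bad_date | grid_violation | bad_pleasure | bad_slot | empty_text | bad_category
    message: str


@dataclass
class ParseReport:
    """Per-row parse errors and summary counts."""

    errors: list[RowError] = field(default_factory=list)
    n_rows: int = 0
    n_parsed: int = 0
    n_duplicates: int = 0

    def count(self, kind: str) -> int:
        return sum(1 for e in self.errors if e.kind == kind)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def _canonical_columns(df: pd.DataFrame) -> dict[str, str]:
    mapping: dict[str, str] = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower and canon not in mapping:
                mapping[canon] = lower[alias]
    return mapping


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    return dt.date.fromisoformat(text)


def _parse_slot(slot_val, hour_val) -> int:
    """Resolve a slot index from a slot column or a clock-hour column."""
    if slot_val is not None and not pd.isna(slot_val):
        slot = int(slot_val)
        if not 0 <= slot < N_SLOTS:
            raise _GridViolation(f"slot {slot} outside 0..{N_SLOTS - 1}")
        return slot
    if hour_val is None or pd.isna(hour_val):
        raise ValueError("row has neither slot nor hour")
    text = str(hour_val).strip()
    if ":" in text:
        text = text.split(":", 1)[0]
    hour = int(float(text))
    try:
        return slot_from_hour(hour)
    except ValueError as exc:
        raise _GridViolation(str(exc)) from None


class _GridViolation(ValueError):
    pass


def parse_diary_table(
    rows: pd.DataFrame | str | Path,
    lexicon: CategoryLexicon | None = None,
    pleasure_scale: tuple[float, float] = (1.0, 10.0),
    reporting_days: dict[str, list[dt.date]] | None = None,
) -> tuple[dict[str, Diary], ParseReport]:
    """Parse a diary table into one :class:`Diary` per patient.

    Parameters
    ----------
    rows
        A DataFrame or a CSV path with the diary columns.  Either a
        ``slot`` (0-15) or an ``hour`` (07:00-22:00 or 7-22) column is
        required; ``slot`` is preferred when both are present.
    lexicon
        Keyword lexicon used for rows without an explicit category.
    pleasure_scale
        (min, max) of the diary's pleasure rating scale.
    reporting_days
        Optional per-patient enrollment calendar; defaults to the dates
        observed in the data.

    Returns
    -------
    (diaries, report)
        Diaries keyed by patient id, and the parse report with counted,
        skipped rows (unparseable date, off-grid hour, out-of-scale
        pleasure, empty activity text).
    """
    if lexicon is None:
        lexicon = DEFAULT_LEXICON
    if isinstance(rows, (str, Path)):
        df = pd.read_csv(rows, dtype={"date": str})
    else:
        df = rows.copy()
    if df.empty:
        raise ValueError("diary table is empty")
    cols = _canonical_columns(df)
    for required in ("patient_id", "date", "raw_text"):
        if required not in cols:
            raise ValueError(f"diary table lacks a {required} column")
    if "slot" not in cols and "hour" not in cols:
        raise ValueError("diary table needs a slot or hour column")

    report = ParseReport(n_rows=len(df))
    ps_min, ps_max = pleasure_scale
    primary: dict[str, dict[tuple[dt.date, int], ActivityEntry]] = {}
    overflow: dict[str, list[ActivityEntry]] = {}

    def _get(record, canon):
        col = cols.get(canon)
        return record[col] if col is not None else None

    for idx, record in enumerate(df.to_dict("records")):
        try:
            pid = str(_get(record, "patient_id")).strip()
            date = _parse_date(_get(record, "date"))
        except (ValueError, TypeError) as exc:
            report.errors.append(RowError(idx, "bad_date", str(exc)))
            continue
        try:
            slot = _parse_slot(_get(record, "slot"), _get(record, "hour"))
        except _GridViolation as exc:
            report.errors.append(RowError(idx, "grid_violation", str(exc)))
            continue
        except (ValueError, TypeError) as exc:
            report.errors.append(RowError(idx, "bad_slot", str(exc)))
            continue
        raw_text = _get(record, "raw_text")
        raw_text = "" if raw_text is None or pd.isna(raw_text) else str(raw_text)
        if not raw_text.strip():
            report.errors.append(RowError(idx, "empty_text", "empty activity text"))
            continue
        ps_val = _get(record, "pleasure")
        pleasure: float | None = None
        if ps_val is not None and not pd.isna(ps_val):
            try:
                pleasure = float(ps_val)
            except (TypeError, ValueError):
                report.errors.append(
                    RowError(idx, "bad_pleasure", f"unparseable pleasure {ps_val!r}")
                )
                continue
            if not ps_min <= pleasure <= ps_max:
                report.errors.append(
                    RowError(
                        idx,
                        "bad_pleasure",
                        f"pleasure {pleasure} outside scale {pleasure_scale}",
                    )
                )
                continue
        cat_val = _get(record, "category")
        if cat_val is not None and not pd.isna(cat_val) and str(cat_val).strip():
            try:
                category = ActivityCategory.from_label(cat_val)
            except ValueError as exc:
                report.errors.append(RowError(idx, "bad_category", str(exc)))
                continue
        else:
            category = lexicon.categorize(raw_text)

        entry = ActivityEntry(pid, date, slot, raw_text.strip(), category, pleasure)
        slots = primary.setdefault(pid, {})
        key = (date, slot)
        if key in slots:
            overflow.setdefault(pid, []).append(entry)
            report.n_duplicates += 1
        else:
            slots[key] = entry
        report.n_parsed += 1

    diaries = {
        pid: Diary(
            patient_id=pid,
            entries=list(slots.values()),
            overflow=overflow.get(pid, []),
            pleasure_scale=pleasure_scale,
            reporting_days=(reporting_days or {}).get(pid, []),
        )
        for pid, slots in primary.items()
    }
    return diaries, report


def write_diary_csv(
    diaries: dict[str, Diary] | list[Diary], path: str | Path
) -> pd.DataFrame:
    """Write diaries to the diary CSV dialect; returns the frame written.

    Columns: patient_id, date (ISO), slot, raw_text, category, pleasure.
    A subsequent :func:`parse_diary_table` reproduces entries exactly.
    """
    if isinstance(diaries, dict):
        diaries = list(diaries.values())
    records = []
    for diary in diaries:
        for e in sorted(
            diary.all_entries(), key=lambda e: (e.patient_id, e.date, e.slot)
        ):
            records.append(
                {
                    "patient_id": e.patient_id,
                    "date": e.date.isoformat(),
                    "slot": e.slot,
                    "raw_text": e.raw_text,
                    "category": e.category.name,
                    "pleasure": e.pleasure,
                }
            )
    df = pd.DataFrame.from_records(
        records,
        columns=["patient_id", "date", "slot", "raw_text", "category", "pleasure"],
    )
    df.to_csv(path, index=False)
    return df
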