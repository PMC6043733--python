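"""Diary parsing, writing, compliance, and round-trip integrity."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from badiary.diary import ActivityEntry, Diary, compliance_rate
from badiary.io import parse_diary_table, write_diary_csv
from badiary.synthetic import CohortConfig, generate_cohort
from badiary.taxonomy import ActivityCategory

from conftest import MONDAY, entry, make_diary


def frame(rows):
    return pd.DataFrame(rows)


def test_hour_7am_maps_to_slot_zero_and_lexicon_categorizes():
    df = frame(
        [{"patient": "P1", "date": "2017-01-02", "hour": "07:00",
          "activity": "sleeping", "pleasure": 3}]
    )
    diaries, report = parse_diary_table(df)
    assert report.n_parsed == 1 and not report.errors
    (e,) = diaries["P1"].entries
    assert e.slot == 0
    assert e.category is ActivityCategory.DailyLiving
    assert e.pleasure == 3


def test_hour_outside_grid_rejected_with_grid_violation():
    df = frame(
        [
            {"patient": "P1", "date": "2017-01-02", "hour": "23:00",
             "activity": "sleeping"},
            {"patient": "P1", "date": "2017-01-02", "hour": "08:00",
             "activity": "work"},
        ]
    )
    diaries, report = parse_diary_table(df)
    assert report.count("grid_violation") == 1
    assert len(diaries["P1"].entries) == 1


def test_bad_date_and_out_of_scale_pleasure_are_row_level_errors():
    df = frame(
        [
            {"patient": "P1", "date": "not-a-date", "slot": 1, "activity": "work"},
            {"patient": "P1", "date": "2017-01-02", "slot": 2, "activity": "work",
             "pleasure": 14},
            {"patient": "P1", "date": "2017-01-02", "slot": 3, "activity": ""},
        ]
    )
    diaries, report = parse_diary_table(df)
    assert report.count("bad_date") == 1
    assert report.count("bad_pleasure") == 1
    assert report.count("empty_text") == 1
    assert "P1" not in diaries or not diaries["P1"].entries


def test_full_patient_table_yields_expected_days_and_entries():
    # 185 well-formed rows over 12 days -> 185 entries, 12 distinct dates
    rows = []
    start = dt.date(2017, 1, 2)
    for k in range(185):
        day, slot = divmod(k, 16)
        rows.append(
            {"patient": "P1", "date": (start + dt.timedelta(days=day)).isoformat(),
             "slot": slot, "activity": "work"}
        )
    diaries, report = parse_diary_table(frame(rows))
    diary = diaries["P1"]
    assert diary.n_activities == 185
    assert len(diary.dates) == 12
    assert round(100 * compliance_rate(diary)) == 96


def test_duplicate_slot_rows_become_overflow():
    df = frame(
        [
            {"patient": "P1", "date": "2017-01-02", "slot": 4, "activity": "work"},
            {"patient": "P1", "date": "2017-01-02", "slot": 4, "activity": "lecture"},
        ]
    )
    diaries, report = parse_diary_table(df)
    diary = diaries["P1"]
    assert len(diary.entries) == 1
    assert len(diary.overflow) == 1
    assert diary.n_activities == 2
    assert report.n_duplicates == 1
    # duplicates do not change slot occupancy
    assert compliance_rate(diary) == 1 / 16


@pytest.mark.parametrize(
    "days, filled, expected",
    [(1, 16, 1.0), (10, 80, 0.5)],
)
def test_compliance_rate_fractions(days, filled, expected):
    entries = []
    start = dt.date(2017, 1, 2)
    for k in range(filled):
        day, slot = divmod(k, 16)
        entries.append(entry("P1", start + dt.timedelta(days=day), slot))
    diary = make_diary(
        entries,
        reporting_days=[start + dt.timedelta(days=i) for i in range(days)],
    )
    assert compliance_rate(diary) == pytest.approx(expected)


def test_compliance_requires_reporting_days():
    diary = Diary(patient_id="P1")
    diary.reporting_days = []
    with pytest.raises(ValueError):
        compliance_rate(diary)


def test_csv_round_trip_preserves_entries_exactly(tmp_path):
    cfg = CohortConfig(n_patients=3, n_days=10, round_pleasure=False)
    diaries, _ = generate_cohort(cfg, seed=7)
    path = tmp_path / "diaries.csv"
    write_diary_csv(diaries, path)
    parsed, report = parse_diary_table(path)
    assert not report.errors
    for diary in diaries:
        other = parsed[diary.patient_id]
        orig = sorted(diary.all_entries(), key=lambda e: (e.date, e.slot))
        back = sorted(other.all_entries(), key=lambda e: (e.date, e.slot))
        assert len(orig) == len(back)
        for a, b in zip(orig, back):
            assert (a.date, a.slot, a.raw_text, a.category) == (
                b.date, b.slot, b.raw_text, b.category
            )
            assert a.pleasure == pytest.approx(b.pleasure)


def test_pleasure_rescale_maps_five_point_scale_to_ten_point():
    diary = make_diary(
        [entry("P1", MONDAY, 0, ActivityCategory.Social, pleasure=1.0),
         entry("P1", MONDAY, 1, ActivityCategory.Social, pleasure=5.0),
         entry("P1", MONDAY, 2, ActivityCategory.Social, pleasure=3.0)],
        pleasure_scale=(1.0, 5.0),
    )
    scaled = diary.rescale_pleasure((1.0, 10.0))
    assert [e.pleasure for e in scaled.entries] == [1.0, 10.0, 5.5]


def test_diary_rejects_duplicate_primary_and_foreign_entries():
    with pytest.raises(ValueError):
        make_diary([entry(slot=0), entry(slot=0)])
    with pytest.raises(ValueError):
        make_diary([entry(pid="P2")], pid="P1")
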