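"""Daily summaries, category distributions, pooling, pleasure by category."""

import datetime as dt

import numpy as np
import pytest

from badiary import descriptives
from badiary.descriptives import (
    category_distribution,
    daily_summaries,
    pooled_category_distribution,
    ps_by_category,
)
from badiary.synthetic import CohortConfig, generate_cohort
from badiary.taxonomy import ActivityCategory

from conftest import MONDAY, entry, make_day, make_diary

Mv, So = ActivityCategory.Movement, ActivityCategory.Social


def test_day_average_is_mean_of_scored_entries():
    diary = make_diary(
        [entry(slot=0, pleasure=4.0), entry(slot=1, pleasure=6.0),
         entry(slot=2, pleasure=None)]
    )
    (s,) = daily_summaries(diary)
    assert s.avg_ps == pytest.approx(5.0)
    assert s.n_scored == 2


def test_day_without_scores_has_absent_average():
    diary = make_diary([entry(slot=0), entry(slot=1)])
    (s,) = daily_summaries(diary)
    assert s.avg_ps is None and s.n_scored == 0
    assert s.total_hours == 2


def test_one_summary_per_reporting_day_in_order():
    days = [MONDAY + dt.timedelta(days=i) for i in range(28)]
    diary = make_diary([entry(date=d) for d in days[::2]], reporting_days=days)
    summaries = daily_summaries(diary)
    assert len(summaries) == 28
    assert [s.date for s in summaries] == days
    # missed days appear with empty hours
    assert summaries[1].total_hours == 0


def test_summaries_stable_under_entry_order_permutation():
    entries = make_day("P1", MONDAY, [Mv, So, Mv], pleasure=5.0)
    a = daily_summaries(make_diary(entries))
    b = daily_summaries(make_diary(entries[::-1]))
    assert a == b


def test_distribution_simple_shares():
    diary = make_diary(
        make_day("P1", MONDAY, [Mv] * 4 + [So] * 12)
    )
    dist = category_distribution(diary)
    assert dist.percentages[Mv] == pytest.approx(25.0)
    assert dist.percentages[So] == pytest.approx(75.0)
    assert dist.percentages[ActivityCategory.Other] == 0.0


def test_uniform_distribution_over_all_categories():
    cats = [c for c in ActivityCategory for _ in range(2)]
    entries = [
        entry(date=MONDAY + dt.timedelta(days=i // 16), slot=i % 16, category=c)
        for i, c in enumerate(cats)
    ]
    dist = category_distribution(make_diary(entries))
    for c in ActivityCategory:
        assert dist.percentages[c] == pytest.approx(100 / 7)


def test_distribution_sums_to_100_on_random_diaries():
    rng = np.random.default_rng(0)
    cats = list(ActivityCategory)
    for _ in range(25):
        entries = [
            entry(date=MONDAY + dt.timedelta(days=k // 16), slot=k % 16,
                  category=cats[rng.integers(7)])
            for k in range(int(rng.integers(1, 120)))
        ]
        dist = category_distribution(make_diary(entries))
        assert sum(dist.percentages.values()) == pytest.approx(100.0)
        assert sum(dist.rounded().values()) == pytest.approx(100.0, abs=0.05 * 7)


def test_empty_diary_rejected():
    with pytest.raises(ValueError):
        category_distribution(make_diary([]))


def test_pooling_single_diary_equals_own_distribution():
    diary = make_diary(make_day("P1", MONDAY, [Mv, Mv, So]))
    assert (
        pooled_category_distribution([diary]).percentages
        == category_distribution(diary).percentages
    )


def test_pooling_two_equal_count_diaries_is_elementwise_mean():
    d1 = make_diary(make_day("P1", MONDAY, [So] * 8), pid="P1")
    d2 = make_diary(make_day("P2", MONDAY, [Mv] * 8), pid="P2")
    pooled = pooled_category_distribution([d1, d2])
    assert pooled.percentages[So] == pytest.approx(50.0)
    assert pooled.percentages[Mv] == pytest.approx(50.0)
    # general oracle: pooled equals entry-count-weighted mean of patient shares
    d3 = make_diary(make_day("P3", MONDAY, [Mv, Mv, So, So, So, So]), pid="P3")
    pooled = pooled_category_distribution([d1, d2, d3])
    counts = {Mv: 8 + 2, So: 8 + 4}
    total = 22
    for c in (Mv, So):
        assert pooled.percentages[c] == pytest.approx(100 * counts[c] / total)


def test_ps_by_category_mean_sd_and_single_score_flag():
    diary = make_diary(
        [entry(slot=0, category=Mv, pleasure=6.0),
         entry(slot=1, category=Mv, pleasure=8.0),
         entry(slot=2, category=So, pleasure=5.0)]
    )
    table = ps_by_category([diary])
    assert table.loc["Movement", "mean"] == pytest.approx(7.0)
    assert table.loc["Movement", "sd"] == pytest.approx(np.sqrt(2))
    assert table.loc["Social", "n"] == 1
    assert np.isnan(table.loc["Social", "sd"])  # single score: SD undefined
    assert table.loc["Other", "n"] == 0
    assert np.isnan(table.loc["Other", "mean"])


def test_planted_category_effect_recovered_from_generator():
    # isolate category effects: no lag, no social curve, modest noise
    cfg = CohortConfig(
        n_patients=7, n_days=28, lag_gamma=0.0, social_curvature=0.0,
        noise_sd=1.0,
    )
    diaries, truth = generate_cohort(cfg, seed=11)
    table = ps_by_category(diaries)
    planted = 5.0 + truth.category_effects[Mv]
    n = table.loc["Movement", "n"]
    mc_err = 3 * table.loc["Movement", "sd"] / np.sqrt(n)
    assert table.loc["Movement", "mean"] == pytest.approx(planted, abs=max(mc_err, 0.2))
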