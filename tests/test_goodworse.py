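"""Median split, distance weights, and the Wilcoxon signed-rank contrast."""

import datetime as dt
import itertools

import numpy as np
import pytest
from scipy import stats

from badiary import descriptives
from badiary.goodworse import (
    category_goodworse_table,
    median_split,
    weighted_category_hours,
    wilcoxon_signed_rank,
)
from badiary.taxonomy import ActivityCategory

from conftest import MONDAY, entry, make_day, make_diary, weekdays_from

So, Sp = ActivityCategory.Social, ActivityCategory.SpareTime


def diary_with_daily_ps(ps_values, hours_by_day=None):
    entries = []
    days = weekdays_from(MONDAY, len(ps_values))
    for i, (d, ps) in enumerate(zip(days, ps_values)):
        cats = hours_by_day[i] if hours_by_day else [So] * 4
        entries.extend(make_day("P1", d, cats, pleasure=ps))
    return make_diary(entries)


def test_median_split_even_case_labels_and_weights():
    diary = diary_with_daily_ps([3, 4, 5, 6])
    split = median_split(descriptives.daily_summaries(diary))
    assert split.median_ps == pytest.approx(4.5)
    labels = [split.day_labels[d] for d in sorted(split.day_labels)]
    assert labels == ["worse", "worse", "good", "good"]
    weights = [split.day_weights[d] for d in sorted(split.day_weights)]
    assert weights == pytest.approx([1.5, 0.5, 0.5, 1.5])


def test_day_at_median_is_worse_with_zero_weight():
    diary = diary_with_daily_ps([3, 5, 7])
    split = median_split(descriptives.daily_summaries(diary))
    mid = sorted(split.day_labels)[1]
    assert split.day_labels[mid] == "worse"
    assert split.day_weights[mid] == 0.0


def test_all_equal_days_have_zero_weights():
    diary = diary_with_daily_ps([5, 5, 5, 5])
    split = median_split(descriptives.daily_summaries(diary))
    assert all(w == 0 for w in split.day_weights.values())


def test_split_invariant_to_day_order():
    diary = diary_with_daily_ps([2, 7, 4, 6, 3])
    summaries = descriptives.daily_summaries(diary)
    a = median_split(summaries)
    b = median_split(summaries[::-1])
    assert a.day_labels == b.day_labels and a.day_weights == b.day_weights


def test_median_split_needs_two_scored_days():
    diary = diary_with_daily_ps([5])
    with pytest.raises(ValueError):
        median_split(descriptives.daily_summaries(diary))


def test_weighted_hours_are_products_of_hours_and_weights():
    # 4 days, PS (3, 4, 6, 7) -> median 5, weights (2, 1, 1, 2)
    hours = [[So] * 3, [So] * 1, [So] * 2, [So] * 4]
    diary = diary_with_daily_ps([3, 4, 6, 7], hours_by_day=hours)
    summaries = descriptives.daily_summaries(diary)
    split = median_split(summaries)
    good, worse = weighted_category_hours(split, summaries, So)
    assert worse == pytest.approx([3 * 2.0, 1 * 1.0])
    assert good == pytest.approx([2 * 1.0, 4 * 2.0])
    # a category absent that day contributes 0 regardless of weight
    good_sp, worse_sp = weighted_category_hours(split, summaries, Sp)
    assert good_sp == [0, 0] and worse_sp == [0, 0]


def test_weighted_hours_rejects_unknown_category():
    diary = diary_with_daily_ps([3, 6])
    summaries = descriptives.daily_summaries(diary)
    split = median_split(summaries)
    with pytest.raises(ValueError):
        weighted_category_hours(split, summaries, "NotACategory")


# --- signed-rank test -------------------------------------------------------


def brute_force_two_sided_p(diffs):
    """Independent oracle: enumerate every sign assignment explicitly."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(diffs))
    n = len(diffs)
    mu = n * (n + 1) / 4
    w_obs = ranks[diffs > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def test_exact_p_for_three_positive_differences():
    res = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0], pairing="index", mode="exact")
    assert res.p == pytest.approx(0.25)  # 2 of 8 assignments as extreme
    assert res.direction == 1


def test_identical_samples_are_degenerate():
    res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3], pairing="index")
    assert res.degenerate and res.p == 1.0 and res.z == 0.0 and res.n_pairs == 0


def test_exact_mode_matches_full_enumeration_oracle():
    rng = np.random.default_rng(5)
    for _ in range(60):
        n = int(rng.integers(2, 11))
        diffs = rng.normal(size=n)
        res = wilcoxon_signed_rank(diffs, np.zeros(n), pairing="index", mode="exact")
        assert res.p == pytest.approx(brute_force_two_sided_p(diffs))


def test_exact_mode_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(6)
    for _ in range(40):
        n = int(rng.integers(4, 13))
        diffs = rng.normal(size=n)
        res = wilcoxon_signed_rank(diffs, np.zeros(n), pairing="index", mode="exact")
        ref = stats.wilcoxon(diffs, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue)


def test_normal_approximation_close_to_exact_for_n_at_least_12():
    rng = np.random.default_rng(7)
    for _ in range(40):
        n = int(rng.integers(12, 19))
        diffs = rng.normal(size=n)
        exact = wilcoxon_signed_rank(diffs, np.zeros(n), pairing="index", mode="exact")
        normal = wilcoxon_signed_rank(diffs, np.zeros(n), pairing="index", mode="normal")
        assert abs(exact.p - normal.p) < 0.02


def test_z_antisymmetric_under_sample_swap():
    rng = np.random.default_rng(8)
    a, b = rng.normal(size=9), rng.normal(size=9)
    r1 = wilcoxon_signed_rank(a, b, pairing="index", mode="normal")
    r2 = wilcoxon_signed_rank(b, a, pairing="index", mode="normal")
    assert r1.z == pytest.approx(-r2.z)
    assert r1.p == pytest.approx(r2.p)


def test_rank_order_pairing_sorts_and_truncates():
    # descending sort + truncation: pairs (9,6), (5,3) -> diffs (3, 2)
    res = wilcoxon_signed_rank([5, 9], [3, 1, 6], pairing="rank_order", mode="exact")
    assert res.n_pairs == 2 and res.direction == 1
    ref = wilcoxon_signed_rank([3, 2], [0, 0], pairing="index", mode="exact")
    assert res.p == pytest.approx(ref.p)


def test_index_pairing_truncates_unequal_groups_in_given_order():
    res = wilcoxon_signed_rank([5, 9, 7], [3, 1], pairing="index", mode="exact")
    assert res.n_pairs == 2  # pairs (5,3), (9,1); the third value is dropped
    ref = wilcoxon_signed_rank([2, 8], [0, 0], pairing="index", mode="exact")
    assert res.p == pytest.approx(ref.p)


def test_exact_mode_caps_sample_size():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank(np.arange(1, 25), np.zeros(24), pairing="index",
                             mode="exact")


# --- per-category table -----------------------------------------------------


def test_planted_spare_time_excess_on_low_ps_days_detected():
    # low-PS days carry many SpareTime hours, high-PS days none
    rng = np.random.default_rng(9)
    days = weekdays_from(MONDAY, 20)
    entries = []
    for i, d in enumerate(days):
        low = i % 2 == 0
        ps = (3.0 if low else 7.0) + rng.normal(0, 0.3)
        cats = [Sp] * 8 + [So] * 4 if low else [So] * 8
        entries.extend(make_day("P6", d, cats, pleasure=round(ps, 2)))
    diary = make_diary(entries, pid="P6")
    table = category_goodworse_table(diary)
    res = table.results[Sp]
    assert res.significant(0.05)
    assert res.direction == -1  # more spare time on worse days
    assert res.z < 0


def test_patient_without_scores_is_skipped_with_reason():
    diary = make_diary(make_day("P4", MONDAY, [So] * 6), pid="P4")
    table = category_goodworse_table(diary)
    assert table.skipped
    assert "no pleasure scores" in table.skipped_reason


def test_bimodal_days_label_accuracy_is_perfect():
    diary = diary_with_daily_ps([2, 2, 2, 8, 8, 8])
    split = median_split(descriptives.daily_summaries(diary))
    days = sorted(split.day_labels)
    assert [split.day_labels[d] for d in days] == ["worse"] * 3 + ["good"] * 3
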