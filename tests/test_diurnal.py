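"""Diurnal template, Jaccard adherence, pairing rule, and the ANCOVA."""

import datetime as dt

import numpy as np
import pytest
import statsmodels.api as sm

from badiary.diary import N_SLOTS
from badiary.diurnal import (
    AdherencePair,
    adherence_change_pairs,
    build_template,
    day_jaccard,
    per_subject_correlation,
    within_subject_ancova,
)
from badiary.synthetic import CohortConfig, generate_cohort
from badiary.taxonomy import ActivityCategory

from conftest import MONDAY, entry, make_day, make_diary, weekdays_from

Mv = ActivityCategory.Movement
So = ActivityCategory.Social
DL = ActivityCategory.DailyLiving


def test_template_takes_clear_slot_mode():
    days = weekdays_from(MONDAY, 7)
    entries = [entry("P1", d, 0, DL) for d in days[:5]]
    entries += [entry("P1", d, 0, So) for d in days[5:]]
    tpl = build_template(make_diary(entries))
    assert tpl.slot_modes[0] is DL
    assert tpl.support[0] == 7


def test_template_tie_breaks_by_lower_ordinal():
    days = weekdays_from(MONDAY, 2)
    entries = [entry("P1", days[0], 3, So), entry("P1", days[1], 3, Mv)]
    tpl = build_template(make_diary(entries))
    assert tpl.slot_modes[3] is Mv  # ordinal 0 beats 5


def test_template_ignores_weekends_and_marks_empty_slots():
    saturday = MONDAY + dt.timedelta(days=5)
    entries = [entry("P1", MONDAY, 0, DL), entry("P1", saturday, 1, So)]
    tpl = build_template(make_diary(entries))
    assert tpl.slot_modes[0] is DL
    assert tpl.slot_modes[1] is None  # weekend entry must not contribute
    assert tpl.support[1] == 0


def test_template_requires_weekday_entries():
    saturday = MONDAY + dt.timedelta(days=5)
    with pytest.raises(ValueError):
        build_template(make_diary([entry("P1", saturday, 0, So)]))


def test_template_invariant_to_day_order():
    rng = np.random.default_rng(3)
    days = weekdays_from(MONDAY, 10)
    cats = list(ActivityCategory)
    entries = [
        entry("P1", d, s, cats[rng.integers(7)])
        for d in days
        for s in range(N_SLOTS)
    ]
    a = build_template(make_diary(entries))
    b = build_template(make_diary(entries[::-1]))
    assert a.slot_modes == b.slot_modes and a.support == b.support


def make_template_diary(day_cats_by_date):
    entries = []
    for d, cats in day_cats_by_date.items():
        entries.extend(
            entry("P1", d, s, c) for s, c in enumerate(cats) if c is not None
        )
    return make_diary(entries)


def test_jaccard_full_match_half_match_and_missing_slots():
    days = weekdays_from(MONDAY, 3)
    template_cats = [DL] * 8 + [So] * 8
    diary = make_template_diary(
        {
            days[0]: template_cats,
            days[1]: [DL] * 8 + [Mv] * 8,  # 8 of 16 match
            days[2]: template_cats[:12] + [None] * 4,  # 4 unfilled
        }
    )
    tpl = build_template(make_template_diary({days[0]: template_cats}))
    assert tpl.slot_modes[:8] == [DL] * 8
    assert day_jaccard(diary, days[0], tpl) == pytest.approx(1.0)
    assert day_jaccard(diary, days[1], tpl) == pytest.approx(0.5)
    assert day_jaccard(diary, days[2], tpl) == pytest.approx(12 / 16)
    # filled-slots variant divides by the day's filled slots instead
    assert day_jaccard(diary, days[2], tpl, denominator="filled_slots") == 1.0


def test_jaccard_rejects_weekends():
    diary = make_diary([entry("P1", MONDAY, 0, DL)])
    tpl = build_template(diary)
    with pytest.raises(ValueError):
        day_jaccard(diary, MONDAY + dt.timedelta(days=5), tpl)


def test_jaccard_monotone_under_slot_corruption():
    days = weekdays_from(MONDAY, 2)
    cats = [DL] * 16
    diary = make_template_diary({days[0]: cats, days[1]: cats})
    tpl = build_template(diary)
    prev = day_jaccard(diary, days[1], tpl)
    assert prev == 1.0
    for k in range(16):
        corrupted = [So] * (k + 1) + [DL] * (15 - k)
        d2 = make_template_diary({days[0]: cats, days[1]: corrupted})
        tpl2 = build_template(make_template_diary({days[0]: cats}))
        jac = day_jaccard(d2, days[1], tpl2)
        assert jac <= prev + 1e-12
        prev = jac


def build_scored_diary(dates, ps_by_date, cats=None):
    cats = cats or [DL] * 4
    entries = []
    for d in dates:
        entries.extend(make_day("P1", d, cats, pleasure=ps_by_date[d]))
    return make_diary(entries)


def test_pairs_require_calendar_adjacent_weekdays():
    mon, tue = MONDAY, MONDAY + dt.timedelta(days=1)
    fri = MONDAY + dt.timedelta(days=4)
    next_mon = MONDAY + dt.timedelta(days=7)
    ps = {mon: 5.0, tue: 6.0, fri: 4.0, next_mon: 7.0}
    diary = build_scored_diary(list(ps), ps)
    tpl = build_template(diary)
    pairs = adherence_change_pairs(diary, tpl)
    assert [p.date_x for p in pairs] == [mon]  # Fri->Mon excluded
    assert pairs[0].delta_ps == pytest.approx(1.0)
    # relaxed rule pairs each weekday with the next available scored weekday
    relaxed = adherence_change_pairs(diary, tpl, consecutive_only=False)
    assert [p.date_x for p in relaxed] == [mon, tue, fri]


def test_twenty_consecutive_weekdays_yield_sixteen_pairs():
    days = weekdays_from(MONDAY, 20)
    ps = {d: 5.0 + (i % 3) for i, d in enumerate(days)}
    diary = build_scored_diary(days, ps)
    tpl = build_template(diary)
    pairs = adherence_change_pairs(diary, tpl)
    assert len(pairs) == 16  # 4 Fridays dropped


def test_ancova_recovers_noiseless_line_through_zero_point():
    rng = np.random.default_rng(1)
    jac = rng.uniform(0, 1, size=30)
    pairs = [
        AdherencePair("P1", MONDAY + dt.timedelta(days=i), j, 2 * (j - 0.44))
        for i, j in enumerate(jac)
    ]
    res = within_subject_ancova(pairs)
    assert res.beta_jac == pytest.approx(2.0)
    assert res.jac_zero == pytest.approx(0.44)
    assert res.correlation == pytest.approx(1.0)


def test_ancova_single_subject_matches_plain_regression_oracle():
    rng = np.random.default_rng(2)
    jac = rng.uniform(0, 1, size=40)
    delta = 1.2 * jac + rng.normal(0, 0.5, size=40)
    pairs = [
        AdherencePair("P1", MONDAY + dt.timedelta(days=i), j, d)
        for i, (j, d) in enumerate(zip(jac, delta))
    ]
    res = within_subject_ancova(pairs)
    X = sm.add_constant(jac)
    ref = sm.OLS(delta, X).fit()
    assert res.beta_jac == pytest.approx(ref.params[1])
    assert res.p == pytest.approx(ref.pvalues[1])
    # partial correlation reduces to the plain Pearson correlation
    assert res.correlation == pytest.approx(np.corrcoef(jac, delta)[0, 1])


def test_ancova_rejects_constant_jac():
    pairs = [
        AdherencePair("P1", MONDAY + dt.timedelta(days=i), 0.5, float(i))
        for i in range(5)
    ]
    with pytest.raises(ValueError):
        within_subject_ancova(pairs)


def test_ancova_null_has_small_correlation():
    rng = np.random.default_rng(4)
    pairs = [
        AdherencePair(f"S{i % 4}", MONDAY + dt.timedelta(days=i),
                      float(rng.uniform(0, 1)), float(rng.normal()))
        for i in range(200)
    ]
    res = within_subject_ancova(pairs)
    assert abs(res.correlation) < 0.15


def test_per_subject_correlation_closed_form():
    pairs = [
        AdherencePair("P3", MONDAY, 0.0, 0.0),
        AdherencePair("P3", MONDAY + dt.timedelta(days=1), 1.0, 1.0),
        AdherencePair("P3", MONDAY + dt.timedelta(days=2), 0.5, -1.0),
    ]
    jac = np.array([0.0, 1.0, 0.5])
    delta = np.array([0.0, 1.0, -1.0])
    expected = (
        np.sum((jac - jac.mean()) * (delta - delta.mean()))
        / np.sqrt(np.sum((jac - jac.mean()) ** 2) * np.sum((delta - delta.mean()) ** 2))
    )
    r, p = per_subject_correlation(pairs, "P3")
    assert r == pytest.approx(expected)
    perfect = [
        AdherencePair("P1", MONDAY + dt.timedelta(days=i), 0.1 * i, 0.2 * i)
        for i in range(5)
    ]
    r2, _ = per_subject_correlation(perfect, "P1")
    assert r2 == pytest.approx(1.0)


def test_per_subject_correlation_guards():
    with pytest.raises(ValueError):
        per_subject_correlation([], "P1")
    const = [
        AdherencePair("P1", MONDAY + dt.timedelta(days=i), 0.5, float(i))
        for i in range(4)
    ]
    with pytest.raises(ValueError):
        per_subject_correlation(const, "P1")


def test_generator_template_recovered_at_high_adherence():
    cfg = CohortConfig(n_patients=1, n_days=56, adherence_fixed=0.9,
                       compliance=0.9)
    diaries, truth = generate_cohort(cfg, seed=10)
    tpl = build_template(diaries[0])
    true_tpl = truth.weekday_templates["S1"]
    matches = sum(a is b for a, b in zip(tpl.slot_modes, true_tpl))
    assert matches >= 15
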