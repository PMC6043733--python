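"""Diurnal-rhythm template, daily adherence (JAC), and its lagged mood effect.

A patient's *diurnal rhythm* is the modal activity category in each of the
16 hour slots, computed over weekdays.  A day's adherence is the Jaccard
similarity (JAC): the fraction of the day's 16 slots whose category matches
the template (unfilled or template-undefined slots count as non-matches by
default).  The association of interest is lagged: the JAC of day ``x``
against the change in daily average pleasure ``dPS(x+1) - dPS(x)``,
estimated with a within-subject ANCOVA (OLS of the PS change on JAC with
dummy-coded subject intercepts).  The fitted line's zero crossing is the
adherence level above which the next day is predicted to improve.

Weekends are excluded throughout: templates are built from weekdays and
day pairs must be calendar-adjacent weekdays (Mon-Tue ... Thu-Fri), so no
pair spans a weekend.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from . import descriptives
from .diary import Diary, N_SLOTS
from .taxonomy import ActivityCategory

__all__ = [
    "DiurnalTemplate",
    "AdherencePair",
    "AncovaResult",
    "build_template",
    "day_jaccard",
    "adherence_change_pairs",
    "within_subject_ancova",
    "per_subject_correlation",
]


@dataclass
class DiurnalTemplate:
    """Per-slot modal category of one patient's weekdays.

    ``slot_modes[k]`` is None when no weekday entry exists in slot ``k``;
    ``support[k]`` counts the weekday entries that informed the mode.
    """

    patient_id: str
    slot_modes: list[ActivityCategory | None]
    support: list[int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slot": range(N_SLOTS),
                "hour": [7 + k for k in range(N_SLOTS)],
                "category": [c.name if c else None for c in self.slot_modes],
                "support": self.support,
            }
        )


def build_template(diary: Diary) -> DiurnalTemplate:
    """Modal category per slot over all weekday entries.

    Ties are broken deterministically by the lower category ordinal;
    weekend entries never contribute.
    """
    counts: list[dict[ActivityCategory, int]] = [dict() for _ in range(N_SLOTS)]
    n_weekday = 0
    for e in diary.entries:
        if e.is_weekday:
            counts[e.slot][e.category] = counts[e.slot].get(e.category, 0) + 1
            n_weekday += 1
    if n_weekday == 0:
        raise ValueError(f"diary {diary.patient_id} has no weekday entries")
    modes: list[ActivityCategory | None] = []
    support: list[int] = []
    for slot_counts in counts:
        if not slot_counts:
            modes.append(None)
            support.append(0)
            continue
        # most frequent; ties -> lowest ordinal
        best = min(slot_counts.items(), key=lambda kv: (-kv[1], kv[0].ordinal))
        modes.append(best[0])
        support.append(sum(slot_counts.values()))
    return DiurnalTemplate(diary.patient_id, modes, support)


def day_jaccard(
    diary: Diary,
    date: dt.date,
    template: DiurnalTemplate,
    denominator: Literal["all_slots", "filled_slots"] = "all_slots",
) -> float:
    """Fraction of the day's slots matching the diurnal template.

    With the default fixed denominator all 16 slots divide the match count
    and unfilled or template-undefined slots count as non-matches; the
    ``filled_slots`` variant divides by the day's filled slots instead.
    """
    if date.weekday() >= 5:
        raise ValueError(f"{date} is a weekend; adherence is weekday-only")
    day_slots = diary.slot_grid().get(date, {})
    matches = sum(
        1
        for slot, entry in day_slots.items()
        if template.slot_modes[slot] is not None
        and entry.category is template.slot_modes[slot]
    )
    if denominator == "all_slots":
        return matches / N_SLOTS
    if denominator == "filled_slots":
        return matches / len(day_slots) if day_slots else 0.0
    raise ValueError(f"unknown denominator convention {denominator!r}")


@dataclass(slots=True)
class AdherencePair:
    """JAC of day x paired with the next weekday's pleasure change."""

    patient_id: str
    date_x: dt.date
    jac: float
    delta_ps: float  # avg_ps(day x+1) - avg_ps(day x), PS units


def adherence_change_pairs(
    diary: Diary,
    template: DiurnalTemplate,
    denominator: Literal["all_slots", "filled_slots"] = "all_slots",
    consecutive_only: bool = True,
) -> list[AdherencePair]:
    """(JAC, next-day PS change) pairs over calendar-adjacent weekdays.

    A pair exists for weekday ``x`` when the next calendar day is also a
    weekday and both days have a daily average PS; Fri-Mon changes are
    excluded.  ``consecutive_only=False`` relaxes the rule to the next
    *available* scored weekday instead of the next calendar day.
    """
    summaries = descriptives.daily_summaries(diary)
    avg_ps = {s.date: s.avg_ps for s in summaries if s.avg_ps is not None}
    weekdays = sorted(d for d in avg_ps if d.weekday() < 5)
    pairs: list[AdherencePair] = []
    for i, date in enumerate(weekdays):
        if consecutive_only:
            nxt = date + dt.timedelta(days=1)
            if nxt.weekday() >= 5 or nxt not in avg_ps:
                continue
        else:
            if i + 1 >= len(weekdays):
                continue
            nxt = weekdays[i + 1]
        jac = day_jaccard(diary, date, template, denominator=denominator)
        pairs.append(
            AdherencePair(diary.patient_id, date, jac, avg_ps[nxt] - avg_ps[date])
        )
    return pairs


@dataclass
class AncovaResult:
    """Within-subject ANCOVA of next-day PS change on adherence."""

    correlation: float  # partial correlation of JAC, controlling subject
    p: float
    beta_jac: float  # PS units per unit JAC
    subject_intercepts: dict[str, float]
    n_obs: int
    df_resid: int
    jac_zero: float  # JAC at which predicted PS change crosses zero


def within_subject_ancova(pairs: Sequence[AdherencePair]) -> AncovaResult:
    """OLS of delta PS on JAC with dummy-coded subject intercepts.

    The headline association is the partial correlation of JAC,
    ``sign(beta) * sqrt(t^2 / (t^2 + df))`` from the JAC coefficient's
    t-statistic, with its two-sided p.  ``jac_zero`` solves
    ``mean_intercept + beta * JAC = 0`` using the grand-mean subject
    intercept; with one subject the model reduces to simple linear
    regression.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("ANCOVA requires at least 3 adherence pairs")
    df = pd.DataFrame(
        {
            "subject": [p.patient_id for p in pairs],
            "jac": [p.jac for p in pairs],
            "delta_ps": [p.delta_ps for p in pairs],
        }
    )
    if np.ptp(df["jac"].to_numpy()) == 0:
        raise ValueError("JAC is constant across pairs; slope not identifiable")
    subjects = sorted(df["subject"].unique())
    X = pd.DataFrame({"jac": df["jac"]})
    # dummy-code subjects (first subject absorbed into the intercept)
    for s in subjects[1:]:
        X[f"subj_{s}"] = (df["subject"] == s).astype(float)
    X = sm.add_constant(X, prepend=True)
    fit = sm.OLS(df["delta_ps"], X).fit()

    beta = float(fit.params["jac"])
    t = float(fit.tvalues["jac"])
    dof = float(fit.df_resid)
    corr = float(np.sign(beta) * np.sqrt(t * t / (t * t + dof))) if dof > 0 else np.nan
    base = float(fit.params["const"])
    intercepts = {subjects[0]: base}
    for s in subjects[1:]:
        intercepts[s] = base + float(fit.params[f"subj_{s}"])
    mean_intercept = float(np.mean(list(intercepts.values())))
    jac_zero = -mean_intercept / beta if beta != 0 else float("nan")
    return AncovaResult(
        correlation=corr,
        p=float(fit.pvalues["jac"]),
        beta_jac=beta,
        subject_intercepts=intercepts,
        n_obs=int(fit.nobs),
        df_resid=int(dof),
        jac_zero=float(jac_zero),
    )


def per_subject_correlation(
    pairs: Sequence[AdherencePair], subject: str
) -> tuple[float, float]:
    """Pearson correlation of JAC with next-day PS change for one subject."""
    sel = [p for p in pairs if p.patient_id == subject]
    if len(sel) < 3:
        raise ValueError(f"subject {subject!r} has fewer than 3 pairs")
    jac = np.array([p.jac for p in sel])
    delta = np.array([p.delta_ps for p in sel])
    if np.ptp(jac) == 0:
        raise ValueError(f"subject {subject!r} has constant JAC")
    r, p = stats.pearsonr(jac, delta)
    return float(r), float(p)
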