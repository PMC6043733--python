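"""Synthetic diary-cohort generator with full planted ground truth.

Emulates the statistical structure the analyses assume, so every estimator
in the pipeline can be verified by parameter recovery without patient
data:

* per-patient diurnal templates drawn from slot-block priors (distinct
  weekend blocks, since weekends show different behavior);
* per-day adherence ``a_d ~ Beta``: each slot follows the template with
  probability ``a_d``, otherwise a uniformly random *other* category;
* slot-level missingness: each slot is dropped with probability
  ``1 - compliance`` (hourly compliance rate);
* entry pleasure = base + category effect + day effect + Gaussian noise,
  clipped to the rating scale.  The day effect of day ``d`` adds the
  lagged adherence term ``lag_gamma * (JAC_{d-1} - lag_zero)`` whenever
  ``d-1`` is the preceding calendar weekday, plus a concave social
  dose-response term ``curvature * (2 * peak * h - h^2)`` in the day's
  social hours ``h`` (true quadratic coefficient ``-curvature``, optimum
  at ``peak`` hours).

Pleasure values are continuous by default; integer rounding is available
for realism but off so recovery tests are not discretization-limited.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .diary import ActivityEntry, Diary, N_SLOTS
from .taxonomy import ActivityCategory, _DEFAULT_PHRASES

__all__ = ["CohortConfig", "CohortTruth", "generate_cohort", "recovery_report"]

_CATS = list(ActivityCategory)

# phrases to attach as raw_text, keyed by category (round-trips the lexicon)
_PHRASES: dict[ActivityCategory, list[str]] = {c: [] for c in _CATS}
for _phrase, _cat in _DEFAULT_PHRASES.items():
    _PHRASES[_cat].append(_phrase)

# slot-block priors: (first_slot, last_slot, {category: probability})
_WEEKDAY_BLOCKS: list[tuple[int, int, dict[ActivityCategory, float]]] = [
    (0, 1, {ActivityCategory.DailyLiving: 1.0}),
    (2, 8, {ActivityCategory.WorkEducation: 0.6, ActivityCategory.SpareTime: 0.2,
            ActivityCategory.Practical: 0.2}),
    (9, 10, {ActivityCategory.Practical: 0.5, ActivityCategory.Movement: 0.3,
             ActivityCategory.Other: 0.2}),
    (11, 13, {ActivityCategory.Social: 0.6, ActivityCategory.SpareTime: 0.3,
              ActivityCategory.Movement: 0.1}),
    (14, 15, {ActivityCategory.DailyLiving: 0.6, ActivityCategory.SpareTime: 0.4}),
]
_WEEKEND_BLOCKS: list[tuple[int, int, dict[ActivityCategory, float]]] = [
    (0, 2, {ActivityCategory.DailyLiving: 1.0}),
    (3, 10, {ActivityCategory.SpareTime: 0.35, ActivityCategory.Social: 0.35,
             ActivityCategory.Movement: 0.2, ActivityCategory.Practical: 0.1}),
    (11, 13, {ActivityCategory.Social: 0.7, ActivityCategory.SpareTime: 0.3}),
    (14, 15, {ActivityCategory.DailyLiving: 0.7, ActivityCategory.SpareTime: 0.3}),
]

#: Default per-category additive pleasure offsets (PS units): movement
#: clearly highest, social next, passive spare time lowest.
DEFAULT_CATEGORY_EFFECTS: dict[ActivityCategory, float] = {
    ActivityCategory.Movement: 1.5,
    ActivityCategory.WorkEducation: -0.3,
    ActivityCategory.SpareTime: -0.7,
    ActivityCategory.DailyLiving: 0.0,
    ActivityCategory.Practical: 0.2,
    ActivityCategory.Social: 0.8,
    ActivityCategory.Other: -0.4,
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic diary cohort.

    Defaults emulate the observed cohort scale: 7 patients, 4 calendar
    weeks (20 weekdays) each, ~90% hourly compliance, daily adherence
    averaging ~0.49 so the realized JAC averages ~0.44 (compliance x
    adherence), a lagged adherence effect on next-day pleasure crossing
    zero at JAC = 0.44, and a concave social dose-response peaking at 2
    hours/day.
    """

    n_patients: int = 7
    n_days: int = 28  # calendar days per patient (28 -> 20 weekdays)
    start_date: dt.date = dt.date(2017, 1, 2)  # a Monday
    pleasure_scale: tuple[float, float] = (1.0, 10.0)
    compliance: float | Sequence[float] = 0.9
    adherence_alpha: float = 4.9
    adherence_beta: float = 5.1
    adherence_fixed: float | None = None  # point-mass override of the Beta draw
    ps_base: float = 5.0
    category_effects: Mapping[ActivityCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_EFFECTS)
    )
    lag_gamma: float = 1.5  # PS change per unit JAC of the previous day
    lag_zero: float = 0.44  # JAC at which the planted next-day change is 0
    social_peak_hours: float = 2.0
    social_curvature: float = 0.15  # true beta2 = -curvature
    noise_sd: float = 1.0
    round_pleasure: bool = False
    score_fraction: float = 1.0  # fraction of patients reporting PS

    def per_patient_compliance(self) -> list[float]:
        if np.isscalar(self.compliance):
            return [float(self.compliance)] * self.n_patients
        comp = [float(c) for c in self.compliance]  # type: ignore[union-attr]
        if len(comp) != self.n_patients:
            raise ValueError("compliance list length must equal n_patients")
        return comp

    def validate(self) -> None:
        """Raise ValueError listing every violated field."""
        problems: list[str] = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if self.n_days < 1:
            problems.append("n_days must be >= 1")
        lo, hi = self.pleasure_scale
        if not hi > lo:
            problems.append("pleasure_scale max must exceed min")
        comps = (
            [float(self.compliance)]
            if np.isscalar(self.compliance)
            else [float(c) for c in self.compliance]  # type: ignore[union-attr]
        )
        if not np.isscalar(self.compliance) and len(comps) != self.n_patients:
            problems.append("compliance list length must equal n_patients")
        if any(not 0 <= c <= 1 for c in comps):
            problems.append("compliance probabilities must lie in [0, 1]")
        if self.adherence_alpha <= 0 or self.adherence_beta <= 0:
            problems.append("adherence Beta parameters must be positive")
        if self.adherence_fixed is not None and not 0 <= self.adherence_fixed <= 1:
            problems.append("adherence_fixed must lie in [0, 1]")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if not 0 <= self.social_peak_hours <= N_SLOTS:
            problems.append(f"social_peak_hours must lie in [0, {N_SLOTS}]")
        if not 0 <= self.score_fraction <= 1:
            problems.append("score_fraction must lie in [0, 1]")
        if set(self.category_effects) - set(_CATS):
            problems.append("category_effects has unknown categories")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "start_date" in raw:
            raw["start_date"] = dt.date.fromisoformat(str(raw["start_date"]))
        if "category_effects" in raw:
            raw["category_effects"] = {
                ActivityCategory.from_label(k): float(v)
                for k, v in raw["category_effects"].items()
            }
        if "pleasure_scale" in raw:
            raw["pleasure_scale"] = tuple(raw["pleasure_scale"])
        return cls(**raw)


@dataclass
class CohortTruth:
    """Planted parameters and realized per-day quantities of one cohort."""

    seed: int
    weekday_templates: dict[str, list[ActivityCategory]]
    weekend_templates: dict[str, list[ActivityCategory]]
    adherence: dict[str, dict[dt.date, float]]  # drawn a_d
    jac: dict[str, dict[dt.date, float]]  # realized weekday JAC vs true template
    category_effects: dict[ActivityCategory, float]
    lag_gamma: float
    lag_zero: float
    social_peak_hours: float
    social_curvature: float

    @property
    def true_beta2(self) -> float:
        return -self.social_curvature

    def true_value(self, param: str) -> float:
        table = {
            "lag_gamma": self.lag_gamma,
            "beta_jac": self.lag_gamma,
            "jac_zero": self.lag_zero,
            "lag_zero": self.lag_zero,
            "argmax_hours": self.social_peak_hours,
            "social_peak_hours": self.social_peak_hours,
            "beta2": self.true_beta2,
        }
        if param not in table:
            raise KeyError(f"no planted truth for parameter {param!r}")
        return table[param]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "weekday_templates": {
                pid: [c.name for c in tpl]
                for pid, tpl in self.weekday_templates.items()
            },
            "weekend_templates": {
                pid: [c.name for c in tpl]
                for pid, tpl in self.weekend_templates.items()
            },
            "adherence": {
                pid: {d.isoformat(): a for d, a in days.items()}
                for pid, days in self.adherence.items()
            },
            "jac": {
                pid: {d.isoformat(): j for d, j in days.items()}
                for pid, days in self.jac.items()
            },
            "category_effects": {
                c.name: v for c, v in self.category_effects.items()
            },
            "lag_gamma": self.lag_gamma,
            "lag_zero": self.lag_zero,
            "social_peak_hours": self.social_peak_hours,
            "social_curvature": self.social_curvature,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _draw_template(
    rng: np.random.Generator,
    blocks: list[tuple[int, int, dict[ActivityCategory, float]]],
) -> list[ActivityCategory]:
    template: list[ActivityCategory] = [ActivityCategory.Other] * N_SLOTS
    for first, last, prior in blocks:
        cats = list(prior)
        probs = np.array([prior[c] for c in cats], dtype=float)
        probs = probs / probs.sum()
        for slot in range(first, last + 1):
            template[slot] = cats[rng.choice(len(cats), p=probs)]
    return template


def generate_cohort(
    config: CohortConfig, seed: int = 0
) -> tuple[list[Diary], CohortTruth]:
    """Generate a diary cohort and its ground truth, deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    lo, hi = config.pleasure_scale
    effects = {c: float(config.category_effects.get(c, 0.0)) for c in _CATS}
    comps = config.per_patient_compliance()
    n_scored = int(round(config.score_fraction * config.n_patients))

    diaries: list[Diary] = []
    truth = CohortTruth(
        seed=seed,
        weekday_templates={},
        weekend_templates={},
        adherence={},
        jac={},
        category_effects=effects,
        lag_gamma=config.lag_gamma,
        lag_zero=config.lag_zero,
        social_peak_hours=config.social_peak_hours,
        social_curvature=config.social_curvature,
    )

    for p_idx in range(config.n_patients):
        pid = f"S{p_idx + 1}"
        scored = p_idx < n_scored
        wk_tpl = _draw_template(rng, _WEEKDAY_BLOCKS)
        we_tpl = _draw_template(rng, _WEEKEND_BLOCKS)
        truth.weekday_templates[pid] = wk_tpl
        truth.weekend_templates[pid] = we_tpl
        truth.adherence[pid] = {}
        truth.jac[pid] = {}

        entries: list[ActivityEntry] = []
        reporting_days: list[dt.date] = []
        prev_jac: float | None = None  # realized JAC of previous calendar day
        prev_was_weekday = False
        for d_idx in range(config.n_days):
            date = config.start_date + dt.timedelta(days=d_idx)
            reporting_days.append(date)
            is_weekday = date.weekday() < 5
            template = wk_tpl if is_weekday else we_tpl

            a_d = (
                float(config.adherence_fixed)
                if config.adherence_fixed is not None
                else float(rng.beta(config.adherence_alpha, config.adherence_beta))
            )
            truth.adherence[pid][date] = a_d
            adhere = rng.random(N_SLOTS) < a_d
            offsets = rng.integers(1, len(_CATS), size=N_SLOTS)
            cats = [
                template[s]
                if adhere[s]
                else _CATS[(template[s].ordinal + int(offsets[s])) % len(_CATS)]
                for s in range(N_SLOTS)
            ]
            kept = rng.random(N_SLOTS) < comps[p_idx]

            jac_d = (
                sum(
                    1
                    for s in range(N_SLOTS)
                    if kept[s] and cats[s] is template[s]
                )
                / N_SLOTS
            )
            if is_weekday:
                truth.jac[pid][date] = jac_d

            day_effect = 0.0
            if is_weekday and prev_was_weekday and prev_jac is not None:
                day_effect += config.lag_gamma * (prev_jac - config.lag_zero)
            h_social = sum(
                1
                for s in range(N_SLOTS)
                if kept[s] and cats[s] is ActivityCategory.Social
            )
            day_effect += config.social_curvature * (
                2 * config.social_peak_hours * h_social - h_social**2
            )

            noise = rng.normal(0.0, config.noise_sd, size=N_SLOTS)
            for s in range(N_SLOTS):
                if not kept[s]:
                    continue
                cat = cats[s]
                phrases = _PHRASES[cat]
                text = phrases[int(rng.integers(len(phrases)))]
                ps: float | None = None
                if scored:
                    ps = config.ps_base + effects[cat] + day_effect + noise[s]
                    ps = float(min(max(ps, lo), hi))
                    if config.round_pleasure:
                        ps = float(round(ps))
                entries.append(ActivityEntry(pid, date, s, text, cat, ps))

            prev_jac = jac_d
            prev_was_weekday = is_weekday

        diaries.append(
            Diary(
                patient_id=pid,
                entries=entries,
                pleasure_scale=config.pleasure_scale,
                reporting_days=reporting_days,
            )
        )
    return diaries, truth


def recovery_report(
    replicates: Sequence[tuple[CohortTruth, Mapping[str, float]]]
) -> "pd.DataFrame":
    """Bias, RMSE and sign accuracy of estimates against planted truth.

    ``replicates`` pairs each cohort's :class:`CohortTruth` with a mapping
    of parameter name -> estimate produced by the analysis modules on that
    cohort (e.g. ``{"beta_jac": ..., "jac_zero": ..., "argmax_hours": ...}``).
    An estimates mapping carrying a ``seed`` key must match its truth's
    seed (guards against pairing estimates with the wrong cohort).
    """
    import pandas as pd

    if not replicates:
        raise ValueError("recovery_report needs at least one replicate")
    errors: dict[str, list[tuple[float, float]]] = {}
    for truth, estimates in replicates:
        if "seed" in estimates and int(estimates["seed"]) != truth.seed:
            raise ValueError(
                f"estimate seed {estimates['seed']} does not match cohort "
                f"seed {truth.seed}"
            )
        for param, est in estimates.items():
            if param == "seed":
                continue
            errors.setdefault(param, []).append((truth.true_value(param), est))
    rows = []
    for param, pairs in errors.items():
        true = np.array([t for t, _ in pairs])
        est = np.array([e for _, e in pairs])
        rows.append(
            {
                "parameter": param,
                "n_replicates": len(pairs),
                "true_mean": float(true.mean()),
                "estimate_mean": float(est.mean()),
                "bias": float((est - true).mean()),
                "rmse": float(np.sqrt(((est - true) ** 2).mean())),
                "sign_accuracy": float(np.mean(np.sign(est) == np.sign(true))),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
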