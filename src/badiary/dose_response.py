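"""Activity dose-response: daily hours of a category vs daily average pleasure.

Cross-sectional model over all scored days pooled across patients:
``dPS = beta0 + beta1 * X + beta2 * X^2`` with ``X`` the day's hours of the
target category.  If the quadratic term is insignificant at ``alpha`` the
model is refit as linear (the quadratic coefficients are retained for
reporting).  A concave fit (beta2 < 0) has an interior optimum at
``-beta1 / (2 * beta2)`` hours.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import descriptives
from .diary import Diary, N_SLOTS
from .taxonomy import ActivityCategory

__all__ = [
    "DosePoint",
    "DoseResponseFit",
    "daily_dose_points",
    "fit_dose_response",
    "hour_bin_quantiles",
]


@dataclass(slots=True)
class DosePoint:
    """One scored day: hours of the target category and the day's avg PS."""

    patient_id: str
    date: dt.date
    hours: int
    avg_ps: float

    def __post_init__(self) -> None:
        if not 0 <= self.hours <= N_SLOTS:
            raise ValueError(f"hours {self.hours} outside 0..{N_SLOTS}")


def daily_dose_points(
    diaries: Iterable[Diary], category: ActivityCategory
) -> list[DosePoint]:
    """One point per scored day per patient; unscored days contribute none."""
    points: list[DosePoint] = []
    for diary in diaries:
        for s in descriptives.daily_summaries(diary):
            if s.avg_ps is None:
                continue
            points.append(
                DosePoint(
                    s.patient_id, s.date, s.category_hours.get(category, 0), s.avg_ps
                )
            )
    return points


@dataclass
class DoseResponseFit:
    """Quadratic (or fallback linear) least-squares dose-response fit.

    When the quadratic term is insignificant the reported model is the
    linear refit (``beta2 = None``) and the full quadratic coefficients
    stay available in ``quadratic_betas`` / ``quadratic_p2`` for reporting.
    ``argmax_hours`` is defined only for a concave selected quadratic.
    """

    model_order: str  # 'quadratic' | 'linear'
    beta0: float
    beta1: float
    beta2: float | None
    t_stats: dict[str, float]
    p_values: dict[str, float]
    df: int
    argmax_hours: float | None
    quadratic_betas: tuple[float, float, float]
    quadratic_t2: float
    quadratic_p2: float
    n_points: int


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, X).fit()


def fit_dose_response(
    points: Sequence[DosePoint], alpha: float = 0.05
) -> DoseResponseFit:
    """Fit dPS = beta0 + beta1 X + beta2 X^2, falling back to linear.

    The quadratic term is kept when its two-sided t-test has p < alpha;
    otherwise the model is refit as linear while the quadratic estimate is
    retained for reporting.

    Raises
    ------
    ValueError
        Fewer than 4 points or fewer than 3 distinct hour values (the
        quadratic design would be singular); all-equal hours.
    """
    points = list(points)
    x = np.array([p.hours for p in points], dtype=float)
    y = np.array([p.avg_ps for p in points], dtype=float)
    distinct = np.unique(x).size
    if distinct < 2:
        raise ValueError("degenerate design: all days have equal hours")
    if len(points) < 4 or distinct < 3:
        raise ValueError(
            "quadratic fit needs >= 4 points with >= 3 distinct hour values"
        )

    Xq = np.column_stack([np.ones_like(x), x, x * x])
    quad = _ols(y, Xq)
    qb = tuple(float(b) for b in quad.params)
    t2 = float(quad.tvalues[2])
    p2 = float(quad.pvalues[2])

    if p2 < alpha:
        argmax = float(-qb[1] / (2 * qb[2])) if qb[2] < 0 else None
        return DoseResponseFit(
            model_order="quadratic",
            beta0=qb[0],
            beta1=qb[1],
            beta2=qb[2],
            t_stats={"beta0": float(quad.tvalues[0]), "beta1": float(quad.tvalues[1]), "beta2": t2},
            p_values={"beta0": float(quad.pvalues[0]), "beta1": float(quad.pvalues[1]), "beta2": p2},
            df=int(quad.df_resid),
            argmax_hours=argmax,
            quadratic_betas=qb,
            quadratic_t2=t2,
            quadratic_p2=p2,
            n_points=len(points),
        )

    Xl = np.column_stack([np.ones_like(x), x])
    lin = _ols(y, Xl)
    return DoseResponseFit(
        model_order="linear",
        beta0=float(lin.params[0]),
        beta1=float(lin.params[1]),
        beta2=None,
        t_stats={"beta0": float(lin.tvalues[0]), "beta1": float(lin.tvalues[1])},
        p_values={"beta0": float(lin.pvalues[0]), "beta1": float(lin.pvalues[1])},
        df=int(lin.df_resid),
        argmax_hours=None,
        quadratic_betas=qb,
        quadratic_t2=t2,
        quadratic_p2=p2,
        n_points=len(points),
    )


def hour_bin_quantiles(
    points: Sequence[DosePoint], max_hours: int = 5
) -> pd.DataFrame:
    """Median and quartiles of daily avg PS per hour bin 0..max_hours.

    Quantiles use linear interpolation between order statistics.  Empty
    bins are flagged (``n = 0`` with NaN summaries).
    """
    rows = []
    values_by_hour: dict[int, list[float]] = {h: [] for h in range(max_hours + 1)}
    for p in points:
        if p.hours <= max_hours:
            values_by_hour[p.hours].append(p.avg_ps)
    for h in range(max_hours + 1):
        vals = np.asarray(values_by_hour[h], dtype=float)
        if vals.size == 0:
            rows.append(
                {"hours": h, "median": np.nan, "q25": np.nan, "q75": np.nan,
                 "n": 0, "empty": True}
            )
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75], method="linear")
        rows.append(
            {"hours": h, "median": float(med), "q25": float(q25),
             "q75": float(q75), "n": int(vals.size), "empty": False}
        )
    return pd.DataFrame(rows).set_index("hours")
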