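"""Minimal plotting helpers (optional; nothing in the pipeline needs them)."""

from __future__ import annotations

from typing import Sequence

from .descriptives import DaySummary
from .dose_response import DosePoint


def plot_daily_ps(summaries: Sequence[DaySummary], ax=None):
    """Daily average pleasure over time, with gaps on unscored days."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    dates = [s.date for s in summaries]
    values = [s.avg_ps if s.avg_ps is not None else float("nan") for s in summaries]
    ax.plot(dates, values, marker="o")
    ax.set_xlabel("date")
    ax.set_ylabel("daily average pleasure")
    return ax


def plot_dose_response(points: Sequence[DosePoint], fit=None, ax=None):
    """Scatter of daily hours vs daily average pleasure, optional fit curve."""
    import numpy as np
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    xs = [p.hours for p in points]
    ys = [p.avg_ps for p in points]
    ax.scatter(xs, ys, alpha=0.5)
    if fit is not None:
        grid = np.linspace(0, max(xs), 100)
        b0, b1, b2 = fit.quadratic_betas
        ax.plot(grid, b0 + b1 * grid + b2 * grid**2)
    ax.set_xlabel("daily hours of category")
    ax.set_ylabel("daily average pleasure")
    return ax
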