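"""Growth-curve fitting across imaging weeks and correlation-based model
selection, plus weekly cohort summaries.

Three least-squares models are fitted to (time, BTV) observations —
linear V = a + b t, logarithmic V = a + b ln t, quadratic
V = a + b t + c t^2 — and the best model is the one with the highest
Pearson correlation between fitted and observed values. Ties (e.g. data
exactly on a line, which the quadratic also fits perfectly) resolve
toward the model with fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "GrowthError",
    "fit_growth_models",
    "weekly_summary",
]

_RHO_TIE_TOL = 1e-9


class GrowthError(ValueError):
    """Invalid growth series or fitting input."""


@dataclass(frozen=True)
class GrowthSeries:
    """Longitudinal BTV observations of one subject."""

    subject: str
    times_weeks: tuple[float, ...]
    volumes_mm3: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_weeks, dtype=float)
        v = np.asarray(self.volumes_mm3, dtype=float)
        if t.size != v.size:
            raise GrowthError("times and volumes must be equal-length")
        if np.any(np.diff(t) <= 0):
            raise GrowthError("times must be strictly increasing")
        if np.any(v < 0):
            raise GrowthError("volumes must be >= 0")


@dataclass
class GrowthFit:
    """One fitted growth model."""

    kind: str  # linear | logarithmic | quadratic
    coefficients: tuple[float, ...]  # low-order first: (a, b) or (a, b, c)
    fitted: np.ndarray
    pearson_rho: float
    selected: bool = False


def _pearson(fitted: np.ndarray, observed: np.ndarray) -> float:
    if np.ptp(fitted) == 0 or np.ptp(observed) == 0:
        return 0.0
    return float(np.corrcoef(fitted, observed)[0, 1])


def fit_growth_models(
    times_weeks: Sequence[float], volumes_mm3: Sequence[float]
) -> list[GrowthFit]:
    """Fit the three growth models and mark the best one selected.

    Requires >= 3 observations (>= 4 for the quadratic to be attempted)
    and strictly positive times for the logarithmic model. Works on a
    single animal's series or on the pooled cohort alike.
    """
    t = np.asarray(times_weeks, dtype=float)
    v = np.asarray(volumes_mm3, dtype=float)
    if t.size != v.size or t.size < 3:
        raise GrowthError("need at least 3 (time, volume) observations")
    if np.any(t <= 0):
        raise GrowthError("times must be > 0 (required by the logarithmic model)")

    fits: list[GrowthFit] = []

    b, a = np.polyfit(t, v, 1)
    fitted = a + b * t
    fits.append(GrowthFit("linear", (float(a), float(b)), fitted, _pearson(fitted, v)))

    b, a = np.polyfit(np.log(t), v, 1)
    fitted = a + b * np.log(t)
    fits.append(GrowthFit("logarithmic", (float(a), float(b)), fitted, _pearson(fitted, v)))

    if t.size >= 4:
        c, b, a = np.polyfit(t, v, 2)
        fitted = a + b * t + c * t**2
        fits.append(GrowthFit("quadratic", (float(a), float(b), float(c)), fitted, _pearson(fitted, v)))

    # Highest rho wins; ties toward fewer parameters, then listed order.
    best = max(
        range(len(fits)),
        key=lambda i: (round(fits[i].pearson_rho / _RHO_TIE_TOL) * _RHO_TIE_TOL, -len(fits[i].coefficients), -i),
    )
    fits[best].selected = True
    return fits


def weekly_summary(
    table: pd.DataFrame, metric: str, week_column: str = "week"
) -> pd.DataFrame:
    """Per-week mean, SD, min and max of a metric column.

    SD is the sample standard deviation (ddof = 1); a single animal in a
    week reports SD = 0 by convention. The summary is invariant to the
    row order of the input table.
    """
    if metric not in table.columns:
        raise GrowthError(f"unknown metric column {metric!r}")
    if week_column not in table.columns:
        raise GrowthError(f"unknown week column {week_column!r}")
    if len(table) == 0:
        raise GrowthError("empty table")
    grouped = table.groupby(week_column)[metric]
    out = grouped.agg(n="count", mean="mean", sd="std", min="min", max="max").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
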