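"""Theil-Sen trend characterisation with bootstrap uncertainty.

The Theil-Sen slope is the median of pairwise slopes (y_j - y_i)/(x_j - x_i)
over all pairs with distinct abscissae -- a robust, non-parametric trend
estimate with a 29% breakdown point. The intercept is median(y - slope*x).
Uncertainty comes from case resampling: replicate slopes over bootstrap
resamples give a percentile confidence interval and a two-sided sign-based
p-value. For plots and reports the trend is conventionally computed on
monthly means (months below a 75% capture threshold are dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrendEstimate:
    """Trend slope (units of y per year) with optional bootstrap interval."""

    slope: float
    intercept: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    n_points: int = 0


def theil_sen(x, y):
    """Theil-Sen point estimate (median pairwise slope, joint intercept)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three (x, y) points")
    if np.unique(x).size < 2:
        raise ValueError("slope undefined: all x values are equal")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return TrendEstimate(slope=float(slope), intercept=float(intercept),
                         n_points=int(x.size))


def bootstrap_trend(x, y, B=1000, seed=0, max_redraws=100):
    """Theil-Sen estimate with case-resampled bootstrap CI and p-value.

    ``B`` replicates are drawn with replacement; a resample with fewer than
    two distinct x values is discarded and redrawn (up to ``max_redraws``
    consecutive times). The 95% interval is the 2.5/97.5 percentile of the
    replicate slopes; the two-sided p-value for zero slope is
    2 * min(frac <= 0, frac >= 0), capped at 1.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    point = theil_sen(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    slopes = np.empty(B)
    for b in range(B):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            if np.unique(x[idx]).size >= 2:
                break
        else:
            raise RuntimeError("could not draw a resample with two distinct "
                               f"x values in {max_redraws} attempts")
        slope_b, _, _, _ = stats.theilslopes(y[idx], x[idx], method="joint")
        slopes[b] = slope_b
    ci_low, ci_high = np.percentile(slopes, [2.5, 97.5])
    p = 2.0 * min(np.mean(slopes <= 0.0), np.mean(slopes >= 0.0))
    return TrendEstimate(slope=point.slope, intercept=point.intercept,
                         ci_low=float(ci_low), ci_high=float(ci_high),
                         p_value=float(min(p, 1.0)), n_points=n)


def _fractional_year(timestamps):
    ts = pd.DatetimeIndex(timestamps)
    year_start = pd.to_datetime(ts.year.astype(str) + "-01-01")
    next_start = pd.to_datetime((ts.year + 1).astype(str) + "-01-01")
    frac = (ts - year_start) / (next_start - year_start)
    return ts.year.to_numpy() + frac.to_numpy()


def monthly_aggregate(series, min_capture=0.75):
    """Calendar-month means of a daily or hourly series.

    Returns ``(x, y)`` with x the month midpoints in fractional years and y
    the monthly means; months with less than ``min_capture`` of their
    expected records are dropped (reported via a warning).
    """
    s = pd.Series(series).dropna()
    if s.empty:
        warnings.warn("empty series: no monthly means")
        return np.array([]), np.array([])
    step = pd.Series(s.index).diff().median()
    per_day = 24 if step is not pd.NaT and step <= pd.Timedelta(hours=1) else 1

    grouped = s.groupby([s.index.year, s.index.month])
    xs, ys, dropped = [], [], []
    for (year, month), grp in grouped:
        expected = pd.Timestamp(year=year, month=month, day=1).days_in_month * per_day
        if len(grp) < min_capture * expected:
            dropped.append(f"{year}-{month:02d}")
            continue
        mid = (pd.Timestamp(year=year, month=month, day=1)
               + pd.Timedelta(days=(expected / per_day) / 2.0))
        xs.append(_fractional_year([mid])[0])
        ys.append(grp.mean())
    if dropped:
        warnings.warn(f"months below {min_capture:.0%} capture dropped: {dropped}")
    return np.asarray(xs), np.asarray(ys)


def trend_report(series, B=1000, seed=0):
    """Monthly-aggregated bootstrap Theil-Sen trend of a series."""
    x, y = monthly_aggregate(series)
    return bootstrap_trend(x, y, B=B, seed=seed)


def plot_trend(series, estimate=None, ax=None, B=500, seed=0):
    """Monthly means with the fitted Theil-Sen line and 95% slope band."""
    import matplotlib.pyplot as plt

    x, y = monthly_aggregate(series)
    if estimate is None:
        estimate = bootstrap_trend(x, y, B=B, seed=seed)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.plot(x, y, "o-", color="tab:red", ms=3, lw=0.8)
    xe = np.array([x.min(), x.max()])
    ax.plot(xe, estimate.intercept + estimate.slope * xe, color="tab:blue")
    if np.isfinite(estimate.ci_low):
        x0 = np.median(x)
        y0 = estimate.intercept + estimate.slope * x0
        for s in (estimate.ci_low, estimate.ci_high):
            ax.plot(xe, y0 + s * (xe - x0), color="tab:blue", ls="--", lw=0.8)
    label = (f"slope {estimate.slope:+.2f} "
             f"[{estimate.ci_low:+.2f}, {estimate.ci_high:+.2f}] per year")
    if np.isfinite(estimate.p_value):
        label += f" (p = {max(estimate.p_value, 0.001):.3g})"
    ax.set_title(label)
    ax.set_xlabel("year")
    return ax
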