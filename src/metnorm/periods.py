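"""Restriction-period calendar and period-wise change quantification.

The 2020 calendar partitions the intervention year into eight contiguous
phases that track the intensity of the COVID-19 restrictions in Spain, from
pre-lockdown (1 Jan - 13 Mar) through the strict lockdown (14 Mar - 30 Apr),
the de-escalation phases 0-3, the "new normality", and the second state of
alarm (25 Oct - 31 Dec).

Changes are quantified per period against a day-matched multi-year
reference: each calendar day of the intervention year is paired with the
mean of the same (month, day) across the reference years, then period means
are compared as a percentage. As printed, the percentage uses the
intervention-year mean as the denominator,

    P_i = 100 * (Cbar_2020,i - Cbar_ref,i) / Cbar_2020,i,

under which a halving of concentrations reads as -100% (not -50%). The
conventional reference-mean denominator is available through
``denominator="reference"``; see the methods note for the trade-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

DEFAULT_PERIODS_2020 = (
    ("pre-lockdown", date(2020, 1, 1), date(2020, 3, 13)),
    ("lockdown", date(2020, 3, 14), date(2020, 4, 30)),
    ("phase0", date(2020, 5, 1), date(2020, 5, 10)),
    ("phase1", date(2020, 5, 11), date(2020, 5, 24)),
    ("phase2", date(2020, 5, 25), date(2020, 6, 7)),
    ("phase3", date(2020, 6, 8), date(2020, 6, 20)),
    ("new-normality", date(2020, 6, 21), date(2020, 10, 24)),
    ("second-state-of-alarm", date(2020, 10, 25), date(2020, 12, 31)),
)


@dataclass(frozen=True)
class PeriodCalendar:
    """Ordered, non-overlapping list of (label, start, end), inclusive bounds."""

    periods: tuple

    def __post_init__(self):
        labels = [p[0] for p in self.periods]
        if len(set(labels)) != len(labels):
            raise ValueError("period labels must be unique")
        prev_end = None
        for label, start, end in self.periods:
            if start > end:
                raise ValueError(f"period {label!r} has start after end")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"period {label!r} overlaps its predecessor")
            prev_end = end

    @classmethod
    def default_2020(cls):
        return cls(DEFAULT_PERIODS_2020)

    @property
    def labels(self):
        return [p[0] for p in self.periods]

    @property
    def start(self):
        return self.periods[0][1]

    @property
    def end(self):
        return self.periods[-1][2]

    def assign_period(self, day):
        """Label of the unique period whose [start, end] contains ``day``."""
        if isinstance(day, pd.Timestamp):
            day = day.date()
        if day < self.start or day > self.end:
            raise ValueError(f"date {day} outside calendar span "
                             f"[{self.start}, {self.end}]")
        for label, start, end in self.periods:
            if start <= day <= end:
                return label
        raise ValueError(f"date {day} falls in a gap of the period calendar")

    def is_contiguous(self):
        for (_, _, end_a), (_, start_b, _) in zip(self.periods, self.periods[1:]):
            if start_b != end_a + timedelta(days=1):
                return False
        return True


def assign_period(day, calendar):
    return calendar.assign_period(day)


def day_matched_reference(reference_daily):
    """(month, day)-indexed climatology of a multi-year daily series.

    Averages each calendar day over the years in which it is present, so
    29 February is averaged over leap years only. Returns a DataFrame with
    columns ``mean`` and ``n_years``.
    """
    s = reference_daily.dropna()
    if s.empty:
        raise ValueError("reference series is empty")
    span_days = (s.index.max() - s.index.min()).days
    if span_days < 364:
        raise ValueError("reference must span at least one full year")
    frame = pd.DataFrame({"value": s.to_numpy()},
                         index=pd.MultiIndex.from_arrays(
                             [s.index.month, s.index.day],
                             names=["month", "day"]))
    grouped = frame.groupby(level=["month", "day"])["value"]
    return pd.DataFrame({"mean": grouped.mean(), "n_years": grouped.count()})


def percent_change(mean_intervention, mean_reference, denominator="intervention"):
    """Period percentage change between intervention and reference means.

    ``denominator="intervention"`` reproduces the printed formula
    100*(C_int - C_ref)/C_int; ``"reference"`` uses the conventional
    100*(C_int - C_ref)/C_ref.
    """
    if denominator == "intervention":
        denom = mean_intervention
    elif denominator == "reference":
        denom = mean_reference
    else:
        raise ValueError("denominator must be 'intervention' or 'reference'")
    if not denom > 0:
        raise ValueError("percentage change undefined for non-positive "
                         f"{denominator} mean ({denom})")
    return 100.0 * (mean_intervention - mean_reference) / denom


def period_change_table(series_2020, reference_daily, calendar=None,
                        mode="raw", denominator="intervention",
                        min_coverage=0.75, site=None, pollutant=None):
    """Per-period day-matched change records between the intervention year
    and the multi-year reference.

    ``series_2020`` is a daily series covering (part of) the calendar span;
    ``reference_daily`` a multi-year daily series from which the day-matched
    climatology is built. Days present in both are compared; a period needs
    ``min_coverage`` of its days to yield a mean, otherwise its record is
    flagged and the change left undefined (NaN).
    """
    calendar = calendar or PeriodCalendar.default_2020()
    clim = day_matched_reference(reference_daily)["mean"]
    s = series_2020.dropna()

    keys = list(zip(s.index.month, s.index.day))
    ref_vals = np.array([clim.get(k, np.nan) for k in keys])
    valid = ~np.isnan(ref_vals)

    records = []
    for label, start, end in calendar.periods:
        n_period_days = (end - start).days + 1
        in_period = np.array([(start <= d.date() <= end) for d in s.index])
        use = in_period & valid
        n_days = int(use.sum())
        mean_2020 = float(s.to_numpy()[use].mean()) if n_days else np.nan
        mean_ref = float(ref_vals[use].mean()) if n_days else np.nan
        flagged = n_days < min_coverage * n_period_days
        if n_days == 0:
            warnings.warn(f"period {label!r}: no overlapping days; "
                          "change undefined")
        pc = np.nan
        if not flagged and n_days > 0:
            try:
                pc = percent_change(mean_2020, mean_ref, denominator)
            except ValueError:
                warnings.warn(f"period {label!r}: undefined change "
                              "(non-positive denominator mean)")
        records.append({"site": site, "pollutant": pollutant, "period": label,
                        "mean_2020": mean_2020, "mean_ref": mean_ref,
                        "percent_change": pc, "mode": mode,
                        "n_days": n_days, "flagged": flagged})
    return pd.DataFrame.from_records(records)


def summarise_sites(records, group_by=("pollutant", "period", "mode")):
    """Box-plot style distribution summary of change records per group.

    Returns median, quartiles, mean, and min/max non-outlier whiskers
    (1.5 x IQR rule) of ``percent_change`` per group; empty groups are
    omitted with a warning.
    """
    records = records.dropna(subset=["percent_change"])
    group_by = [g for g in group_by if g in records.columns]
    rows = []
    for key, grp in records.groupby(group_by, dropna=False, sort=True):
        vals = grp["percent_change"].to_numpy()
        if vals.size == 0:
            warnings.warn(f"group {key}: empty, omitted")
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        inlier = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        row = dict(zip(group_by, key if isinstance(key, tuple) else (key,)))
        row.update({"median": med, "q1": q1, "q3": q3,
                    "mean": float(vals.mean()),
                    "whisker_low": float(inlier.min()),
                    "whisker_high": float(inlier.max()),
                    "n": int(vals.size)})
        rows.append(row)
    return pd.DataFrame.from_records(rows)
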