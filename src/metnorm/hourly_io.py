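"""Reading, writing and quality screening of hourly tabular data.

Canonical on-disk format: comma-separated UTF-8 with an ISO-8601
``timestamp`` column, met columns (ws [m/s], wd [deg], air_temp [C],
rh [%], sr [W/m2], cl [oktas], ll [L/m2]) and pollutant columns
(no, no2, pm10, o3 in ug/m3); missing values are empty fields. Timestamps
are treated as a single (standard, DST-free) time zone. After reading, the
table is gap-padded to a strictly increasing hourly-regular index;
duplicated timestamps keep the first occurrence (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("metnorm")

MET_COLUMNS = ("ws", "wd", "air_temp", "rh", "sr", "cl", "ll")
POLLUTANT_COLUMNS = ("no", "no2", "pm10", "o3")
SITE_TYPES = ("traffic", "urban background", "industrial", "rural")


def read_hourly(path, schema=None):
    """Read an hourly CSV into a gap-padded, hourly-regular DataFrame.

    ``schema`` optionally maps file column names onto the canonical ones
    (e.g. ``{"temp": "air_temp"}``). Unknown columns are dropped with a
    warning; unparseable timestamps raise with the offending row number.
    """
    raw = pd.read_csv(path)
    if schema:
        raw = raw.rename(columns=schema)
    if "timestamp" not in raw.columns:
        raise ValueError("file must have a 'timestamp' column")
    ts = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce")
    bad = np.nonzero(ts.isna().to_numpy() & raw["timestamp"].notna().to_numpy())[0]
    if bad.size:
        raise ValueError(f"unparseable timestamp at data row {bad[0] + 1}: "
                         f"{raw['timestamp'].iloc[bad[0]]!r}")

    known = [c for c in raw.columns
             if c in MET_COLUMNS or c in POLLUTANT_COLUMNS]
    unknown = [c for c in raw.columns if c not in known and c != "timestamp"]
    if unknown:
        log.warning("ignoring unknown column(s): %s", unknown)

    table = raw[known].copy()
    table.index = pd.DatetimeIndex(ts)
    table = table.sort_index(kind="stable")
    dup = table.index.duplicated(keep="first")
    if dup.any():
        log.warning("dropping %d duplicated timestamp(s), keeping first "
                    "occurrence", int(dup.sum()))
        table = table[~dup]
    full = pd.date_range(table.index.min(), table.index.max(), freq="h")
    table = table.reindex(full)
    table.index.name = "timestamp"
    return table.astype(float)


def write_hourly(table, path):
    """Write an hourly table in the canonical CSV layout (ISO timestamps)."""
    out = table.copy()
    out.index = out.index.strftime("%Y-%m-%dT%H:%M:%S")
    out.index.name = "timestamp"
    out.to_csv(path, na_rep="")


@dataclass
class QualityReport:
    """Per-column data-capture fractions with pass/fail screening flags.

    The screening mirrors routine monitoring-network practice: met columns
    need >= 90% data capture (inclusive bound) and pollutants at most 5%
    missing data. The report is advisory: downstream steps proceed with a
    warning rather than aborting.
    """

    capture: dict
    missing: dict
    passed: dict

    @property
    def all_passed(self):
        return all(self.passed.values())


def quality_check(table, met_min_capture=0.90, pollutant_max_missing=0.05):
    if len(table) == 0:
        raise ValueError("empty table")
    capture, missing, passed = {}, {}, {}
    for col in table.columns:
        frac = float(table[col].notna().mean())
        capture[col] = frac
        missing[col] = 1.0 - frac
        if col in MET_COLUMNS:
            passed[col] = frac >= met_min_capture
        elif col in POLLUTANT_COLUMNS:
            passed[col] = (1.0 - frac) <= pollutant_max_missing
        else:
            passed[col] = True
        if not passed[col]:
            log.warning("column %r failed quality screening "
                        "(capture %.1f%%)", col, 100 * frac)
    return QualityReport(capture=capture, missing=missing, passed=passed)
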