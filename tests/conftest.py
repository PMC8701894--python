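import numpy as np
import pandas as pd
import pytest

import metnorm as mn
from metnorm.pipeline import build_training_frame


@pytest.fixture(scope="session")
def year_dataset():
    """One simulated year (2020) with a 0.5 lockdown multiplier."""
    calendar = mn.PeriodCalendar.default_2020()
    scenario = mn.EmissionScenario(period_multipliers={"lockdown": 0.5})
    return mn.simulate_dataset("2020-01-01", "2020-12-31",
                               scenario=scenario, calendar=calendar, seed=42)


@pytest.fixture(scope="session")
def year_frame(year_dataset):
    return build_training_frame(year_dataset.to_hourly_table(), "no2")


@pytest.fixture(scope="session")
def small_model(year_frame):
    """A modest ensemble on the one-year frame, shared across tests."""
    predictors = [c for c in year_frame.columns if c != "no2"]
    model = mn.BoostedTreeRegressor(n_estimators=60, learning_rate=0.1,
                                    interaction_depth=6)
    model.fit(year_frame[predictors], year_frame["no2"])
    return model


def exhaustive_best_split(x, r):
    """Independent O(n^2) oracle: scan every midpoint cutpoint directly."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    xs = np.unique(x)
    best = None
    for s in (xs[:-1] + xs[1:]) / 2.0:
        mask = x < s
        rl, rr = r[mask], r[~mask]
        lm, rm = rl.mean(), rr.mean()
        rss = float(np.sum((rl - lm) ** 2) + np.sum((rr - rm) ** 2))
        if best is None or rss < best[1]:
            best = (float(s), rss, float(lm), float(rm))
    return best
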