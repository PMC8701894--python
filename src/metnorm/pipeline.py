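"""End-to-end analysis pipeline: training frames, model fits, normalised
series and period-change tables.

The canonical workflow, per pollutant and site:

1. build hourly training frames for the intervention year and the
   multi-year reference (met predictors + hour, weekday, week, trend);
2. fit a boosted-tree model to each frame (80/20 random split, hold-out
   r/RMSE/MB logged);
3. weather-normalise the intervention year (trend held) and
   weather+trend-normalise the reference (trend resampled);
4. compare the two daily series period-by-period against the day-matched
   reference climatology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boosting import BoostedTreeRegressor, split_train_test, evaluate
from .normalise import met_sim, detrend, for_model
from .periods import PeriodCalendar, period_change_table

log = logging.getLogger("metnorm")

TEMPORAL_PREDICTORS = ("hour", "weekday", "week", "trend")


def build_training_frame(table, response, trend_origin=None, dropna=True):
    """Predictor/response frame from an hourly table.

    Adds the temporal predictors: hour (0-23), weekday (1=Monday..7),
    week-of-year (1..53, seven-day blocks from 1 January so that week
    boundaries align across years), and trend (fractional years since
    ``trend_origin``, default the first timestamp). Rows with any missing
    predictor or response are dropped (the quality screen guarantees they
    are few).
    """
    if response not in table.columns:
        raise KeyError(f"response column {response!r} not in table")
    met_cols = [c for c in table.columns
                if c not in (response,) and table[c].dtype.kind in "fi"
                and c not in TEMPORAL_PREDICTORS]
    frame = table[met_cols].copy()
    idx = table.index
    frame["hour"] = idx.hour
    frame["weekday"] = idx.dayofweek + 1
    frame["week"] = (idx.dayofyear - 1) // 7 + 1
    origin = pd.Timestamp(trend_origin) if trend_origin is not None else idx[0]
    frame["trend"] = (idx - origin).total_seconds() / (365.25 * 86400.0)
    frame[response] = table[response]
    if dropna:
        frame = frame.dropna()
    if (frame[response] < 0).any():
        raise ValueError("negative response values in training frame")
    return frame


def fit_pollutant_model(frame, response, n_trees=1000, learning_rate=0.1,
                        interaction_depth=6, train_fraction=0.8, seed=0):
    """Fit a boosted-tree concentration model with the 80/20 protocol.

    Returns ``(model, metrics)``; the model is fitted on the random training
    fraction and scored (Pearson r, RMSE, mean bias) on the held-out rows.
    """
    train, test = split_train_test(frame, train_fraction, seed=seed)
    predictors = [c for c in frame.columns if c != response]
    model = BoostedTreeRegressor(n_estimators=n_trees,
                                 learning_rate=learning_rate,
                                 interaction_depth=interaction_depth,
                                 random_state=seed)
    model.fit(train[predictors], train[response])
    metrics = evaluate(model, test[predictors], test[response])
    log.info("model fit (%s): r=%.3f RMSE=%.2f MB=%+.2f on %d test rows",
             response, metrics.pearson_r, metrics.rmse, metrics.mean_bias,
             metrics.n_test)
    return model, metrics


@dataclass
class ReportResult:
    """Artifacts of a full normalisation-and-change run for one pollutant."""

    changes: pd.DataFrame              # raw + dwdt period records
    metrics_2020: object
    metrics_ref: object
    dw_2020: object                    # NormalisedSeries
    dwdt_ref: object                   # NormalisedSeries
    model_2020: BoostedTreeRegressor = None
    model_ref: BoostedTreeRegressor = None


def run_report(table, response, calendar=None, intervention_year=2020,
               n_trees=1000, learning_rate=0.1, interaction_depth=6,
               n_samples=200, seed=0, denominator="intervention",
               site=None, keep_models=False):
    """Full pipeline on one hourly table containing reference years plus the
    intervention year.

    Fits separate models for the intervention year and the reference span,
    produces the deweathered intervention series and the deweathered +
    detrended reference series, and returns raw and normalised (dwdt)
    period-change tables.
    """
    calendar = calendar or PeriodCalendar.default_2020()
    is_2020 = table.index.year == intervention_year
    if not is_2020.any() or is_2020.all():
        raise ValueError("table must contain the intervention year and at "
                         "least one reference year")
    table_2020 = table[is_2020]
    table_ref = table[table.index.year < intervention_year]

    frame_2020 = build_training_frame(table_2020, response)
    frame_ref = build_training_frame(table_ref, response)
    predictors = [c for c in frame_2020.columns if c != response]

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    model_2020, metrics_2020 = fit_pollutant_model(
        frame_2020, response, n_trees, learning_rate, interaction_depth,
        seed=int(seeds[0]))
    model_ref, metrics_ref = fit_pollutant_model(
        frame_ref, response, n_trees, learning_rate, interaction_depth,
        seed=int(seeds[1]))

    dw_2020 = met_sim(model_2020, frame_2020[predictors],
                      for_model(model_2020, n_samples=n_samples,
                                seed=int(seeds[2])))
    dwdt_ref = detrend(model_ref, frame_ref[predictors],
                       for_model(model_ref, detrend=True, n_samples=n_samples,
                                 seed=int(seeds[3])))

    obs_2020_daily = table_2020[response].resample("D").mean()
    obs_ref_daily = table_ref[response].resample("D").mean()

    raw = period_change_table(obs_2020_daily, obs_ref_daily, calendar,
                              mode="raw", denominator=denominator,
                              site=site, pollutant=response)
    dwdt = period_change_table(dw_2020.values, dwdt_ref.values, calendar,
                               mode="dwdt", denominator=denominator,
                               site=site, pollutant=response)
    changes = pd.concat([raw, dwdt], ignore_index=True)
    return ReportResult(changes=changes, metrics_2020=metrics_2020,
                        metrics_ref=metrics_ref, dw_2020=dw_2020,
                        dwdt_ref=dwdt_ref,
                        model_2020=model_2020 if keep_models else None,
                        model_ref=model_ref if keep_models else None)
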