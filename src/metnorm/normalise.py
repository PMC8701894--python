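"""Weather (and trend) normalisation by resampled prediction.

A fitted concentration model is predicted many times, each time replacing
the "nuisance" predictors of every row with those of a row drawn uniformly
at random (with replacement) from the whole frame. Averaging the
predictions over repetitions yields a daily series representing average
meteorology: the weather-driven variability is integrated out while
predictors that are held (notably "week", which carries the seasonal cycle,
and "trend" for intervention-year runs) keep their original values, so the
emission signal of interest survives.

Resampling draws whole rows as a joint block so cross-variable coherence is
preserved (e.g. solar radiation stays consistent with hour of day, which is
resampled together with the met block). The day-of-week predictor is
instead resampled independently and uniformly over 1-7, averaging out the
working-day/weekend emission pattern. Including "trend" among the resampled
variables converts a multi-year reference series into a fixed-emissions
scenario (detrending).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default joint-resample block: surface met + hour of day
DEFAULT_RESAMPLE = ("ws", "wd", "air_temp", "rh", "sr", "cl", "ll",
                    "hour", "weekday")
DEFAULT_HOLD = ("week", "trend")


@dataclass
class NormalisationConfig:
    """Configuration of the resampled-prediction normalisation.

    ``resample`` and ``hold`` must partition the model's predictors.
    ``weekday_uniform`` draws the day-of-week independently and uniformly
    over 1-7 instead of from the donor row. ``n_samples`` is the number of
    Monte-Carlo repetitions ("hundreds of times"); the per-day standard
    error across repetitions is reported so adequacy can be judged.
    """

    resample: tuple = DEFAULT_RESAMPLE
    hold: tuple = DEFAULT_HOLD
    n_samples: int = 200
    seed: int = 0
    weekday_uniform: bool = True
    clip_zero: bool = False

    def validate(self, feature_names):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        resample, hold = set(self.resample), set(self.hold)
        overlap = resample & hold
        if overlap:
            raise ValueError(f"variables both resampled and held: {sorted(overlap)}")
        features = set(feature_names)
        unknown = (resample | hold) - features
        if unknown:
            raise ValueError(f"variables absent from model schema: {sorted(unknown)}")
        uncovered = features - (resample | hold)
        if uncovered:
            raise ValueError(f"predictors neither resampled nor held: {sorted(uncovered)}")


def for_model(model, detrend=False, **kwargs):
    """Build a NormalisationConfig matching a fitted model's schema.

    Holds "week" always and "trend" unless ``detrend``; everything else is
    resampled.
    """
    features = list(model.feature_names_in_)
    hold = {"week"} if detrend else {"week", "trend"}
    hold &= set(features)
    resample = tuple(f for f in features if f not in hold)
    return NormalisationConfig(resample=resample, hold=tuple(sorted(hold)),
                               **kwargs)


@dataclass
class NormalisedSeries:
    """Daily normalised concentrations with Monte-Carlo standard errors."""

    daily: pd.DataFrame        # index: date; columns: value, se
    n_samples: int
    config: NormalisationConfig = None

    @property
    def values(self):
        return self.daily["value"]

    def to_csv(self, path):
        out = self.daily.copy()
        out["n_samples"] = self.n_samples
        out.to_csv(path, index_label="date", float_format="%.6f")


def met_sim(model, frame, config=None):
    """Weather-normalised daily series by resampled prediction.

    ``frame`` must contain the model's predictor columns on an hourly
    DatetimeIndex. For each repetition the resampled block of every row is
    replaced by that of a uniformly drawn donor row; predictions are
    averaged over repetitions and aggregated to daily means.
    """
    config = config or for_model(model)
    features = list(model.feature_names_in_)
    config.validate(features)
    X0 = np.ascontiguousarray(frame[features].to_numpy(dtype=np.float64))
    if not np.isfinite(X0).all():
        raise ValueError("frame contains missing predictor values; drop them "
                         "before normalising")
    n = X0.shape[0]
    col_index = {name: k for k, name in enumerate(features)}
    joint_cols = [col_index[v] for v in config.resample
                  if not (config.weekday_uniform and v == "weekday")]
    weekday_col = (col_index["weekday"]
                   if config.weekday_uniform and "weekday" in config.resample
                   else None)

    dates = frame.index.normalize()
    day_codes, day_index = pd.factorize(dates, sort=True)
    n_days = len(day_index)
    counts = np.bincount(day_codes, minlength=n_days)

    rng = np.random.default_rng(config.seed)
    daily = np.empty((config.n_samples, n_days))
    X = X0.copy()
    for k in range(config.n_samples):
        donors = rng.integers(0, n, size=n)
        X[:, :] = X0
        if joint_cols:
            X[:, joint_cols] = X0[donors][:, joint_cols]
        if weekday_col is not None:
            X[:, weekday_col] = rng.integers(1, 8, size=n)
        pred = model.predict(X)
        daily[k] = np.bincount(day_codes, weights=pred, minlength=n_days) / counts

    value = daily.mean(axis=0)
    se = daily.std(axis=0, ddof=1) / np.sqrt(config.n_samples)
    if config.clip_zero:
        value = np.clip(value, 0.0, None)
    out = pd.DataFrame({"value": value, "se": se}, index=day_index)
    return NormalisedSeries(daily=out, n_samples=config.n_samples, config=config)


def detrend(model, frame, config=None, **kwargs):
    """Weather- and trend-normalised series (fixed-emissions scenario).

    Identical mechanics to :func:`met_sim`, but the long-term "trend"
    predictor is resampled with the met block, averaging the emission trend
    out of a multi-year reference series.
    """
    config = config or for_model(model, detrend=True, **kwargs)
    if "trend" in config.hold:
        raise ValueError("detrending requires 'trend' among the resampled "
                         "variables, not held")
    if "trend" not in config.resample:
        raise ValueError("detrending requires a 'trend' predictor")
    return met_sim(model, frame, config)
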