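"""Synthetic hourly meteorology and pollutant series with known structure.

The generator provides ground truth for every downstream stage: it emits a
co-located hourly meteorological series (wind speed/direction, temperature,
relative humidity, solar radiation, cloud cover, precipitation) and a
pollutant concentration series built multiplicatively from

    c_t = base * diurnal[hour] * weekday[dow] * (1 + trend_slope * years)
               * period_multiplier(t) * g(met_t) + noise,  truncated at 0,

where ``g`` is a documented meteorological response (monotone decreasing in
wind speed, exponential in temperature/solar radiation/precipitation, and a
smooth bimodal function of wind direction so that the circular variable
carries signal). Period multipliers are step changes over a configurable
restriction calendar; they are the injected "intervention" whose recovery
the analysis pipeline is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .periods import PeriodCalendar

MET_COLUMNS = ("ws", "wd", "air_temp", "rh", "sr", "cl", "ll")


@dataclass
class MetParams:
    """Parameters of the hourly meteorology generator.

    Defaults emulate a mid-latitude oceanic coastal climate (mild, humid,
    frequently overcast): mean temperature 14 C with 4 C diurnal and 6 C
    seasonal amplitude and AR(1) hourly noise; log-normal wind speed with
    median ~2 m/s; von-Mises wind direction around a prevailing 225 deg
    (south-west); solar radiation from a clear-sky solar-elevation proxy at
    43.4 N attenuated by sampled cloud cover (oktas); exponential wet-hour
    precipitation.
    """

    temp_mean: float = 14.0          # deg C
    temp_diurnal_amp: float = 4.0    # deg C
    temp_seasonal_amp: float = 6.0   # deg C
    temp_ar1: float = 0.9            # hourly AR(1) coefficient, in [0, 1)
    temp_noise_sd: float = 1.0       # deg C innovation s.d.
    ws_logmean: float = 0.7          # log(m/s)
    ws_logsd: float = 0.6
    wd_prevailing: float = 225.0     # deg
    wd_concentration: float = 2.0    # von Mises kappa, >= 0
    rh_mean: float = 75.0            # %
    rh_sd: float = 12.0              # %
    sr_peak: float = 800.0           # W/m2 clear-sky noon peak
    cloud_p: tuple = (0.10, 0.08, 0.08, 0.10, 0.12, 0.12, 0.14, 0.14, 0.12)
    wet_prob: float = 0.15           # probability an hour is wet
    precip_rate: float = 1.0         # expected L/m2 in a wet hour
    latitude: float = 43.4           # deg N, for the solar-elevation proxy

    def validate(self):
        if not 0.0 <= self.temp_ar1 < 1.0:
            raise ValueError("temp_ar1 must be in [0, 1)")
        if self.wd_concentration < 0:
            raise ValueError("wd_concentration must be >= 0")
        if len(self.cloud_p) != 9 or abs(sum(self.cloud_p) - 1.0) > 1e-9:
            raise ValueError("cloud_p must be 9 okta-class probabilities summing to 1")
        if not 0.0 <= self.wet_prob <= 1.0:
            raise ValueError("wet_prob must be a probability")


@dataclass
class MetResponse:
    """Coupling of concentration to meteorology in the generative model.

    g(met) = (1 + ws)^ws_exponent                      dispersion, monotone
             * exp(temp_coeff * (T - 15))              stability proxy
             * exp(sr_coeff * SR / 800)                photochemistry proxy
             * exp(-precip_coeff * LL)                 washout
             * (1 + wd_amplitude * cos(2*(wd - wd_phase)))   bimodal in wd

    All-zero coefficients give g identically 1.
    """

    ws_exponent: float = -0.4
    temp_coeff: float = -0.02     # per deg C
    sr_coeff: float = -0.15       # per 800 W/m2
    precip_coeff: float = 0.08    # per L/m2
    wd_amplitude: float = 0.15    # must stay < 1 to keep g positive
    wd_phase: float = 225.0       # deg

    def g(self, met):
        wd_rad = np.deg2rad(met["wd"].to_numpy() - self.wd_phase)
        return ((1.0 + met["ws"].to_numpy()) ** self.ws_exponent
                * np.exp(self.temp_coeff * (met["air_temp"].to_numpy() - 15.0))
                * np.exp(self.sr_coeff * met["sr"].to_numpy() / 800.0)
                * np.exp(-self.precip_coeff * met["ll"].to_numpy())
                * (1.0 + self.wd_amplitude * np.cos(2.0 * wd_rad)))


def _flat_met_response():
    return MetResponse(ws_exponent=0.0, temp_coeff=0.0, sr_coeff=0.0,
                       precip_coeff=0.0, wd_amplitude=0.0)


@dataclass
class EmissionScenario:
    """Ground-truth emission structure of a simulated pollutant."""

    base_level: float = 20.0                      # ug/m3
    diurnal_profile: tuple = ()                   # 24 multipliers, mean 1
    weekday_profile: tuple = (1.1, 1.1, 1.1, 1.1, 1.1, 0.8, 0.7)
    annual_trend_slope: float = -0.02             # fraction per year
    period_multipliers: dict = field(default_factory=dict)
    noise_sd: float = 2.0                         # ug/m3
    met_response: MetResponse = field(default_factory=MetResponse)

    def __post_init__(self):
        if not self.diurnal_profile:
            self.diurnal_profile = default_diurnal_profile()
        if isinstance(self.met_response, dict):
            self.met_response = MetResponse(**self.met_response)
        self.validate()

    def validate(self):
        if self.base_level <= 0:
            raise ValueError("base_level must be positive")
        if len(self.diurnal_profile) != 24:
            raise ValueError("diurnal_profile needs exactly 24 entries")
        if abs(np.mean(self.diurnal_profile) - 1.0) > 1e-9:
            raise ValueError("diurnal_profile must average 1")
        if len(self.weekday_profile) != 7:
            raise ValueError("weekday_profile needs exactly 7 entries")
        if abs(np.mean(self.weekday_profile) - 1.0) > 1e-9:
            raise ValueError("weekday_profile must average 1")
        if any(m <= 0 for m in self.period_multipliers.values()):
            raise ValueError("period multipliers must be positive")


def default_diurnal_profile():
    """Traffic-like double-peak diurnal emission profile (mean 1)."""
    hours = np.arange(24)
    profile = (1.0
               + 0.45 * np.exp(-0.5 * ((hours - 8.0) / 1.8) ** 2)
               + 0.35 * np.exp(-0.5 * ((hours - 19.0) / 2.2) ** 2)
               - 0.35 * np.exp(-0.5 * ((hours - 3.0) / 2.5) ** 2))
    profile /= profile.mean()
    return tuple(float(v) for v in profile)


def flat_scenario(base_level=20.0, **overrides):
    """Scenario with every modulation disabled (constant expected level)."""
    params = dict(base_level=base_level,
                  diurnal_profile=(1.0,) * 24,
                  weekday_profile=(1.0,) * 7,
                  annual_trend_slope=0.0,
                  period_multipliers={},
                  noise_sd=0.0,
                  met_response=_flat_met_response())
    params.update(overrides)
    return EmissionScenario(**params)


def simulate_meteorology(start_date, end_date, params=None, seed=0):
    """Hourly meteorology from ``start_date`` 00:00 to ``end_date`` 23:00.

    Temperature follows seasonal + diurnal cosine cycles plus AR(1) noise;
    solar radiation is a clipped solar-elevation proxy attenuated by cloud
    cover (zero at night); wind speed is log-normal, wind direction von
    Mises, humidity clipped Gaussian, precipitation exponential in randomly
    wet hours. Bitwise reproducible for a fixed seed.
    """
    params = params or MetParams()
    params.validate()
    start_date = pd.Timestamp(start_date)
    end_date = pd.Timestamp(end_date)
    if end_date < start_date:
        raise ValueError("end_date must not precede start_date")
    index = pd.date_range(start_date, end_date + pd.Timedelta(hours=23), freq="h")
    n = len(index)
    rng = np.random.default_rng(seed)

    hour = index.hour.to_numpy()
    doy = index.dayofyear.to_numpy() + hour / 24.0
    seasonal = params.temp_seasonal_amp * np.cos(2 * np.pi * (doy - 196.0) / 365.25)
    diurnal = params.temp_diurnal_amp * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    if params.temp_noise_sd > 0:
        eps = rng.normal(0.0, params.temp_noise_sd, n)
        ar1 = lfilter([1.0], [1.0, -params.temp_ar1], eps)
    else:
        ar1 = np.zeros(n)
    air_temp = params.temp_mean + seasonal + diurnal + ar1

    ws = rng.lognormal(params.ws_logmean, params.ws_logsd, n)
    if params.wd_concentration > 0:
        wd = (np.rad2deg(rng.vonmises(0.0, params.wd_concentration, n))
              + params.wd_prevailing) % 360.0
    else:
        wd = rng.uniform(0.0, 360.0, n)
    rh = np.clip(rng.normal(params.rh_mean, params.rh_sd, n), 0.0, 100.0)

    cl = rng.choice(9, size=n, p=params.cloud_p).astype(float)
    declination = 23.44 * np.sin(2 * np.pi * (doy - 81.0) / 365.25)
    lat = np.deg2rad(params.latitude)
    dec = np.deg2rad(declination)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    sin_elev = (np.sin(lat) * np.sin(dec)
                + np.cos(lat) * np.cos(dec) * np.cos(hour_angle))
    sr = params.sr_peak * np.clip(sin_elev, 0.0, None) * (1.0 - 0.75 * cl / 8.0)

    wet = rng.random(n) < params.wet_prob
    ll = np.where(wet, rng.exponential(params.precip_rate, n), 0.0)

    return pd.DataFrame({"ws": ws, "wd": wd, "air_temp": air_temp, "rh": rh,
                         "sr": sr, "cl": cl, "ll": ll}, index=index)


def simulate_pollutant(met, scenario, calendar=None, seed=0):
    """Hourly pollutant concentrations driven by ``met`` and ``scenario``.

    ``calendar`` (a :class:`PeriodCalendar`) maps timestamps inside its span
    to period labels whose multipliers come from
    ``scenario.period_multipliers`` (default 1); timestamps outside the
    calendar span (e.g. reference years) get multiplier 1. A timestamp
    inside the span but in a calendar gap raises, naming the timestamp.
    """
    scenario.validate()
    index = met.index
    hour = index.hour.to_numpy()
    dow = index.dayofweek.to_numpy()  # Monday=0
    years = (index - index[0]).total_seconds().to_numpy() / (365.25 * 86400.0)

    multiplier = np.ones(len(index))
    if calendar is not None and scenario.period_multipliers:
        dates = index.normalize()
        unique_dates = dates.unique()
        lookup = {}
        for d in unique_dates:
            dd = d.date()
            if calendar.start <= dd <= calendar.end:
                label = calendar.assign_period(dd)  # raises in gaps
                lookup[d] = scenario.period_multipliers.get(label, 1.0)
            else:
                lookup[d] = 1.0
        multiplier = dates.map(lookup).to_numpy(dtype=float)

    diurnal = np.asarray(scenario.diurnal_profile)[hour]
    weekday = np.asarray(scenario.weekday_profile)[dow]
    trend = 1.0 + scenario.annual_trend_slope * years
    g = scenario.met_response.g(met)
    conc = scenario.base_level * diurnal * weekday * trend * multiplier * g
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, scenario.noise_sd, len(index))
    conc = np.clip(conc, 0.0, None)
    return pd.Series(conc, index=index, name="concentration")


def inject_missingness(series, fraction, seed=0):
    """Mask exactly ``floor(fraction * n)`` values (uniform, no replacement)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    out = series.copy()
    n_mask = int(np.floor(fraction * len(series)))
    if n_mask == 0:
        return out
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(series), size=n_mask, replace=False)
    out.iloc[positions] = np.nan
    return out


@dataclass
class SyntheticDataset:
    """A simulated site: hourly met + pollutant plus its generative truth."""

    met: pd.DataFrame
    pollutant: pd.Series
    truth: EmissionScenario
    seed: int
    pollutant_name: str = "no2"

    def to_hourly_table(self):
        table = self.met.copy()
        table[self.pollutant_name] = self.pollutant
        return table

    def write(self, csv_path, truth_path=None):
        from .hourly_io import write_hourly
        write_hourly(self.to_hourly_table(), csv_path)
        if truth_path is not None:
            payload = asdict(self.truth)
            payload["seed"] = self.seed
            payload["pollutant"] = self.pollutant_name
            with open(truth_path, "w") as fh:
                yaml.safe_dump(payload, fh)


def simulate_dataset(start_date, end_date, met_params=None, scenario=None,
                     calendar=None, seed=0, missing_fraction=0.0,
                     pollutant_name="no2"):
    """Generate a complete synthetic site dataset (met + pollutant + truth).

    All randomness derives from ``seed`` through independent child streams
    for meteorology, concentration noise and the missingness mask.
    """
    scenario = scenario if scenario is not None else EmissionScenario()
    met_seed, conc_seed, miss_seed = np.random.SeedSequence(seed).spawn(3)
    met = simulate_meteorology(start_date, end_date, met_params, seed=met_seed)
    pollutant = simulate_pollutant(met, scenario, calendar, seed=conc_seed)
    if missing_fraction > 0:
        pollutant = inject_missingness(pollutant, missing_fraction, seed=miss_seed)
    return SyntheticDataset(met=met, pollutant=pollutant, truth=scenario,
                            seed=seed, pollutant_name=pollutant_name)
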