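# metnorm

Meteorological and emission-trend normalisation of hourly air-quality time
series, for quantifying how an intervention (such as the 2020 COVID-19
restrictions) changed pollutant levels relative to a multi-year reference.

Observed concentration changes confound three things: emissions, weather
and long-term emission trends. A mild, windy spring can mimic an emission
reduction; a multi-year downward trend inflates any "2020 vs previous
years" comparison. `metnorm` disentangles them:

1. **Model** — a boosted regression tree ensemble
   f̂(x) = Σ_b λ·f̂ᵇ(x) is fitted to hourly concentrations from surface
   meteorology (wind speed/direction, temperature, relative humidity, solar
   radiation, cloud cover, precipitation) and temporal covariates (hour,
   weekday, week of year, long-term trend). Trees are grown on residuals
   with RSS-minimising binary splits, d splits per tree, residuals updated
   as rᵢ ← rᵢ − λ·f̂ᵇ(xᵢ); assessed on a random 80/20 split with
   Pearson r, RMSE and mean bias.
2. **Normalise** — the fitted model is predicted hundreds of times with the
   meteorological block of every hour replaced by that of a randomly drawn
   donor hour; averaging gives a daily series at "average meteorology"
   (deweathering, *dw*). Resampling the trend covariate as well converts
   the reference period into a fixed-emissions scenario (detrending, *dt*).
   The seasonal `week` variable is always held, the day-of-week is
   normalised.
3. **Compare** — each calendar day of the intervention year is paired with
   the mean of the same (month, day) across the reference years, and
   period means over a restriction calendar (pre-lockdown, lockdown,
   de-escalation phases, …) are compared as a percentage,
   P_i = 100·(C̄_2020,i − C̄_ref,i)/C̄_2020,i (the printed convention;
   a reference-mean denominator is available via
   `denominator="reference"`).

Theil–Sen trend estimation (median pairwise slope, bootstrap CI) is
included for characterising reference-period trends and for verifying the
detrending step. A synthetic-data module generates hourly meteorology and
multiplicatively structured pollutant series with known emission
multipliers, trends and meteorological coupling, so the whole pipeline is
validated end-to-end against ground truth without any external data.

## Worked example

Simulate four years of hourly data (2017–2019 reference + 2020) in which
lockdown emissions are halved (multiplier 0.5) on top of a −2%/yr trend,
weekday/diurnal cycles and weather-driven variability, then run the full
pipeline:

```python
import metnorm as mn
from metnorm.pipeline import run_report

calendar = mn.PeriodCalendar.default_2020()
scenario = mn.EmissionScenario(period_multipliers={"lockdown": 0.5})
ds = mn.simulate_dataset("2017-01-01", "2020-12-31", scenario=scenario,
                         calendar=calendar, seed=1)
result = run_report(ds.to_hourly_table(), "no2", n_trees=100, n_samples=40,
                    seed=1, denominator="reference")
print(f"hold-out r (2020 model): {result.metrics_2020.pearson_r:.3f}")
dwdt = result.changes[result.changes["mode"] == "dwdt"]
print(dwdt[["period", "mean_2020", "mean_ref", "percent_change", "n_days"]]
      .round(2).to_string(index=False))
```

Output:

```
hold-out r (2020 model): 0.902
               period  mean_2020  mean_ref  percent_change  n_days
         pre-lockdown      13.33     13.02            2.42      72
             lockdown       6.65     12.91          -48.53      48
               phase0      11.85     12.86           -7.85      10
               phase1      11.64     12.87           -9.54      14
               phase2      11.66     12.86           -9.34      14
               phase3      11.68     12.85           -9.06      13
        new-normality      11.78     12.86           -8.43     126
second-state-of-alarm      12.74     12.85           -0.86      68
```

The deweathered-and-detrended (dwdt) comparison recovers the injected
lockdown halving (−48.5% vs the true −50% under the reference-mean
denominator) and a near-null pre-lockdown "validation" period (+2.4%),
while the hold-out correlation shows the model explains most of the hourly
variability. The few-percent negative offsets in the later periods reflect
the method's structural convention of comparing against the
reference-period average emission level (see `docs/methods.md`).

The same workflow is available from the shell:

```sh
metnorm simulate --start 2017-01-01 --end 2020-12-31 --seed 1 --out data.csv
metnorm report --config run.yaml --out changes.csv
```

with `run.yaml` holding the data path, pollutant, hyperparameters and
seeds; `metnorm fit`, `normalise`, `trend` and `changes` expose the
individual stages.

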