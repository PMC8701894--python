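# Methods

## Problem and approach

Hourly pollutant concentrations (NO, NO₂, PM₁₀, O₃, µg/m³) at a monitoring
site are driven simultaneously by emissions and by meteorology: wind speed
governs dispersion, temperature proxies atmospheric stability, solar
radiation drives photochemistry, precipitation washes particles out. When an
intervention (here, the 2020 COVID-19 restriction calendar) changes
emissions, the observed concentration change confounds the emission signal
with whatever weather happened that year and with multi-year emission
trends. `metnorm` removes both nuisance components by *meteorological
normalisation*: a flexible regression model is fitted to the hourly data and
then predicted many times under resampled nuisance conditions; averaging the
predictions yields a daily series at "average meteorology" in the original
units.

The pipeline per site and pollutant:

1. **Model.** A boosted regression tree ensemble f̂(x) = Σ_b λ·f̂ᵇ(x) is
   fitted to hourly concentrations from predictors
   {ws, wd, air_temp, rh, sr, cl, ll, hour, weekday, week, trend}.
   Separate models are fitted for the intervention year and for the
   multi-year reference period.
2. **Deweathering (dw).** The met block (plus hour, weekday) is resampled;
   `week` and `trend` are held. Applied to the intervention year.
3. **Deweathering + detrending (dw+dt).** As above but `trend` is also
   resampled, converting the reference period into a fixed-emissions
   scenario. Applied to the reference period only.
4. **Comparison.** Each calendar day of the intervention year is paired with
   the mean of the same (month, day) over the reference years; period means
   over the restriction calendar are compared as a percentage.

## Boosted regression trees

Trees are grown on residuals with least-squares splits: every split is the
(predictor j, cutpoint s) minimising

    Σ_{x∈R1}(r−r̄_R1)² + Σ_{x∈R2}(r−r̄_R2)²,  R1={x_j<s}, R2={x_j≥s},

with candidate cutpoints at midpoints between consecutive distinct sorted
values. The cutpoint search scans an O(n log n) cumulative-sum recursion,
then recomputes the RSS of near-minimal candidates with the direct
two-region formula so the reported (s, RSS) is exact (the scan can lose
precision to cancellation). Ties break deterministically: lowest RSS, then
lowest predictor index, then lowest cutpoint; tied leaves split in creation
order.

*Interaction depth* d counts **splits per tree** (a depth-6 tree has ≤7
leaves), allocated best-first across the frontier: each of the d splits is
the largest-RSS-reduction split available anywhere in the current tree. The
alternative reading (d = maximum tree depth, ≤2ᵈ leaves) would give bushier
trees; the split-count reading matches the additive-residual formulation and
is what the implementation uses.

The ensemble starts from zero — residuals initialise at y, with no intercept
term — so the residual identity rᵢ = yᵢ − f̂(xᵢ) holds exactly at every
iteration. Common implementations initialise at the response mean; with
shrinkage λ = 0.1 the zero start is absorbed within a few dozen trees and
makes the additive identity literal. Default hyperparameters are
λ = 0.1, d = 6, 1000 trees, chosen as the standard configuration for this
application domain; `bag_fraction = 1.0` by default, so boosting is fully
deterministic (an optional seeded subsample < 1 is provided but not used in
the validation runs). Model assessment uses a uniform random 80/20
train/test split and reports Pearson r, RMSE and mean bias.

Categorical temporal variables (hour 0–23, weekday 1–7, week 1–53) are
encoded as ordered integers and split like continuous predictors. Wind
direction enters as raw degrees; trees approximate the circular response
with multiple splits (the synthetic generator's bimodal wd response is
recovered this way). Rows with any missing predictor or response are
dropped before fitting; predicting on rows with missing predictors is an
error rather than a guess.

`week` is defined as ((dayofyear−1) // 7) + 1, i.e. seven-day blocks
anchored at 1 January. ISO week numbers were rejected because they wrap
year boundaries (late-December days belong to ISO week 1), which would
break the alignment between the held seasonal variable and the day-matched
comparison.

## Normalisation by resampled prediction

For each of `n_samples` repetitions (default 200), every row's resampled
predictors are replaced by those of one uniformly drawn donor row — drawn
as a **joint row block**, preserving cross-variable correlation (so full
solar radiation cannot be paired with midnight: `hour` travels with the met
block). `weekday` is resampled independently and uniformly over 1–7,
averaging the working-day/weekend emission cycle. Predictions are averaged
over repetitions and aggregated to daily means; the per-day standard error
across repetitions is reported so the Monte-Carlo adequacy of `n_samples`
can be judged (error shrinks as 1/√n_samples; the exact limit is the
enumeration average over all donor rows, which the tests verify on small
frames).

Sampling is with replacement from the full span of the supplied frame, not
season-matched: seasonality is carried by the held `week` variable, which
is the mechanism that keeps the day-matched comparison meaningful. Output
clipping at zero is off by default — averages of tree predictions fitted to
non-negative responses are non-negative anyway.

Holding `trend` (intervention-year runs) preserves that year's emission
level; resampling it (reference runs) averages emissions over the reference
span. Note the consequence: the detrended reference sits at the
*reference-period mean* emission level, not at the intervention year's
trend-extrapolated level. With a persistent emission trend this leaves a
deliberate residual gap — the method quantifies changes against the
reference-period average, not against a business-as-usual counterfactual,
which it explicitly does not construct.

## Trend characterisation

Reference-period trends are characterised by the Theil–Sen estimator
(median of all pairwise slopes with distinct abscissae; intercept
median(y − slope·x)), computed on calendar-month means (months under 75%
capture dropped). Uncertainty comes from case-resampling bootstrap
(B = 1000): percentile 95% CI and a two-sided sign p-value
2·min(frac ≤ 0, frac ≥ 0). No autocorrelation correction is applied; with
monthly aggregation the residual autocorrelation is modest and the CI is
used descriptively. Deseasonalisation before trend estimation is available
conceptually but off by default, as the validation scenarios have no
week-by-trend interaction.

## Period-change quantification

The default 2020 calendar has eight contiguous periods: pre-lockdown
(1 Jan–13 Mar), lockdown (14 Mar–30 Apr), phases 0–3 (1–10 May, 11–24 May,
25 May–7 Jun, 8–20 Jun), new normality (21 Jun–24 Oct), second state of
alarm (25 Oct–31 Dec). Period bounds are inclusive; every day of 2020 maps
to exactly one period (property-tested over all 366 days).

As printed in the reference formulation, the percentage change divides by
the **intervention-year** mean:

    P_i = 100 · (C̄_2020,i − C̄_ref,i) / C̄_2020,i,

under which a halving reads as −100% and a doubling as +50%. This is the
package default. The conventional reference-mean denominator
(`denominator="reference"`, halving = −50%) is provided because the
intervention denominator stretches the scale exactly where reductions are
large: a given relative error in the recovered level roughly doubles on the
P scale once concentrations halve. The end-to-end validation is therefore
quoted under the reference denominator, where truth for a 0.5 multiplier is
−50%. A period mean requires ≥75% of its days present in both series;
sparser periods are flagged and their change left undefined.

Site-group summaries are five-number box-plot statistics plus the mean,
with 1.5×IQR whiskers; no site exclusions are applied by default.

## Synthetic data generator

The generator defines the study conditions for every validation. The
meteorology emulates a mild oceanic coastal climate: temperature =
14 °C mean + 6 °C seasonal and 4 °C diurnal cosine cycles + AR(1) hourly
noise (φ = 0.9, σ = 1 °C); log-normal wind speed (median ≈ 2 m/s); von
Mises wind direction around a prevailing 225°; clipped-Gaussian humidity;
solar radiation from a clear-sky solar-elevation proxy at 43.4° N
attenuated by sampled okta cloud cover (zero at night); exponential
precipitation in wet hours (p = 0.15, mean 1 L/m²).

Concentrations are multiplicative — base level 20 µg/m³ × diurnal
(two rush-hour peaks) × weekday (weekend reduction) × linear annual trend ×
period multiplier × met response g(met), plus Gaussian noise (σ = 2 µg/m³)
truncated at zero. The met response is monotone decreasing in wind speed
((1+ws)^−0.4), mildly decreasing in temperature and solar radiation,
washout in precipitation, and smoothly bimodal in wind direction. The
multiplicative structure makes "percentage change" exactly defined (a 0.5
lockdown multiplier is a −50% emission change) and is learnable by trees;
it is a deliberate idealisation. Features of real data it does **not**
emulate: NOx–O₃ titration chemistry, Saharan-dust episodes, boundary-layer
height variation, instrument drift, or spatial correlation between sites —
so passing recovery tests demonstrate the statistical machinery, not
robustness to those physical processes. An unobserved-confounder channel
was considered and left out: the recovery tests need unambiguous truth.

All generators are pure functions of (arguments, seed); dataset-level
seeding derives independent child streams for meteorology, noise and
missingness from one integer.

## Validation results computed by the suite

The end-to-end check simulates 8 years (7 reference + intervention) with a
0.5 lockdown multiplier, −2%/yr trend and met confounding, then runs the
full pipeline at 200 trees and n_samples = 50 (problem sizes chosen so the
whole validation runs comfortably on one CPU; the full 1000-tree
configuration is exercised once as a hold-out-accuracy smoke check). Across
seeds the dwdt lockdown estimate lands within ±10 points of −50%
(reference denominator) and pre-lockdown within ±10 of 0%. The residual
few-point pre-lockdown bias is structural, as discussed above: the
detrended reference sits at mid-reference emission levels (≈3.6 years
before the intervention year at −2%/yr ⇒ ≈7% level gap), partially offset
by what the one-year intervention model attributes to its held `week`
variable. This mirrors the behaviour of the method on real data, where the
pre-lockdown period acts as a validation phase and is not exactly null.

## Known limitations

- The intervention-denominator convention amplifies level errors for large
  reductions; use `denominator="reference"` when comparing against
  emission-multiplier ground truth.
- Detrending does not extrapolate the trend into the intervention year (no
  business-as-usual counterfactual); estimates are relative to the
  reference-period average emission level.
- Bootstrap trend intervals ignore serial correlation.
- The quality screen (90% met capture, 5% pollutant missingness) is
  advisory: it warns and proceeds, matching monitoring-network practice of
  ignoring small gaps.
- Hourly models, daily comparison: models are fitted on hourly rows and
  predictions aggregated to daily means at the normalisation stage; fitting
  directly on daily means would discard the diurnal information the hour
  predictor carries.
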