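# Methods

## Scope and model

The package estimates the long-term burden of ambient PM2.5 on a city
population and the benefits of observed or hypothetical concentration
reductions. It is an attributable-burden calculation, not an epidemiological
fit: all concentration-response parameters are inputs, taken from published
cohort and time-series literature, and the pipeline propagates them through
exposure, burden and valuation arithmetic.

**Exposure.** Annual mean concentration per monitoring station is the
arithmetic mean of available daily values (daily maximum 8-h running mean for
O3). District annual means are unweighted means over the district's stations;
the city mean is the unweighted mean over *all* stations (station-weighted,
not district-weighted — this matches the convention of averaging "over the
fixed monitoring stations" rather than population- or area-weighting).
Districts with no station in a year receive the city mean, flagged
`imputed = true`. Station-years with daily coverage below 0.75 of the civil
year trigger a warning but are never dropped: silent exclusion would bias
means in ways the user cannot see. Years are civil years; leap days count in
coverage denominators.

**Mortality risk (GEMM).** For cause-specific mortality among adults the
hazard ratio at annual concentration `c` is

    HR(c) = exp{ θ · f(z) · ω(z) },   z = max(0, c − c_cf)

with `f(z) = z` (`linear`) or `log(1+z)` (`log1p`), and logistic weight
`ω(z) = 1/(1 + exp{−(z−μ)/(τ·r)})` where `r` is the concentration range of
the fitting data. The counterfactual `c_cf` defaults to 2.4 µg/m³ — the lower
bound of the exposure range the GEMM family was estimated over — and is
configurable. HR is exactly 1 at `z = 0`; a negative θ at a confidence bound
is floored at HR = 1 with a warning, since attributing protective effects to
PM2.5 would contradict the model's boundary condition. The exact (θ, μ, τ, r)
sets per cause used in the original city study are not published; the package
ships plausible-magnitude defaults in `gemm_params.csv` as *editable data*,
and nothing in the validation depends on their exact values. The combined
non-communicable-disease + lower-respiratory-infection curve is included but
unused by default (the per-cause tables cover IHD, stroke, LC, COPD).

**Morbidity risk (log-linear).** `RR(c) = exp[β · max(0, c − C₀)]` with
`β = ln(RR_ΔC)/ΔC` from published relative risks per ΔC = 10 µg/m³ and
reference concentration C₀ = 10 µg/m³. The shipped defaults are the published
values: RHA 1.022 (1.013–1.032), CHA 1.013 (1.007–1.019), CB 1.029
(1.014–1.044), AA 1.021 (1.015–1.028), REV 1.010 (1.005–1.016). Exposure at
or below C₀ yields RR = 1 (clamped).

**Burden.** Per endpoint and district,
`HI = [(RR−1)/RR] · P · Pop` with P the baseline event rate (events per
person-year) and Pop the exposed population; city totals sum districts.
Counts are kept as reals internally; rounding to whole events (half-up)
happens only at report rendering. Confidence bounds rerun the whole pipeline
at the low/central/high risk bound (θ ± 1.96·SE for mortality, the published
CI endpoints for morbidity). Benefit tables difference central estimates;
benefit bounds difference bound-wise and are then min/max-ordered so
low ≤ central ≤ high. This is a declared convention: the published
per-endpoint benefit CIs are not derivable from the per-year CIs by any
stated rule (e.g. IHD 669 with CI 621–710 cannot be obtained by subtracting
the year columns), so validation uses central estimates only. Scenarios
replace every district's PM2.5 by a uniform target while holding the
comparison year's rates and populations fixed; each comparison year uses its
own population.

**Valuation.** `value = events × cost_per_case`, willingness-to-pay for
mortality and cost-of-illness for morbidity, with borrowed unit costs
rescaled by the GDP-per-capita ratio
(`cost × gdp_pc_target / gdp_pc_source`). All currency is nominal US$ of a
declared reference year; no discounting, inflation or exchange-rate
modelling. GDP shares are `100 × benefit / GDP`, rendered to two decimals.

## Synthetic data

The generator reproduces the *structure* the analysis assumes, not the
physics of any real airshed:

- **Daily series**: `value = target · s(day) · ε`, where `s` is
  `1 + A·cos(2π(d − peak)/365.25)` with peak Jan 15 (Jul 15 for O3),
  normalized to mean exactly 1 over each civil year, and `ε` is lognormal
  with unit mean and coefficient of variation `noise_cv`. The normalization
  makes the noise-free annual mean equal the configured target exactly, which
  keeps seasonality and exact calibration compatible. Defaults: A = 0.4,
  cv = 0.3 — winter/summer contrasts and day-to-day scatter of the size seen
  in heavily polluted northern-Chinese cities; the source study reports no
  dispersion magnitudes, so these are exposed in the config.
- **Targets**: PM2.5 city means 110 → 63 µg/m³ over 2013–2017 (the study
  period's published values); SO2, PM10, CO, NO2 decline and O3 rises
  consistent with the published percent changes.
- **Network**: 15 stations over the six core districts in 2013–2015, 32
  covering all ten districts from 2016; the four outlying districts are
  imputed with the city mean before 2016.
- **Population**: district shares drawn once per run (lognormal, normalized),
  city total linear from 7.0 M to 7.3 M.
- **Baseline rates**: `scale × endpoint multiplier × ~10% district jitter`,
  constant across years by default (benefit attribution varies exposure, not
  rates; `year_specific_rates=True` adds a small yearly perturbation).
  Default scales give cause-specific mortality rates of order 10⁻³ and
  morbidity rates of order 10⁻³–10⁻², plausible for an adult urban
  population.
- **Unit costs**: defaults back-derived from the published monetary and count
  tables (≈ US$ 134,000 per death; US$ 8–7,150 per morbidity case), since the
  study's cost table is in unpublished supplementary material.
- **Randomness**: one master seed; each generator derives an independent
  stream from `SeedSequence((seed, stream_id))`, so outputs are byte-identical
  for identical (seed, config) and adding a generator never perturbs another.

What passing tests on synthetic data do **not** show: real data have spatial
autocorrelation between stations, missing days, meteorology-driven
persistence, and rate trends over time — none of which are modelled. The
synthetic runs validate the arithmetic and plumbing, not the epidemiology.

## Published-table fixture

`data/reference_tables.csv` carries the published per-endpoint central
estimates and 95% CIs (attributable counts and monetary values for 2013,
2017, the 15 µg/m³ scenario, and both benefit columns) plus the headline
summary figures. `verify_reference_tables` re-derives the summary figures
from the cells through the package's aggregation operations. Three
discrepancies internal to the published tables are flagged as notes, not
failures: the RHA/CHA benefit cells differ by 1 case from the year-column
differences (print rounding); the mortality monetary benefit cells (printed
to 0.1 hundred-million US$) sum to 320 M vs the printed 312.8 M; and the
printed overall benefit total (317.7 M) is inconsistent with its own
components (312.8 + 44.9 = 357.7 M). GDP-share computations therefore use the
printed totals as direct inputs. The avoided-morbidity total (15,822) is the
sum of the printed benefit cells; differencing the yearly totals gives 15,820
for the same print-rounding reason. One published percent reduction (IHD
scenario, 49.87%) contradicts its own table cells (2,542/4,246 = 59.87%) and
is excluded from the checks.

## Numerical choices

- Sub-reference clamping: RR = HR = 1 for `c ≤ C₀` (morbidity) or
  `c ≤ c_cf` (mortality); `attributable_fraction` rejects RR < 1 so clamping
  must happen upstream, never silently inside the burden sum.
- Problem sizes: the default synthetic run generates ~239k station-day
  records (5 years × 15–32 stations × 6 pollutants) and completes in about
  two seconds; tests use two-year configs where the full period adds nothing.
- Rendering rounds half-up (`floor(x+0.5)`) to integer events and one decimal
  in the money block's unit; totals are computed at full precision and
  rounded independently of the endpoint rows, so a rendered total can differ
  from the sum of rendered rows by a unit in the last place.
- Percent changes are signed so that positive = reduction, matching how
  air-quality improvements are reported.

## Limitations

- No age stratification, life-table or years-of-life-lost computation; the
  baseline rate absorbs the age structure.
- No short-term (time-series) effects, lags between exposure and outcome
  years, or O3/NO2/SO2 health effects — the health model is PM2.5-only.
- City means are station-weighted; population-weighted exposure would change
  district contributions in a city with uneven monitoring density.
- The published city-level percent changes in concentrations (e.g. 43.1% for
  PM2.5) rest on unrounded means not recoverable from the printed values, so
  they are cross-checked only approximately by the synthetic defaults.
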