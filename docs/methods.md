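# Methods

## Model

The PT-JPL formulation downscales Priestley-Taylor potential evaporation
to actual ET with multiplicative, unitless eco-physiological constraints,
and partitions it into canopy transpiration (ET_c), soil evaporation
(ET_s) and interception evaporation (ET_i). The implementation treats the
three component equations and the Beer–Lambert radiation partition as
given, and makes the following concrete choices where the formulation
leaves freedom:

- **Saturation vapor pressure and its slope Δ** use the Tetens (FAO-56)
  form `e_sat = 0.6108·exp(17.27·Tm/(Tm+237.3))` with its analytic
  derivative. This is the standard choice for daily air-temperature data;
  tests verify Δ against a centered finite difference of e_sat.
- **Constraint factors** follow the canonical forms of the original
  algorithm family: f_wet = (Rh/100)⁴; f_g = f_APAR/f_IPAR capped at 1;
  f_T = exp(−((Tm−T_opt)/T_opt)²); f_M = f_APAR/f_APAR,max with
  f_APAR,max the per-pixel record maximum; f_SM = (Rh/100)^(VPD/β) with
  β = 1 kPa by default. All coefficients are `PTJPLParams` fields.
- **f_APAR pathway**: a configurable linear function of NDVI (slope m₁,
  intercept b₁), defaulting to the same coefficients as f_IPAR so that
  f_g = 1 wherever vegetation is present. Whether a study uses a separate
  satellite f_PAR product or an NDVI-derived f_APAR is a data choice, not
  a model property; keeping both pathways configurable isolates the
  ambiguity.
- **T_opt** is estimated per pixel as the climatological-monthly mean air
  temperature of the month maximizing NDVI·Tm/VPD (the phenology-peak
  heuristic standard for this model family), falling back to 25 °C where
  the estimate is non-positive or undefined.
- **Soil evaporation energy**: ET_s is driven by the radiation reaching
  the soil surface, R_ns − G. A `printed_soil_radiation` flag switches
  the soil term to R_nc for comparison with formulations that print the
  canopy term there; the default follows the physical definition of R_ns.
- **Ground heat flux G** defaults to 0 at daily aggregation (daily soil
  heat storage approximately closes); optionally a fixed fraction of
  R_ns.
- **Energy→depth conversion** uses a fixed λ = 2.45 MJ/kg, i.e. 1 mm of
  water ≡ 2.45 MJ/m². A temperature-dependent λ changes daily ET by <2%
  over the physical range and is omitted.
- **f_IPAR clamp** to [0, 0.98] prevents the logarithmic LAI singularity
  as f_IPAR → 1 and negative values at sparse NDVI.
- **Negative fluxes** (e.g. nocturnal-dominated days with Rn < 0) are
  clamped to zero per component *before* summation, and clamp counts are
  logged. Additivity ET = ET_c + ET_s + ET_i is therefore exact by
  construction, as is radiation conservation R_nc + R_ns = Rn (R_nc is
  computed as the residual).

## Attribution experiments

`S_ALL` is a normal run; `S_CLI0` freezes Rn, Tm and Rh, and `S_NDVI0`
freezes NDVI, at a baseline annual cycle. The default baseline policy
repeats the first calendar year's daily cycle (the closest literal
reading of "initial baseline level"); a first-3-years climatology is
selectable. Composite-cadence drivers are gap-filled within the base year
before mapping and the target year's own missingness pattern is
re-imposed, so frozen NDVI keeps the cadence downstream interpolation
expects. Feb 29 maps to Feb 28 where the baseline year lacks it.

Sensitivities are intercept-free least-squares fits of annual basin-mean
differences, which coincide with the Gaussian maximum-likelihood
estimates; standard errors use the unbiased residual-variance estimator.
The vegetation (ΔNDVI) and climate (ΔTm, ΔRh, ΔRn) regressions are fitted
separately, as the two experiment pairs define them, at annual resolution.
An intercept flag exists because difference series need not be centered.
Rank-deficient designs (collinear or all-zero driver differences) raise
rather than silently pseudo-inverting. Per-pixel attribution is possible
by aggregating per pixel instead of basin-mean before fitting.

## Trends, turning points, correlation

Trends are ordinary least squares of annual values on the year with a
two-sided t-test on the slope; a constant series reports slope 0, p = 1.
The turning-point model is a *continuous* broken stick (the second
segment shares β₀ and β₁), fitted by exhaustive search over integer break
years excluding the first and last three years of the span — this
guarantees at least three points per segment and avoids endpoint
artifacts. The break is accepted when β₂ (the slope change) is
significant at 0.05; an exactly-linear input is reported not significant
rather than dividing two rounding residues. Correlation maps are
per-pixel Pearson R on annual series with a p > 0.05 mask and no
multiple-testing correction across pixels (each pixel is read as its own
test, matching the per-pixel gray-masking convention in basin studies);
numerically-constant pixels are flagged undefined and excluded from the
mask.

## Validation statistics and closure

R, RMSE, bias = mean(sim) − mean(obs), and NSE follow their standard
definitions; R² is reported as R·R for consistency between the two common
reporting conventions. Zero observation variance leaves R and NSE
undefined (NaN), not zero. The energy-balance-closure correction scales
daily latent heat by (Rn − G)/(LE + H), preserving the Bowen ratio while
closing the balance; records with non-positive available energy or
turbulent-flux sum are skipped and counted. Daily resolution is assumed
throughout.

## Synthetic forcing generator

Each driver is seasonal sinusoid + linear trend + stationary AR(1)
Gaussian noise, clipped to physical ranges after noise addition (clipped
fractions logged, so range invariants remain testable). The linear trend
advances with fractional year position (year index + (doy−1)/days-in-year)
so annual means step by exactly one trend increment per year regardless of
leap days, making injected trends exactly recoverable by regression on
annual means. AR(1) noise mimics weather persistence and deliberately
stresses the significance tests relative to white noise. NDVI is emitted
on a 16-day composite cadence restarting each Jan 1 (the cadence of
standard 16-day vegetation-index products) and gap-filled to daily by
linear interpolation downstream, with endpoints held flat.

Defaults emulate the study basin's climatology: Rn 7.25 MJ/m²/day,
Tm 9.89 °C, Rh 59.26 %, Ws 2.33 m/s, annual precipitation ≈ 522 mm, NDVI
around 0.45 with a +0.004/yr greening trend — and *only* NDVI carries a
deterministic trend, matching the observed situation in which vegetation
indices are the only significantly trending driver. Amplitudes and noise
levels (e.g. Tm amplitude 13 °C, sd 1.5 °C, AR(1) 0.7) are chosen as
realistic for a temperate monsoon basin; observation-error magnitudes for
the site generator are free parameters with a default of 0.5 mm/day. The
default grid is 20×20 pixels over 21 years of daily steps — large enough
for pixel-level significance analyses, small enough that the full
pipeline (model run, three scenario runs, attribution, trends) completes
in well under a minute. A deterministic ±5% across-column ramp of each
driver's mean keeps pixels from being statistically identical.

What the generator does *not* emulate: satellite QC bitfields and
orbit/cloud gap structure, spatial autocorrelation of noise between
pixels, station-interpolation error, land-cover heterogeneity, irrigation
or snow. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated statistical structure, not
the fidelity of any particular real-data product chain.

## Numerical choices

- Determinism: all generators derive independent per-driver streams from
  a single `SeedSequence`, so the same seed gives bit-identical cubes.
- Bilinear resampling operates on cell-center coordinates of north-up
  grids; out-of-envelope targets raise unless edge-clamping is enabled.
- NetCDF I/O uses the classic (NetCDF-3) format via xarray; cube payloads
  are stored float32. Map products are written as float32 TIFF with a
  JSON sidecar carrying grid origin, cell size and CRS.
- Zero-variance detection in correlation maps uses a relative threshold
  (10⁻¹⁰ of the series magnitude) so numerically-constant series are
  classified as degenerate despite rounding residue.
- The CLI `trends` stage skips turning-point detection for spans shorter
  than 7 years instead of failing the whole run.

## Known limitations

- The attribution regressions are strictly linear and additive; no
  interaction terms or variance decomposition.
- Freezing drivers at a first-year baseline conflates that year's weather
  with "the baseline state"; the climatology policy mitigates but does
  not remove this.
- The broken-stick search assumes at most one turning point and integer
  break years.
- No reprojection between coordinate systems; grids must share a CRS.
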