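# Methods

This note documents the models, estimators and design choices behind
`heatrisk`: a pipeline that quantifies heatwave *hazard*, population
*exposure* and a development-based *vulnerability* proxy on a global grid,
and aggregates them into an Illustrative Risk Index (IRI) under stabilised
warming levels (1.5 °C, 2 °C) and two socioeconomic pathways (SSP1, SSP4).

## Heatwave definition and indices

A heatwave is at least three consecutive days with daily maximum temperature
above the local calendar-day 90th-percentile threshold. The threshold for
calendar day *d* is the 90th percentile (linear interpolation between order
statistics) of all reference-period values in a 31-day window centred on
*d*, pooled across reference years; windows wrap across the year boundary.
The reference period is the present-climate ensemble of each model, pooled
over its years.

The annual **HWMId** (Heat Wave Magnitude Index daily) scales each heatwave
day's temperature by the interquartile range of the reference-period annual
maxima,

    Md(T) = (T − T25p) / (T75p − T25p)   if T > T25p, else 0,

sums `Md` over the days of each heatwave, and takes the maximum event sum in
the year (0 in years without a heatwave). Cells whose reference IQR is
degenerate (T75p = T25p, possible only on pathological inputs such as
constant series) are defined to have magnitude 0 and are flagged. **TX5x**,
the annual maximum of the 5-day running mean of daily Tmax, serves as a
simpler validation index; percentile rule, window length, threshold
percentile and minimum duration are all configurable.

## Extreme-value model

Annual HWMId values are reduced to 10-year block maxima and fitted with a
Generalized Extreme Value (GEV) distribution by the method of L-moments
(unbiased probability-weighted moments; Hosking's rational approximation for
the shape). The shape is constrained to the Gumbel/Fréchet branch,
ξ ≥ 0 (Coles convention): when the unconstrained solution lands in the
Weibull branch the sample is re-fitted as Gumbel, which keeps the constraint
continuous as ξ → 0.

**Return-period convention.** Return periods count *blocks* (decades): the
"HW500Y" event is the level whose fitted per-decade exceedance probability
is 1/500 = 0.2 %. The "year" in the name is a conventional label only. The
hazard of a warmed state is the per-decade probability, under that state's
fit, of exceeding the *present-climate* HW500Y level; under the present fit
itself this probability is 0.2 % exactly, because the return level and the
exceedance probability are exact functional inverses.

Confidence intervals for return levels come from the profile likelihood of
z_T under the ξ ≥ 0 constraint: the likelihood is re-parametrised in
(z_T, σ, ξ), the profile deviance is compared with the χ²(1) quantile, and
the bounds are found by bracketing plus Brent root-finding with multi-start
Nelder–Mead inner optimisations (a bootstrap CI is not provided; the profile
construction respects the boundary constraint directly).

Goodness of fit uses the Anderson–Darling statistic — more tail-weight than
Kolmogorov–Smirnov, appropriate for extremes — with a parametric bootstrap
p-value (default 200 replicates, each re-fitted by L-moments) because the
null parameters are estimated from the same sample. The test's empirical
size at α = 0.05 is checked in the acceptance suite (500 replicates of
n = 100 samples).

## Normalization of exposure and vulnerability

Population density and 1 − HDI are mapped to (0, 1) through the CDF of a
Johnson-family distribution fitted to the *present-period* field:

* population: the log-normal branch S_L with lower bound pinned at 0
  (support [0, ∞)); a zero density maps to score 0 exactly;
* 1 − HDI: the bounded branch S_B with support pinned to (0, 1), the
  definitional range of the index, so projected values can never leave the
  fitted support.

Ties are removed from the fitting sample only; the fitted CDF is applied to
the full present and projected fields, so equal raw values always receive
equal scores, and projections are always transformed through the
present-period fit. With the bounds pinned, both branches reduce to a
Gaussian model on the log/logit scale, where the maximum-likelihood
estimates of (γ, δ) are closed-form; a percentile-matching initialisation
would be refined to the same optimum, so the closed form is used directly.
Goodness of fit is reported via a Kolmogorov–Smirnov test; a rejection
flags the fit without failing it. Future population above the present range
saturates at score 1.

The fit requires at least 30 unique values. Because vulnerability is
constant within countries, this sets a lower bound on the number of
countries in the synthetic world (default 32).

## Risk index and aggregation

At each cell,

    IRI = hazard × exposure × vulnerability × 100   (percent),

with all three factors in [0, 1]. In the present period the two scores are
≤ 1, so present IRI ≤ 100 × present hazard probability = 0.2 %. The
non-normalized variant multiplies the hazard probability by raw population
density and raw 1 − HDI and keeps physical units (persons/km²).

Countries are classed by the fixed Human Development Report cutoffs with
strict inequalities: low development HDI < 0.55, very high development
HDI > 0.8; the band between is reported as "medium". Exposure tables sum
people — density × spherical cell area (cos-latitude weighting enters
through the exact sin-latitude band areas) — over cells with population
density > 0, binned by hazard probability or IRI level, and report each bin
as a percentage of the present global population. Ensemble tables give the
per-bin median, min and max across models. The bundle always contains the
difference fields (2 °C − 1.5 °C | SSP1), (2 °C − 1.5 °C | SSP4),
(SSP4 − SSP1 | 1.5 °C), (SSP4 − SSP1 | 2 °C) and (2 °C, SSP4) − (1.5 °C,
SSP1).

## Synthetic world

The generator emulates the statistical structure the analysis assumes,
not the physics of any region:

* **Climate.** Tmax = baseline(lat) + seasonal cycle + ΔT(state) + AR(1)
  noise, on a 365-day no-leap calendar. The AR(1) process (φ = 0.7,
  stationary start) resets each year, so annual index values are
  exchangeable and decadal block maxima meet the GEV block-maxima
  assumptions. Noise standard deviation is 1 °C inside a contiguous
  tropical band (|lat| ≤ 20°) and 3 °C outside it: the band's larger
  warming-to-noise ratio reproduces the amplified increase of extreme
  heatwave probabilities in low-variability regions. Warming offsets
  default to ΔT = 0.6 °C (1.5 °C state) and 1.1 °C (2 °C state) above
  present, reflecting roughly 0.9 °C of realised warming in the present
  state. Ensembles default to 500 years per state (50 decadal blocks),
  which keeps far-tail fits stable at desk-scale runtime; 200 years is the
  configurable minimum. Warmed states reuse the present noise realisation
  (common random numbers), so warming acts as a pure shift of the daily
  series and scenario orderings are not blurred by independent sampling
  noise.
* **Population.** Log-normal density (log-mean 4, log-sd 1.2 — median
  ≈ 55 persons/km²) on a native raster at twice the model resolution, with
  20 % of cells exactly zero (uninhabited; the zero set is fixed across
  periods and pathways). Future fields keep the present pattern and scale
  totals by 1.2 (SSP1) and 1.4 (SSP4), the end-of-century global totals of
  the two pathways relative to present.
* **Countries and HDI.** Countries are contiguous rectangular blocks of
  native cells. Present HDIs spread evenly over (0.35, 0.93), covering all
  three development classes; future HDI adds a pathway increment (0.08
  under rapid development SSP1, 0.03 under high-inequality SSP4), capped at
  0.98, so per country: SSP1 future ≥ SSP4 future ≥ present, all strictly
  inside (0, 1).

Everything is deterministic given the world seed; independent seed streams
cover climate (per model), population and HDI.

What the generator does *not* emulate — trends within an ensemble, monsoon
or ENSO-like structure, spatially correlated noise, population clustering
along coasts, sub-national HDI heterogeneity — means passing tests
demonstrate the statistical machinery, not fidelity to any observed region.
Headline percentages computed on the synthetic world (for instance
population shares above a given IRI level) characterise the synthetic study
conditions only and are not comparable to estimates from real climate and
population data.

## Grids and remapping

All grids are regular latitude–longitude with [−180, 180) half-open
longitude cells. Population and country rasters are remapped onto the model
grid by *first-order* conservative (area-overlap-weighted) averaging, which
preserves the area-integrated population exactly up to rounding; the
second-order refinement (gradient reconstruction) is omitted because on
smooth synthetic fields its correction is below test tolerances. Country
rasters remap by majority area with ties broken towards the lowest country
id. Missing values are NaN in memory and `_FillValue` on disk (classic
NetCDF via xarray's scipy engine; tables as UTF-8 CSV).

## Problem sizes and numerical choices

Default study conditions: 8×8 model grid, 16×16 native raster, 2 synthetic
models, 500 years per state, 3 climate states, AD bootstrap 200, 500-block
return period (a single configuration switch gives the HW100Y variant).
A full pipeline run completes in well under a minute on one CPU; the test
suite's statistical simulations (AD size study: 500 × 200 refits; profile-CI
coverage: 200 intervals) are sized to finish in a few minutes total.

Numerical details worth knowing: percentiles interpolate linearly between
order statistics everywhere (thresholds, quartiles, L-moment oracles);
L-moment fits treat |ξ| < 1e−9 as Gumbel; degenerate cells (identical block
maxima) are masked from hazard maps rather than fitted; the AD p-value uses
the (1 + #{A*≥A}) / (B + 1) convention so it is never exactly zero;
exposure bins follow `numpy.histogram` (right-closed last bin) and must be
strictly increasing.

## Known limitations

* The hazard is conditional on a decade: no multi-decadal variability, no
  non-stationary (covariate) GEV, no peaks-over-threshold alternative.
* Vulnerability is a country-constant proxy; the IRI has no dose–response
  calibration and its values are not physical risk estimates.
* The profile-likelihood CI can fail to bracket on pathological samples;
  such cells return missing intervals rather than halting.
* First-order (not second-order) conservative remapping, as noted above.
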