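# Methods

## The model

`soilews` treats each pixel's monthly spectral-index series as

    y(t) = trend(t) + seasonal(t) + ε(t),        t = 1 … n (months)

with `seasonal` a harmonic term of period 12 (default two sine/cosine
pairs), `trend` piecewise linear with at most one break, and `ε` Gaussian
AR(1) noise. Two questions are asked of every series:

1. **Did an abrupt change happen, and when?** The largest admissible break
   is located by scanning every candidate month and minimising the
   residual sum of squares of a two-segment trend fit; significance is a
   conjunction of an information-criterion comparison and a parametric
   bootstrap of the sup-F statistic (below).
2. **Was the change preceded by critical slowing down?** On the pre-break
   part of the record (everything up to two years before the break, so the
   indicators measure the *approach* to the transition, not the transition
   itself), rolling-window lag-1 autocorrelation, standard deviation and
   skewness are computed on the detrended series, and each indicator's
   monotone drift is summarised by the Kendall tau of indicator value
   against window end time.

The spatial companion reduces each pixel to the Kendall tau of raw index
value against month number — a rank-based "strength of change" in [−1, 1]
— and flags |τ| > 0.5 with p < 0.05 as strong-change hotspots. The ICONA
lookup-table model supplies the hazard stratification within which those
signals are read; its three matrices (erodibility from slope × lithofacies,
protection from land use × cover, hazard from protection × erodibility) are
data, not code, and live in `soilews/data/icona_tables.yaml`.

## Breakpoint detection in detail

The scan de-seasons the series with the harmonic fit of the no-break
decomposition, then evaluates every candidate break b with
`min_segment ≤ b ≤ n − min_segment` (default `min_segment` = 12: one full
seasonal cycle per segment) using closed-form two-segment linear
regression from prefix sums, so the scan is O(n) per series.

Significance of the best candidate at confidence level c (default 0.95)
requires both:

* **Information criterion.** BIC of the break model (two intercepts, two
  slopes, noise variance, and the searched break date charged *double*
  weight, following modified-BIC practice for changepoint selection) below
  the BIC of the unbroken model. With the conventional single charge the
  IC bar sits below the bootstrap's, i.e. it would never filter anything.
* **Bootstrap sup-F.** A parametric bootstrap (default 199 replicates,
  seeded) of the maximum F statistic over all candidates. Replicates are
  simulated from the null linear fit plus AR(1) noise whose lag-1
  coefficient is estimated from the null residuals with a first-order bias
  correction, and each replicate passes through the same seasonal-refit
  path as the observed series. Matching the autocorrelation matters: an
  i.i.d. bootstrap is anticonservative exactly when critical slowing down
  is plausible. Measured on stationary AR(0.2) series of length 240 the
  combined test rejects ~2.5 % of the time at c = 0.95.

Once a break is accepted, its month, magnitude and fitted components are
recomputed from an exact joint fit (two-segment trend *plus shared
harmonics* on the raw values) at the selected date. The two-stage split —
fast approximate scan for location and calibration, exact joint refit for
reporting — keeps the scan linear while making noise-free worked examples
exact to machine precision: de-seasoning with a single-trend harmonic fit
leaks a small seasonal error into a broken series, which would otherwise
contaminate the reported magnitude.

Reported break months are 1-based; `break_month` is the first month of the
post-break regime. Missing values: runs of ≤ 3 consecutive masked months
are linearly interpolated; longer gaps exclude the pixel from break
analysis rather than imputing structure.

## Early-warning indicators

All three indicators are computed inside windows of `window_frac` × series
length (default 0.5; valid range 0.25–0.75) advancing one month at a time
and stamped at the window's *end* month — the convention compatible with
early warning, since the indicator at time t then uses only data up to t.

* lag-1 autocorrelation: mean cross-product of deviations one step apart
  (n−1 pairs) over the biased window variance; zero-variance windows are
  flagged NaN, not errors.
* standard deviation: n−1 denominator.
* skewness: moment skewness m₃/m₂^{3/2}. (The common alternative that
  normalises by √(1/n)·Σ(z−μ)² is dimensionally inconsistent; the moment
  form is what "standardised third moment" means.)

Detrending menu: residuals of a Gaussian-kernel smooth (default, kernel
sigma = 0.1 × series length), LOWESS residuals, OLS-line residuals, or
first differences. The pipeline removes the harmonic seasonal component
*before* detrending: rolling AR1 on a still-seasonal monthly series mostly
measures the seasonal harmonic (lag-1 autocorrelation of a period-12
sinusoid is cos(2π/12) ≈ 0.87), not slowing down. Because no single
detrend/window choice is canonical, `sensitivity_grid` tabulates the
Kendall taus over the full factorial of methods × bandwidths × window
fractions; conclusions should be stable across the grid.

Kendall tau is tau-b (tie-corrected), with exact enumeration for n ≤ 8
without ties and the tie-corrected normal approximation otherwise; the
Mann–Whitney U test used in validation follows the same exact/asymptotic
switch at n_a + n_b ≤ 12. Indicator p-values are reported uncorrected for
multiple testing (a Benjamini–Hochberg pass is available but off by
default, matching common practice in the EWS literature).

## The synthetic generator

`ScenarioConfig` defaults encode the emulated study conditions: 240 monthly
steps from January 2003 on a 20×20 grid of 30 m pixels, half the pixels in
an *eroded* stratum, an abrupt level step at month 121 (January 2013) of
0.15 index units = 3 × noise sd (NDVI down, NDSI up, TGSI unchanged — the
grain-size index acts as the no-signal control), a pre-break AR(1) ramp
from φ = 0.2 to φ = 0.9, harmonic seasonality of amplitude 0.1, and
Gaussian AR(1) noise of stationary sd 0.05.

Choices worth knowing:

* `noise_sd` is the *marginal* (stationary) noise sd — innovations are
  scaled by √(1−φ²) — so the planted step height stays interpretable in
  index units while φ ramps. The alternative (constant innovation sd)
  conflates the autocorrelation ramp with a variance ramp.
* After the break φ returns to `phi_start`: the system has settled into a
  new stable state, and indicators computed across the break should not
  inherit the ramp.
* An optional `break_slope_change` plants a continuing post-break trend in
  addition to the level step. A *pure* step bounds the per-pixel |τ| of
  the spatial map near 0.5 (only cross-segment pairs are concordant:
  2·(n/2)²/(n(n−1)/2) ≈ 0.503), so step-only scenes sit exactly at the
  hotspot threshold by construction; sustained post-break change is what
  makes spatial hotspots unambiguous.
* Ancillary rasters are drawn so the ICONA composition exactly recovers
  the strata (eroded: slope > 35 %, lithofacies 5, dry-farming/bare land,
  cover < 25 % → hazard 4–5; non-eroded the opposite → hazard 1).

What the generator does **not** emulate: cloud/gap structure, sensor
change and calibration drift, spatial autocorrelation between neighbouring
pixels (each pixel's noise is independent), mixed pixels at stratum
boundaries, and non-Gaussian heavy-tailed disturbances. Passing tests
therefore demonstrate the statistical machinery recovers planted structure
under the stated noise model — not that real Landsat records are this
clean.

## Numerical choices and edge cases

* Slope bins [0,3), [3,12), [12,20), [20,35), [35,∞) and cover bins
  [0,25), [25,50), [50,75), [75,100]: half-open with the top bin closed,
  resolving the published tables' overlapping endpoints deterministically.
* Zero-denominator index pixels (water/shadow) become NaN and propagate as
  mask, never exceptions, so cube computation cannot abort mid-scene.
* Index values are clipped to [−1, 1] after noise addition.
* A series whose unbroken linear fit already attains RSS ≤ 10⁻¹²·n is
  declared break-free without scanning (the F statistic is undefined).
* Protection levels stay symbolic (MA…MB): the published class-number
  prose and the hazard-table row order disagree, so numbering them invites
  silent transposition. The protection matrix rows for Sand Areas,
  Rangeland and Bare Land are typeset ambiguously in the source tables;
  the shipped parse keeps the monotone cover→protection pattern of the
  unambiguous rows, and `load_tables()` accepts a user-edited YAML for any
  alternative reading (the table hash is logged in every run report).
* "Severe" stratum = hazard classes 4–5, "low" = 1–2; class 3 is excluded
  from validation sampling as an intermediate band.

## Problem sizes

Defaults are sized for a desk-scale machine: the default scene is 20×20
pixels × 240 months; break detection with a 199-replicate bootstrap runs
at ~5 ms per pixel series, the full default scene in a few seconds, and
the complete pipeline (hazard map, 100-point break + EWS analysis, three
spatial tau maps, validation) in well under a minute.

## Known limitations

* Only the single largest break per series is modelled; staircase
  degradation (multiple breaks) will be summarised by its dominant step.
* The bootstrap models residuals as AR(1); strongly seasonal
  heteroscedasticity or long-memory noise would miscalibrate it.
* The spatial analysis is per-pixel temporal tau only; no
  spatial-neighbourhood indicators (spatial variance, Moran's I).
* Real-mode band-to-sensor mapping is the user's responsibility: the index
  formulas take R/G/B/NIR reflectances as given.
* Expert validation labels are an input; the package provides no
  elicitation tooling (synthetic truth labels stand in as pseudo-expert
  classes for pipeline tests).
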