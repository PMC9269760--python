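# Methods

This note records the models implemented by rseikit, the assumptions and
defaults behind them, and the design choices made where the problem was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Scope and data model

All per-pixel quantities live in a `RasterGrid`: a 2-D array with a
north-up affine georeference (top-left origin, positive pixel sizes in
metres, height applied southward), an opaque CRS string and an optional
nodata sentinel (NaN is always treated as nodata in float grids). GeoTIFF
I/O goes through tifffile, writing the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) plus a JSON ImageDescription
carrying the CRS and band names; a write→read round trip preserves values,
transform, CRS and nodata bit-exactly. Reprojection between CRSs is out of
scope — all stages require co-registered inputs and raise
`CoregistrationError` otherwise.

## Aerosol optical depth (dense dark vegetation)

The single-layer top-of-atmosphere equation for a uniform Lambertian
surface, with gas absorption ignored, is

    rho*(th_s, th_v, phi) = rho_a + T * rho / (1 - S * rho)

with path reflectance `rho_a`, total transmissivity `T` and spherical
albedo `S` supplied per (solar zenith, view zenith, relative azimuth, tau)
by a radiative-transfer lookup table. The inverse used per candidate tau is

    rho = (rho* - rho_a) / (T + S * (rho* - rho_a)),

exact wherever the denominator is positive; invalid pixels are flagged NaN
rather than clipped. Dark pixels are those with TOA NDVI strictly above
0.3 — TOA, not surface, NDVI, because the surface reflectance is not known
until the AOD is (a surface-NDVI criterion would be circular). For each
dark pixel the candidate tau grid (defaulting to the LUT's tau axis, which
guarantees every interpolation stays inside the hull) is scanned; the
retrieval is the tau minimising |rho_red/rho_blue − k| with k = 1.60, ties
broken toward smaller tau. Non-dark pixels receive the inverse-distance-
weighted mean (power 2) of the 12 nearest retrievals, and the whole field
is smoothed with a 3×3 mean filter: the method names these steps but not
their parameters, so these are this package's defaults, chosen as the
common practice values. IDW followed by mean filtering is a chain of convex
combinations, so filled values never leave the range of the retrievals, and
the result depends only on the set of retrieved pixels, not their order.

LUT interpolation is 4-D multilinear (scipy `RegularGridInterpolator`),
exact at grid nodes; queries outside the axis hull raise. A synthetic LUT
generator provides complete grids with physically shaped curves (path
reflectance rising and transmissivity decaying with tau and air mass, blue
scattering more than red); published sample rows can be stamped onto grid
nodes so that interpolation reproduces them exactly. The aerosol model and
atmospheric profile behind any real LUT are taken as given — running a
radiative-transfer code is out of scope.

An optional helper implements the mid-infrared dark-target relations
(surface red ≈ ½ and blue ≈ ¼ of the 2.1 µm reflectance) only implicitly
through the k-ratio path; the target sensor modelled here has no 2.1 µm
band, so the ratio path is the default and only fully supported route.

## Soil salinity

Band screening uses the diagnosis index `Di = 100 * sigma_i * R_i`, where
`sigma_i` is the population (ddof = 0) standard deviation of band i's
reflectance across the soil samples — computed on reflectance in the units
provided, since no single rescaling of the published screening tables is
self-consistent — and `R_i` its Pearson correlation with measured soluble
salt. Bands rank by |Di| descending, ties by band order; constant bands are
flagged and excluded rather than given Di = 0.

The linear model is ordinary least squares with intercept; the fitted
five-band regression from the Changyi campaign
(y = 23.25·B2 − 119.43·B6 + 375.46·B7 − 123.36·B8 − 237.96·B8A + 31.20)
ships as a named constant for map prediction and for parameter-recovery
testing. The BP network is a single-hidden-layer perceptron (logistic
activation, LBFGS, fixed seed) on min-max normalised inputs and outputs,
with the hidden-node count searched step-by-step from 2 upward until the
training MSE on normalised targets reaches 0.001 (cap 20 nodes; the
original campaign stopped at 14); if the target is never reached the best
network is returned with a `converged=False` flag. The network inputs
default to the same five bands as the regression — the alternative reading
(visible bands only) contradicts the side-by-side comparison the validation
table makes, so the consistent reading is adopted.

Validation reports `error = inverted − measured` and
`relative_error = 100 · error / inverted`. The denominator convention is
fixed by arithmetic: the published cells satisfy 9.43/10.96 = 86.04% only
with the inverted value underneath. Zero inversions are flagged, not
divided.

## Indicator suite

NDVI, wetness and the bare soil index are exact closed forms over
co-registered grids, with nodata propagated and zero denominators masked.
The bare soil index is the normalized difference
[(SWIR1+Red) − (NIR+Blue)] / [(SWIR1+Red) + (NIR+Blue)]: only this form is
bounded in [−1, 1] and inverse to wetness, which the dryness indicator
must be. The same tasseled-cap wetness weights serve Sentinel-2 surface
reflectance and Landsat apparent reflectance; the input convention is the
caller's to record, as the coefficients themselves are identical.

LST uses the single-channel radiative-transfer correction with
Planck-constant inversion; all parameters (emissivity, transmissivity,
path radiances, K1/K2, radiance gain/offset) come from scene metadata
configuration and are never hard-coded, because they are scene- and
sensor-specific. Pixels whose corrected blackbody radiance is non-positive
become nodata. Resampling between grids (e.g. a 30 m thermal product onto
a 10 m optical grid) offers nearest-neighbour (value-set preserving) and
bilinear (exact on linear ramps) over the same extent.

## RSEI composition

Normalization clips each indicator to its 2nd/98th percentile — the robust
reading of "2% confidence intervals" on the pixel histogram — then min-max
scales to [0, 1]; constant rasters map to 0.5 by declared convention. The
stack shares a union nodata mask. Negative-sense indicators (dryness,
heat, AOD, salinity) are *not* inverted before PCA: the published loading
table shows signed loadings on un-inverted inputs, and orientation is
handled once at composition.

SPCA is an eigendecomposition of the covariance (not correlation) matrix
of the valid-pixel observation vectors — the published eigenvalues are
variances of [0, 1]-scaled layers, not unit-normalised ones. All valid
pixels are used (no subsampling); eigenvalues are sorted descending and
each loading column's first nonzero entry is made positive, so the
decomposition is deterministic. RSEI projects pixels onto PC1, flips the
sign if the greenness loading is negative (the greenness-positive
convention — whether the original workflow rescaled PC1 or 1−PC1 is
unstated, so the convention is declared, not inferred), and min-max
rescales to [0, 1], a monotone transform that preserves pixel ranking.

Grades partition [0, 1] at 0.2 intervals, left-closed/right-open with the
top bin closed at 1.0 (no gaps, no overlaps); areas are pixel counts times
pixel area and always sum to the valid total. Change detection classifies
Δ = RSEI_b − RSEI_a with the Unchanged interval closed at both ends
(−0.1 ≤ Δ ≤ 0.1). The correlation report computes Pearson correlations
over valid pixels and, per variable, the mean absolute off-diagonal
correlation against the indicator layers.

**Water masking.** `run_on_scene` drops water pixels from the indicator
stack by default. Open water's extreme wetness/dryness/heat values
dominate the first principal component and, through the per-date min-max
rescale, can invert cross-date comparisons of the land surface; evaluating
RSEI over land only is the established convention for the index. The flag
`mask_water=False` restores the unmasked behaviour.

## Synthetic scenes

The generator emulates the structure the analysis assumes, not a
radiometric simulation: per-band surface reflectance is a linear mixture
of three endmembers (dense shrub, bright saline soil, water) plus Gaussian
noise (default sd 0.005), with the soil endmember brightening with
salinity so the salinity inversion has signal. The vegetation-abundance
field is smoothed noise rank-mapped so that the configured share of pixels
clears the NDVI > 0.3 dark-pixel threshold with a small safety margin; the
water body hugs the sea edge at an exact quantile fraction. Defaults
portray a ~1.3 km coastal reserve strip at 10 m pixels: salinity 0.5–30
g/kg rising land→sea (sea = north by default; the gradient direction is
configurable since only its existence, not its axis, is a property of such
sites), AOD base 0.95 ± 0.45 (range 0.50–1.40, matching the span reported
for tamarisk forest sites), LST 24.5–30.2 °C with dense vegetation coolest
and water at the minimum, 45 % vegetated and 10 % water pixels.

Two stages are exactly invertible by construction: the thermal radiance is
the Planck forward model of the truth LST under the configured
(ε, τ, L↑, L↓, K1, K2), so the LST stage recovers truth to machine
precision; and the aerosol-sensor TOA red/blue bands are the lookup-table
forward model of the truth AOD at fixed viewing geometry, with dark-pixel
surface red/blue built at exactly the ratio k — the DDV assumption made
literal. With truth AOD snapped to the candidate grid and zero band noise,
retrieval is therefore exact at every dark pixel; with off-grid truth the
error is bounded by half the candidate spacing on a smooth LUT.

What the generator does **not** emulate: sensor point-spread functions,
topography, clouds, gas absorption, mixed-pixel adjacency effects,
radiometric calibration error, or realistic spectral covariance between
soil chemistry and moisture. Passing tests therefore demonstrate the
correctness of the algorithms under their own assumptions, not retrieval
accuracy on real imagery.

## Problem sizes and determinism

Default test scenes are 128×128 pixels (the two-date end-to-end checks use
48×48), sizes at which every property asserted is stable across seeds; the
acceptance script regenerates its scenes at 128×128 from the seed it is
given. All randomness descends from explicit integer seeds
(`numpy.random.default_rng`); the pipeline derives per-stage seeds from
the single top-level seed via CRC-tagged `SeedSequence`, so reruns with
the same configuration produce byte-identical outputs.

## Known limitations

- The salinity models are fitted on 10 training points, mirroring the
  campaign design; with so few samples the regression generalises poorly
  (the published hold-out relative errors reach 99 %) and the BP network's
  advantage is on fit, not guaranteed on hold-out RMSE.
- Relative error against the inverted value explodes when inversions are
  near zero; it is reported because it is the established convention for
  this validation table, with RMSE as the steadier companion statistic.
- The published lookup-table sample rows cover the red band only; blue-band
  coefficients for the published-row fixture come from the synthetic model,
  and stamping real rows onto a synthetic grid can make the red/blue
  coefficient ratio non-monotone in tau between nodes.
- Grading requires RSEI in [0, 1] and will refuse un-rescaled scores.
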