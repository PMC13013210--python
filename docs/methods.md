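# Methods

## The index and its classification

The Summer Simmer Index maps air temperature `Ta` (°F) and relative
humidity `Ur` (%) to a perceived temperature on the Fahrenheit scale:

```
SSI = a · [ Ta − (b − c·Ur)(Ta − pivot) ] − offset
      a = 1.98,  b = 0.55,  c = 0.0055 /%,  pivot = 58 °F,  offset = 56.83
```

The constants live in `FormulaConstants` and are injected into every
computation rather than inlined, so tests can verify the frozen
defaults and researchers can experiment with recalibrated variants.
Analytic properties the implementation (and the test suite) rely on:

- ∂SSI/∂Ta = a·(1 − b + c·Ur) > 0 — strictly increasing in temperature;
- ∂SSI/∂Ur = a·c·(Ta − pivot) — humidity amplifies heat above 58 °F,
  damps it below, and has no effect at the pivot;
- at Ur = 100 % the humidity coefficient vanishes and SSI = a·Ta − offset.

Classification uses half-open `[lower, upper)` intervals with
breakpoints 70, 77, 83, 91, 100, 112, 125, 150 °F. Two policy choices
the interval table leaves open are fixed explicitly:

- **Below 70 °F** — interpolated highland or shoulder-season pixels
  legitimately fall below the table's first bound, so an explicit
  code-0 "Below scale" category covers (−∞, 70) instead of raising.
- **Exactly 150 °F** — the printed table is ambiguous at 150; the top
  category's lower bound is closed, so 150 classifies as Deadly Hot.

Two interval pairs share the labels "Cold" and "Extremely Hot"; all
eight intervals keep distinct codes. A six-label legend
(Cold/Cool/Comfortable/Warm/Hot/So Hot) relabels the same intervals for
exposure summaries; the interval→label mapping is not standardized, so
the package default (0-1→Cold, 2→Cool, 3→Comfortable, 4→Warm, 5→Hot,
6-8→So Hot) is configurable through the scheme JSON.

Classification always operates on the Fahrenheit-scale value. A
Celsius display unit applies the ordinary affine °F→°C map to the index
number itself — a display convention only, with no physical meaning.

## Raster model

Grids are single-band, north-up, axis-aligned rasters with a GDAL-style
6-tuple geotransform; rotation terms are rejected. GeoTIFF I/O writes
ModelPixelScale, ModelTiepoint, a minimal GeoKeyDirectory with a CRS
citation string, and the GDAL_NODATA tag, so outputs open in standard
GIS software. The CRS is treated as an opaque identifier: inputs must
already share a CRS, and misaligned rasters are an error rather than an
implicit resample (silent warping would corrupt humidity extremes).
Alignment tolerance is 1e-6 of a pixel per geotransform component.

Nodata conventions: −9999 for float rasters, 255 for categorical ones,
both recorded in the file tags. Nodata in either input propagates to
the output cell. Humidity outside [0, 100] on valid cells is a
validation error reporting the offending cell count; a `clamp_rh`
override clips instead, for noisy rasters and for interpolated
surfaces that overshoot the physical range.

SSI rasters are stored float32 and computed float64 internally.
Interpolated surfaces and SSI grids are quantized to float32 at
operation boundaries — the storage dtype — which is what makes the
file-based CLI pipeline bit-identical to the in-process one, a property
the test suite asserts.

Area shares use exact cell counts times cell area. For geographic
(lon/lat) rasters, cell areas are weighted by cos(latitude) per row —
sufficient at city scale; full ellipsoidal cell areas are not computed,
which overstates areas by < 0.1 % over a 1° extent.

## Interpolation: regression-kriging with an elevation drift

Station observations are turned into continuous surfaces in two
stages:

1. **Drift.** Ordinary least squares of value on elevation. For
   temperature the slope is the lapse rate (≈ −6.5 °C/km in the
   standard atmosphere); for humidity the elevation trend is weaker but
   usually present, and the drift is on by default for both fields
   (disable with `use_elevation_drift=False`). The fit requires ≥ 3
   stations with non-constant elevation.
2. **Residual kriging.** The Matheron estimator bins squared residual
   differences into 12 lags out to half the station-domain diagonal
   (empty bins are kept, flagged NaN). A variogram model — exponential
   by default; spherical and gaussian available — is fitted by least
   squares weighted by pair counts, with nonnegativity enforced by
   bounded optimisation. `range_param` is the correlation length of
   the exponential/gaussian forms and the exact range of the spherical
   form; γ(0) = 0 by convention, so a zero-nugget model interpolates
   exactly at stations. Ordinary kriging then solves the
   (n+1)-equation system with a Lagrange multiplier over the 16 nearest
   stations (a single global solve when the network is that small);
   solves are batched across all target cells.

Choosing regression-kriging over cokriging is deliberate: cokriging
needs a modeled cross-covariance between the field and elevation,
which is rarely estimable from typical station networks, while
regression-kriging uses the covariate for the same purpose — borrowing
topographic structure where stations are sparse — and is fully
specifiable. The covariate-benefit property (regression-kriging RMSE ≤
drift-free ordinary kriging RMSE on terrain with a real lapse rate) is
asserted in the tests.

Distances are planar in the working CRS; geographic inputs are
rejected rather than silently mistreated. Duplicate station
coordinates are averaged into one record with a warning. A
leave-one-out routine exists for diagnostics; no cross-validation UI is
provided.

## Exposure

Zones are population-bearing polygons in the raster CRS. Cell
membership uses a cell-center-in-polygon test (deterministic and fast;
at coarse resolutions boundary cells can flip relative to exact
clipping — the documented accuracy caveat). Each zone's population is
spread uniformly within the zone and split across comfort classes in
proportion to covered valid-cell area (areal weighting — the standard
assumption absent dasymetric data). Integer person counts come from
largest-remainder rounding with ties broken by ascending category
code, so each zone's counts sum exactly to its population and tables
are reproducible bit-for-bit. Zones with no valid raster coverage go
wholly to an "Unclassified" bucket (code −1). Area percentages are
computed over the union of zone footprints; population percentages
over the summed populations; both columns sum to 100.

## Synthetic scenario

The generator builds a miniature Mediterranean-like coastal city: a
DEM rising from a southern plain to northern highlands (power-law
gradient plus band-limited noise), temperature linear in elevation with
a configurable lapse rate, humidity decreasing with elevation, and
spatially correlated residual fields. Defaults — 120×120 cells at
250 m, sea-level temperature 32 °C, lapse rate −6.5 °C/km, humidity
75 % at the coast falling at 2.2 %/100 m (spanning roughly 40–80 %
across the relief, a realistic coastal-to-highland contrast), residual
σ 0.5 °C / 2 % with a 5 km correlation length, 60 stations, 16 zones,
1.2 M residents concentrated at low elevation (zone weights
∝ exp(−elevation/300 m)) — are the study conditions for all recovery
and conservation tests. The 250 m default keeps the full pipeline
under two seconds; operational 30 m resolutions are a configuration
value, not a default.

Correlated residuals are synthesised spectrally: white noise filtered
by the square root of the circulant-embedded power spectrum of an
exponential correlogram, then recentred and rescaled to the target
standard deviation. The exponential correlogram matches the
interpolation module's default variogram, so parameter recovery is
well-posed. All randomness flows through one `numpy` Generator seeded
by a single integer; identical seeds give bit-identical bundles, with
no time-based entropy anywhere.

What the synthetic world does *not* emulate: urban heat-island
morphology, coastal sea-breeze effects, anisotropic terrain
correlation, non-uniform within-zone population density, and
observation error at stations (stations sample the truth field
exactly; measurement noise would add a nugget). Passing tests
therefore demonstrate the correctness of the machinery — formula, map
algebra, kriging solver, apportionment arithmetic — under a known
truth, not the climatological fidelity of any particular city's maps.

## Numerical choices

- float64 arithmetic throughout; float32 only as the raster storage
  dtype, applied at operation boundaries.
- Variogram fit initialisation: sill from the mean of the last third of
  non-empty bins, range from a third of the largest lag; bounded
  least squares (`scipy.optimize.least_squares`, xtol = ftol = 1e-12).
- All-zero semivariances short-circuit to a pure-drift model (nugget
  and partial sill 0) instead of invoking the optimiser.
- Kriging at a duplicate-free station set is always solvable; duplicate
  coordinates raise with the offending locations named.
- Classification uses `numpy.digitize` on the scheme's interior
  breakpoints, which implements the left-closed/right-open convention
  exactly at boundary values.
- Largest-remainder ties break by ascending category code.

## Known limitations

- No reprojection or resampling; co-registration is the caller's job.
- No anisotropic variograms or full cokriging.
- Cell-center zone membership, not exact polygon clipping.
- The six-label legend mapping is a convention, not a standard.
- Geographic-CRS area weighting is the cos-latitude approximation.
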