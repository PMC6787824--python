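# Methods

This note documents the models and rules `seaseg` implements, the defaults it
ships, the numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Solar ephemeris

All twilight and day/night logic rests on a low-precision solar position:
geometric mean longitude and anomaly with the equation of centre, apparent
obliquity, and the classical equation-of-time series (the algorithm used by
the NOAA solar calculator). Accuracy is well under 0.05° in declination and
0.1 min in the equation of time — negligible against the ~186 km error class
of threshold geolocation. All times are UTC; local apparent time is derived,
never stored. The Earth is spherical with R = 6371 km throughout, including
the Lambert azimuthal equal-area projection.

## Threshold geolocation

**Twilight detection.** Light is clipped to [0, 64] and a crossing of
threshold 20 (configurable) defines sunrise (upward) and sunset (downward),
linearly interpolated between samples. Because loggers sample every 60 s and
store the *maximum* per 5/10-min bin stamped at the bin start, rising light is
effectively sampled at the last 60-s sample of the bin; sunrise crossings are
shifted late by (interval − 60 s) to remove the resulting bias (~1.25° of
longitude if uncorrected). Events with another crossing within a 30-min guard
window are flagged as interference — a reproducible stand-in for the visual
curve inspection used historically — and dropped before inversion.

**Calibration.** The effective sun elevation angle is grid-searched over
[−9°, 0°] in 0.05° steps to minimise the median great-circle distance between
inverted positions and a known site over a ≥5-day calibration window; values
outside the empirically usual [−6°, −3°] band warn but do not fail.

**Inversion.** Each alternating twilight pair yields one position: longitude
from the requirement that apparent local time at the pair midpoint be noon
(sunrise→sunset pairs) or midnight (sunset→sunrise), corrected by the
equation of time; latitude by inverting the day-length equation
`cos H₀ = (sin a − sin φ sin δ)/(cos φ cos δ)`. The inversion scans a 1°
latitude grid from the equator outward for a sign change and bisects it to
0.01° — day length is not monotone in latitude near the polar-night limit,
so plain endpoint bisection can miss the root. Pairs spanning less than 2 h
or more than 22 h are discarded as mispairings (an event was lost between
them). Near the equinoxes (|δ| < 1.5°) both hemispheres solve; the branch
nearer the closest unambiguous latitude is kept and flagged.

**Filtering and smoothing.** Latitudes within ±20 days of either equinox are
masked (longitudes kept — they are unaffected); positions implying sustained
speed above 35 km/h to both neighbours are dropped, as are positions whose
longitude departs from a 7-point rolling median by more than 15° (badly
shaded twilights evade the speed filter when latitude is masked). Smoothing
is two passes of 1-2-1 weighting on longitude and latitude separately,
endpoints fixed, gaps over 3 days not bridged, longitudes unwrapped first so
the antimeridian is safe.

## Migration phenology

A cycle runs 1 July – 30 June so austral wintering stays within one cycle.
The rules replace a visual procedure and are deliberately explicit:

- **Departure**: the first day farther than 500 km (config) from the median
  of the previous 10 days, *remaining outside that radius for the following
  two days*, with net displacement over those two days above 200 km/day. The
  stay-out requirement is part of the rule: at the ~186 km position error a
  single-day excursion beyond 500 km is routine, and without it roughly a
  third of noisy replicates trigger weeks early.
- **Arrival**: the first day that itself lies within 500 km of the median of
  the next 10 days while at most one of those days strays beyond — again one
  tolerated outlier is what makes the rule robust at realistic noise without
  moving the clean-track answer by more than a day.
- Inside equinox masks both rules run on longitude alone, converted to km at
  the latitude of the nearest resolved fix.
- **Colony arrival**: the first night (sunset→sunrise, using the calibrated
  sun angle) with zero wet counts in every 10-min bin; a single wet bin
  rejects the night. Truncated first/last nights are skipped.
- **Residency**: a bird is nonmigratory when its wintering centroid sits
  within 1000 km (strict inequality at the boundary) of the colony; for such
  birds only the colony-arrival date is reported.

Recovery under the study conditions: events exact to ±1 day on clean tracks;
at the 186-km error level, departure and wintering arrival fall within ±3
days of truth in ≥95% of replicates across generator seeds.

## Kernel space use

Positions are projected with a spherical LAEA projection centred on the data
centroid (antimeridian-crossing sets are recentred first), binned on a 25-km
grid and smoothed with a fixed Gaussian kernel of σ = 186 km — the bandwidth
is metric, resolving the "~2°, depending on latitude" convention in favour of
exactness. The grid extends 3 bandwidths beyond the data. Contour levels are
density thresholds enclosing 50%/95% of mass; areas and overlaps are computed
on the raster masks (cell = bandwidth/7.4, so discretisation error is far
below the 5% tolerance of the analytic checks), polygons are exported to
GeoJSON via marching squares. With these choices the 50% area of an n→∞
Gaussian cloud converges to `2π·ln2·(σ² + h²)`; the implementation matches
within 0.5% at n = 5000. The centroid of a multi-polygon 50% contour is the
geometric centroid of the polygon holding the most positions (days). Overlap
re-evaluates both point sets on one shared grid and reports
`area(A∩B)/area(A)` and `/area(B)`. The bundled nonbreeding-area catalog
(seven named Atlantic polygons) is schematic — synthetic boundaries for
plumbing, swappable via GeoJSON; assignment falls back to the nearest polygon
with a warning, ties breaking by catalog order.

## Night flight index

Flying is read as dry: a bin contributes its dry fraction `(200 − wet)/200`
of time flying, so partial bins count fractionally rather than by
thresholding (a documented choice; a 0/200 threshold variant changes NFI by
< 0.02 under the generator's behaviour model). Dark means the sun below the
calibrated twilight angle at the bird's position — the same darkness
definition as the geolocation chain, not civil twilight. Daily
`NFI = (p_fly_dark − p_fly_light)/max(·,·)` ∈ [−1, 1]; the per-bird summary
averages daily NFI over the first complete 28-day window anchored at a new
moon (synodic period 29.530588 d, anchor 2000-01-06 18:14 UTC) that fits
inside the wintering period with full coverage. Anchor and window length are
configuration.

## Isotopic niche

`SEA = π·√(λ₁λ₂)` from the sample covariance of (δ¹³C, δ¹⁵N);
`SEAc = SEA·(n−1)/(n−2)`. Groups need n ≥ 4. The Bayesian SEAb draws
covariances directly from the conjugate normal–inverse-Wishart posterior —
prior df 3, prior scale `diag(sample variances)·10⁻³` (near-flat, keeps the
posterior proper at small n), mean-update term vanishing at the sample mean —
so no MCMC is needed and draws are exactly reproducible from a seed.
`P(area_A < area_B)` is the fraction of paired draws. Note its sampling
behaviour: the posterior concentrates on each group's *sample* covariance,
so for two groups from the same distribution the probability is near-uniform
across data draws and centres on 0.5 only on average over replicates —
single-draw values far from 0.5 are expected at field sample sizes.
Measurement error (0.2‰ C, 0.3‰ N) is a generator parameter, not deconvolved
in estimation.

## Comparative statistics

SSI is `(m − f)/(0.5(m + f))·100`. The bill PCA is on the covariance (not
correlation) of culmen, head+bill, and the two bill depths — all in mm, so
PC1 stays interpretable as size; PC1 is oriented positive-with-size. The χ²
test is uncorrected Pearson (the published worked values match only without
continuity correction) with df = (r−1)(c−1) and a low-expected-count warning.
Area merging uses Welch's t with Satterthwaite df on each element; two areas
merge only when both δ¹³C and δ¹⁵N are indistinguishable (p > 0.05 each).
Mixed-effects modelling is deliberately out of scope: the pipeline emits tidy
per-bird tables ready for any external LMM fit.

## Synthetic data generator

The generator is the package's statement of the study conditions, not a test
dial. Defaults: five real colony coordinates with Veneguera as the default
site; 10 birds per sex; female departure centred on cycle day 130 (~7 Nov,
SD 4 d) with males 4 d earlier, colony return day 245 (~3 Mar) with males
3 d earlier; transit at 600 km/d along the great circle; wintering wander SD
120 km (males) vs 180 km (females) so the female core area is larger;
sex-structured area choice (only males use the North Atlantic, females
favour the Brazil Current); light as a linear ramp in sun elevation crossing
the threshold exactly at the configured twilight angle, max-per-interval
recorded, optional shading (a 10–20-min zero span per affected twilight) and
clock jitter; immersion from a persistent two-state fly/sit process
(refresh probability 0.2 per 10-min bin) with night flight probability 0.32
(males) vs 0.42 (females) and 0.50 by day; isotopes as area baselines plus a
male offset of +0.2‰ δ¹³C and +0.5‰ δ¹⁵N (the magnitude of the published
sex contrast) with 0.5–0.6‰ individual and 0.2/0.3‰ instrument noise;
biometrics from a shared size factor (CV 2.5%) with per-variable SSI targets
of 3.5–13%. Position-level noise with a 186-km mean radial error (per-axis
σ = 186/√(π/2) km) emulates geolocation error for tests that do not need the
full light chain.

What the generator does *not* emulate: real oceanography or habitat,
foraging-driven movement dynamics (the movement is a kinematic sketch — the
analysis consumes positions, not dynamics), weather-dependent shading,
individual repeatability across years, or age structure. Passing recovery
tests therefore show the estimators are correct under the stated error
model, not that real data meet that model.

## Problem sizes and determinism

Default analyses run at desk scale: 20-bird campaigns, 40-day calibration
runs, 100-replicate noise studies, 1000–4000 posterior draws — sizes chosen
so the full suite and the acceptance script each complete in a few minutes
while keeping Monte-Carlo error well inside the stated tolerances. Every
stochastic routine takes an explicit seed or Generator; pipeline outputs are
byte-identical under a repeated seed.

## Known limitations

- The interference guard window and the phenology cluster radii replace
  irreproducible visual procedures; they are documented config, not inferred
  intent.
- Latitude near the equinoxes is unidentifiable by design; longitude-only
  phenology rules cover the gap but lose the meridional component.
- The Scopoli's-type 2×3 contingency worked example reports df = 2 (the
  mathematical value for a 2×3 table); published df = 3 for the same counts
  would require an additional unprinted category.
- The area catalog is schematic; real analyses should supply oceanographic
  boundaries.
- No state-space or curve-fit geolocation refinements; the threshold method
  is the model.
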