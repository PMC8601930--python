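# Methods

This note documents the conventions, models and design choices behind the
pipeline, in the order the data flow through it.

## Detection events

Photos arrive as labeled rows (camera, ISO-8601 timestamp with UTC offset,
species). Rows for non-target species are ignored. Within one camera,
photos are collapsed into independent detection events by a **chaining
rule** with gap parameter `gap_minutes` (default 5): a photo joins the
current event iff its timestamp is at most the gap after the *previous*
photo of that event. The phrase "within 5 minutes of one another" is
ambiguous between this rule and a window anchored at the first photo; we
adopt chaining because it matches the common camera-trap notion of an
independent event (an animal lingering in front of the camera, triggering
every few minutes, stays one event) and the alternative is one config flag
away (`gap_minutes` applies to either reading of the data). Events are
timed at their first photo. Collapsing partitions the photos (event photo
counts sum to the photo count) and is idempotent on event start times; both
properties are tested.

## Time handling

All analysis clocks use one fixed local UTC offset from the run config
(default −360 min, CST). Input timestamps may carry any offset — e.g.
recorded across the November daylight-saving transition — and are
reconciled through UTC, then expressed in the fixed offset. This avoids the
double/skipped local hour at DST transitions at the cost of a one-hour
clock shift relative to wall clocks during the daylight-saving part of the
study window; since classification boundaries and event times shift
together, diel classes are unaffected.

## Solar anchors and diel classification

Sunrise and sunset come from the NOAA solar-calculator equations: Julian
centuries from J2000, geometric mean longitude and anomaly, equation of
center, apparent longitude with the nutation correction, mean obliquity
polynomial; the equation of time and declination feed the hour-angle
formula at zenith **90.833°** (refraction 34′ + solar semidiameter 16′).
Event times are refined by three fixed-point passes (the equation of time
is re-evaluated at the current event estimate). Agreement with an
independently implemented ephemeris (Astronomical Almanac low-precision
position + minute-grid elevation crossing, in the test suite) is better
than 0.1 min over 1950–2100 for |latitude| < 60°. Polar-circle latitudes
(≥ 66°) are rejected.

Classification uses the **monthly anchor convention**: every event in
calendar month *m* is compared against the *clock times* of sunrise/sunset
on the 15th of *m* at the camera's site, so the day/night boundary is
constant within a month and tracks daylength between months. Per-date
classification is available behind an off-by-default flag. Boundaries are
half-open: an event exactly at anchor sunrise is DAY, exactly at anchor
sunset is NIGHT, so every instant classifies exactly once. Anchor times are
kept at full precision internally and rounded to whole minutes only for
display.

**Minutes after sunset** (the nocturnal-timing response) is measured from
the governing sunset: events between sunset and midnight use the same
evening's anchor sunset; events between midnight and sunrise use the
previous evening's (i.e. 1440 − sunset + clock). Whether after-midnight
detections should anchor to the previous evening is a genuine convention
choice; we adopt it because the alternative (negative or >1000-min values)
has no ecological reading, and observed site means up to ~394 min are
consistent with it.

## Landscape covariates

Rasters are ESRI ASCII grids in a projected plane (meters). Camera
coordinates are geographic; they are mapped into the raster plane by a
local equirectangular projection about the downtown anchor (sub-0.3% error
at the <70 km scale of the study; no datum transforms are attempted).

* `forest_ha_500m`, `developed_ha_500m` — area of the configured landcover
  class codes within `buffer_radius_m` (default 500 m) of the camera,
  counted by **cell-center-in-circle** membership (not fractional-area
  weighting); exactly reproducible by brute-force enumeration, which the
  tests do. The legend (which codes are "forest", "developed/pavement") is
  a config mapping, never hard-coded.
* `dist_downtown_km` — great-circle (haversine, R = 6371 km) distance to
  the population-center anchor (36.066166, −94.157889). At these distances
  the difference from projected Euclidean distance is negligible.
* `sound_L50_db` — the anthropogenic L50 sound raster value of the cell
  containing the camera (half-open cell-edge convention; nodata → NaN).

## Diurnality GLMM

Response: indicator that a detection event is diurnal. Fixed effects:
forest area, developed area, month (6 levels October–March, October
reference), distance, sound; random effect: site intercept
u ~ N(0, σ²) on the log-odds scale.

The marginal likelihood integrates u out per site by **adaptive
Gauss–Hermite quadrature**: for each site the integrand's mode is found by
damped Newton steps and its curvature rescales the Hermite node grid
(15 nodes by default; the fitted log-likelihood changes by <1e−4 between 7
and 31 nodes on study-scale data). (β, σ) are maximized jointly by
L-BFGS-B with σ bounded at zero; at σ = 0 the likelihood reduces exactly to
plain logistic regression, which is enforced as a test oracle
(statsmodels `Logit`, and R `lme4::glmer` with `nAGQ = 15` as an external
cross-check — agreement to ~1e−4 on coefficients, SEs and log-likelihood).
Starting values are the GLM estimates with σ₀ = 0.5; under (quasi-)
separation the start falls back to a weakly ridge-penalized fit and the
result is flagged. Convergence requires optimizer success or gradient norm
< 1e−3; otherwise a diagnostic error carries the gradient norm.

Standard errors come from the numerically differentiated Hessian of the
marginal log-likelihood (β-block only when σ̂ sits on the zero boundary,
where the σ direction is one-sided). Wald tests mirror mixed-model
software: per continuous term F = (β̂/se)² with (1, n − rank) df; the month
factor gets a joint 5-df Wald F from the covariance block. Denominator
df = n − rank is a convention choice (no Satterthwaite/Kenward-Roger
correction). Continuous predictors can be standardized, off by default —
the reported coefficient scales are raw units (ha, km, dB).

Population-level predicted-probability curves are the inverse logit of the
linear predictor at the sample means of the other columns (random intercept
at zero), with 95% Wald intervals by the delta method on the linear scale.

## Nocturnal timing model

OLS of minutes-after-sunset on landscape covariates, nocturnal events only
(no site effect — the model is a plain general linear model). Estimates
are checked against the closed-form normal equations to 1e−8; the overall
F's type-I error rate under pure noise is verified at ~5%. Rank-deficient
designs fail with the aliased columns named.

## Synthetic studies

The generator emits everything the pipeline reads — deployments, photo
bursts, landcover and sound rasters — for a configurable multi-site winter
study (October 2020–March 2021). Defaults mirror the 10-site study design:
per-site camera counts, trap nights, expected detections and diurnal
counts, distance and sound covariates, and nocturnal timing means.

* **Geography.** Sites sit along a west–east corridor at exactly their
  configured great-circle distance from the downtown anchor, offset into
  three parallel 1.5-km bands so neighbouring sites' raster neighbourhoods
  never collide; cameras are spaced 160 m with small jitter. One compact
  landcover grid (30 m) and one sound grid (250 m) cover the corridor.
* **Landcover.** Around each site's cameras, cells become forest/developed
  with densities `forest_ha_mean / 78.54` and `developed_ha_mean / 78.54`
  (78.54 ha = the full 500-m buffer), painted once per site from a single
  random field, so the *expected* extracted buffer areas equal the
  configured hectares. The sound raster carries each site's dB exactly at
  its cameras' cells. Per-site forest/developed values are not published;
  the defaults are plausible values on the urban–rural gradient (remote
  sites ~70–74 ha forest, <1 ha developed; urban sites ~35–45 ha forest,
  18–25 ha developed).
* **Counts.** Per camera, detections are Poisson with mean
  `expected_detections / n_cameras`; deployment windows split the site's
  trap nights across cameras, staggered so all six months are sampled.
* **Diel classes.** Each detection is diurnal with probability
  `invlogit(β·x + month effect + u_site)`, where **x is the camera's
  realized covariate vector** (forest/developed measured on the generated
  raster, distance from the camera's coordinates) — the generating model is
  exactly the model the analysis fits, so parameter recovery is a clean
  check of the estimator. Default coefficients: distance +0.08/km, sound
  −0.408/dB, forest −0.032/ha, developed +0.14/ha; month effects rise
  monotonically (0, 0.2, 0.5, 0.8, 1.0, 1.2) from October to March,
  matching the observed mid-winter increase in diurnality; σ_site = 0.5.
  The intercept (−1.639) was calibrated once so that the model-implied
  expected diurnal count over the design equals the study total of 270.
* **Event times.** Diurnal times are uniform between the monthly anchor
  sunrise and sunset. Nocturnal times are the anchor sunset plus a
  truncated-Normal offset on [0, night length − 10 min] whose *truncated*
  mean equals the site's configured timing mean (location solved
  numerically per month) — the configured value is interpreted as the
  observable mean of recorded times, which are necessarily bounded by the
  night. Published timing sds exist for two sites (84 and 246 min); the
  others default to 0.6 × mean, the ratio those two show.
* **Fixed-counts mode** replaces the stochastic draws of counts and
  classes with deterministic ones reproducing the configured per-site
  detection and diurnal counts exactly (diurnal events spread evenly
  through the sequence, dates spread evenly through each camera's window,
  timing offsets as stratified quantiles), giving the round-trip fixture
  used by the descriptive tests.
* **Reproducibility.** Each site draws from RNG streams derived from the
  master seed and the site index, so adding or removing sites does not
  perturb the other sites' draws; identical config + seed yields
  byte-identical output files.

What the generator does **not** emulate: animal movement and home ranges
(detections are independent given the rates), camera detection-distance
physics, weather, within-night activity structure beyond the
truncated-Normal, or real Landsat/sound-model rasters (landcover is an
uncorrelated random scatter at the right density, without spatial patch
structure). Passing tests therefore demonstrate that the *estimators and
plumbing* behave correctly under the study's design and assumed model, not
that the model is right for real armadillos.

## Problem sizes and statistical checks

The replicate-recovery check fits the GLMM to 50 synthetic studies at the
full design scale (~1209 events, 10 sites) through the complete pipeline
and compares the replicate-mean distance and sound coefficients with the
generating values within two Monte-Carlo standard errors. With 10 sites
and strongly correlated site-level covariates (the realistic situation:
development, sound and proximity to town co-vary, |r| ≈ 0.9) the sound and
developed coefficients are individually noisy (replicate sd ≈ 0.2) and the
site-variance MLE frequently sits on the zero boundary — both honest
small-sample properties of the design, visible in `lme4` as well. The
nocturnal-timing round trip regenerates the most delayed site (mean 394,
sd 246, n ≈ 347) and recovers its mean through the solar/ingest modules
within two standard errors.

## Known limitations

* The monthly-anchor convention makes the diel boundary discontinuous at
  month changes (by design, following the study's definition).
* Conditional coefficients in the 3-term timing model are sign-unstable
  under the covariate collinearity of the default design; the distance
  effect should be read marginally.
* Buffer areas ignore fractional cell coverage; at 30-m cells inside a
  500-m buffer the discretization error is ≤ ~1 ha.
* No occupancy/detection-probability modelling, no autocorrelation of
  repeat visits, no model selection — matching the scope of the original
  analysis.
* Wald-z intervals undercover at the 10-site design (~80–92% observed
  instead of 95%): the site-variance MLE frequently hits the zero boundary,
  and with ~10 clusters a z critical value is too small (the z-vs-t
  effect under the df = n − rank convention). Interval coverage is nominal
  once the number of sites grows (~40 clusters in the test suite); at study
  scale, site-level inferences should be read with this in mind.
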