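# Methods

This note documents the models and procedures implemented in `herdtrack`,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate about real collar data.

## Processing model

A collar's raw stream is a sequence of (id, herd, species, UTC time,
lat, lon) fixes at a nominal 30-min cadence with stochastic losses. The
analysis unit is the **collar-day**, the half-open UTC interval
[00:00, 24:00): a fix at exactly midnight belongs to the day it begins.
Timestamps are stored in UTC throughout; a `tz_policy` option at ingest
converts local-time inputs once, because both the daily partition and the
solar geometry require a single time convention.

Processing order is fixed: (1) day-level QC → (2) raw-track implausibility
filter → (3) resampling to the standardized grid → (4) smoothing →
(5) indicators. The implausibility metrics (daily path, maximum step) are
deliberately computed on the **raw** fixes, before any interpolation can
dilute a spurious jump.

### Quality control

A collar-day is dropped when it has fewer than 10 messages or when more
than 12 consecutive hours pass between two transmissions. All four QC
thresholds (10 messages, 12 h gap, 10 km/day, 4 km/step) are strict
inequalities: boundary values pass. Two modelling decisions here were
genuinely open and are worth stating:

* Gaps from midnight to the first fix (or last fix to midnight) do not
  count toward the 12 h rule — the rule concerns silence *between*
  transmissions, and a day whose first fix arrives late is already policed
  by the message count.
* The audit reports retention both as a fraction of fixes and as a fraction
  of collar-days, since a deletion percentage can be bookkept either way;
  both appear in `audit.attrs`.

### Trajectories

Each surviving day is resampled to 48 slots (00:00, 00:30, …, 23:30).
Grid instants inside the observed span are linearly interpolated in
latitude and longitude between the bracketing fixes; instants outside it
hold the nearest observed position and carry an `imputed` flag. Operating
on degrees directly is justified at the study scale (tens of km, mid
latitudes, far from the antimeridian); all *distances* are nevertheless
great-circle (haversine, R = 6,371,000 m).

Smoothing is a Savitzky–Golay filter of polynomial order 3 and window 5,
applied independently to the latitude and longitude series. Interior
values are the central value of the local least-squares cubic (impulse
response (−3, 12, 17, 12, −3)/35); the first and last two slots come from a
one-sided cubic fitted to the edge-most five points, so the day keeps its
full length. The filter is exact on cubics, which the tests verify to
machine precision.

Velocities use the nominal 1800 s slot interval — after standardization
the interval is constant by construction. Two "daily distance" readings
coexist in the field: the summed path length and the midnight-to-midnight
straight line (net displacement). Both are computed; `path_km` is the
headline daily distance used in summaries, because reported per-day travel
magnitudes for grazing livestock correspond to path length on smoothed
tracks. Whether daily distance should be measured on smoothed or raw
resampled positions is equally ambiguous in practice; the pipeline
defaults to smoothed with a `smooth=False` escape hatch.

### Behavior classification

The average velocity between consecutive standardized fixes indexes
behavior: low = resting (including rumination), medium = grazing,
high = walking. Cut points are the 57.5th and 97.5th empirical percentiles
of the velocity distribution (linear-interpolation quantile definition,
the convention of the major statistical environments) — the split under
which cattle allocate 57.5/40/2.5 % of time to the three states.
Classifying the calibration sample with its own thresholds therefore
returns those fractions to within 1/n; this *self-calibration identity* is
the central invariant of the method and is what the acceptance script
recomputes.

Because species differ in speed and slope slows travel, thresholds are
refitted per (species × slope-bin) stratum, with slope bins <10°, 10–20°,
>20° and a species-pooled fallback for strata under 100 observations (and
for fixes without terrain). This stratified-percentile design is one
admissible reading of "the same percentile, adjusted for the speed of each
species and the slope of the terrain"; the adjustment is configurable and
flagged as a design choice, not a ground truth. Ties at a threshold take
the lower-activity state (deterministic and conservative). Thresholds are
always fitted on the analyzed dataset at run time, never shipped as
constants.

### Home range and dispersal

Daily home range is the 95 % minimum convex polygon: points whose
haversine distance to the arithmetic-mean centroid exceeds the 95th
percentile of those distances are removed, the rest are projected onto a
local tangent plane (equirectangular, centered on the centroid — distortion
< 0.1 % at ≤ 10 km extents, which spares a projection dependency), and the
convex-hull shoelace area is reported in hectares. Percentile removal (not
iterative peeling) matches the documented behavior of the classic
home-range estimators. Days with fewer than 5 points, or all points
coincident, are degenerate (area 0, flagged). Edge-held (imputed) slots
are excluded by default from both MCP and dispersal, because a held
position fabricates a zero-movement cluster; this is configurable since
the original convention is unstated.

Herd dispersal requires synchronized fixes, which is exactly what the
standardized grid provides: at each slot with ≥ 2 herd members, each
animal's haversine distance to the arithmetic-mean centroid is one
dispersal record.

### Diel partition

Sun elevation comes from the NOAA low-accuracy ephemeris approximation
(Fourier declination and equation of time), accurate well inside the 0.5°
needed here. Daylight is elevation > −0.833° (refraction + solar radius,
the civil sunrise/sunset convention, chosen because "sunrise/sunset" is
otherwise numerically undefined); night is elevation ≤ −12° (nautical
boundary); twilight is the band between. Each 30-min step accrues its
length to the class of its **midpoint** instant at its midpoint position —
midpoint, not endpoint, so steps straddling a boundary are assigned
without bias. A day's partition is each class's share of total path,
in percent; zero-path days are flagged undefined. Civil twilight is
available through `SolarConfig` but not used in the default partition.

## Synthetic data: what it emulates

The simulator generates the statistical structure the analysis assumes,
with every default chosen once to represent a desk-scale slice of a
mountain grazing season (two herds per species × 10 collars × 30 days from
June 1st, ~42.4° N):

* **States and speeds.** A time-inhomogeneous Markov chain over
  resting/grazing/walking: at each slot the state persists with
  probability 0.5 or resamples from the hour's target distribution. The
  target grazing probability is a 0.30 baseline plus two Gaussian bumps
  (amplitude 0.32, width 1.5 h) at 07:00 and 17:00 UTC — morning and
  late-afternoon grazing peaks — and walking is a constant 0.025, which
  makes the time-averaged mix ≈ 57.5/40/2.5, the split the classifier is
  calibrated to. The low persistence keeps the realized diel profile's
  peaks within half a slot of the configured hours.
* **Speeds.** Characteristic speeds (m/s) resting/grazing/walking:
  bovine 0.005/0.030/0.150, equine 0.005/0.026/0.130, ovine
  0.006/0.055/0.250, each multiplied per slot by a unit-mean lognormal
  (σ = 0.35). These yield daily paths of roughly 1.3 (bovine), 1.2
  (equine) and 2.4 (ovine) km/d after smoothing — sheep travel farthest,
  horses least, with gaps wide enough that the ordering is identifiable
  from a 30-day sample.
* **Cohesion.** Each animal is pulled a fraction (bovine 0.008,
  equine 0.015, ovine 0.18 per slot) of its offset toward the herd
  centroid, plus 0.005 toward the herd camp. Sheep flock tightest and
  cows loosest, so mean dispersal orders bovine > equine > ovine. A
  three-day burn-in is simulated and discarded so the herd-spread process
  starts at its stationary regime.
* **Terrain and season.** Terrain is a south→north 900–2,900 m elevation
  ramp plus Gaussian-smoothed noise; the herd camp drifts daily toward the
  latitude whose ramp altitude matches a monthly target (1,500 m in
  May/October up to 1,900 m in July/August), emulating seasonal altitude
  movement.
* **Transmission.** Each fix is delivered with probability 0.70
  (≈ 33.6 of 48 nominal fixes per day), and each collar-day suffers a
  6–18 h burst outage with probability 0.15 — outages long enough that a
  realistic share of days trips the 12 h QC rule.

What passing tests on this generator **do** show: the pipeline's stages
compose correctly; thresholds, profiles, MCP, dispersal and the diel
partition recover the generator's marginals, peak hours and configured
species orderings from degraded data. What they **do not** show: anything
about GPS position error (the generator has none — observed positions are
exact), collar-specific failure modes, shepherding interventions,
vegetation-driven movement, or the magnitudes of real herds' indicators.
Real daily distances, home ranges and dispersal depend on husbandry and
landscape and can only be validated against field data.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics, everywhere.
* Classification ties go to the lower-activity state.
* Haversine clamps its argument to [0, 1] before `arcsin` (antipodal
  safety); distances are exactly symmetric.
* Resampling needs ≥ 2 fixes; a one-fix day raises rather than fabricating
  a stationary day.
* Proximity distances project features and labels onto one tangent plane
  centered on the label cloud; point-to-segment distances are exact in
  that plane.
* MCP areas for collinear kept points are 0 (valid, non-degenerate hull).
* `summarize` flags single-observation groups (sd undefined) instead of
  erroring; empty proximity bins are emitted with `defined=False`.
* Terrain slope is the arctangent of the central-difference gradient
  magnitude with metric node spacing (longitude spacing scaled by
  cos latitude); it is invariant to constant elevation offsets.

## Known limitations

* Only WGS84 geographic input; no reprojection of arbitrary CRSs.
* Terrain input is the ESRI ASCII grid format; the grid must be lat/lon
  aligned.
* Linear interpolation only — no continuous-time or state-space movement
  model; imputed edge slots are position-held, not modelled.
* The species-and-slope threshold adjustment is one admissible design;
  others (e.g. fixed cattle thresholds rescaled by species speed ratios)
  would classify borderline steps differently.
* Statistical inference on the indicator tables (mixed models, contrasts,
  variance partitioning) is intentionally out of scope: `report` emits a
  modeling-ready table (log-transformed daily distance and home range,
  season and year factors) for a dedicated statistics environment.
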