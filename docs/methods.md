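# Methods

`fallout` re-implements, as a tested library, the analysis chain used to study
light-induced grounding of petrel fledglings on their maiden flight: flight
metrics from GPS tracks, light-pollution exposure from a nocturnal radiance
raster, randomisation/correlation inference, grouped-binomial grounding-rate
models ranked by AICc, and a mark-recovery back-calculation of breeding
population size.  Because raw tracking data of this kind are generally not
deposited, the package ships a synthetic island nightscape generator whose
defaults reproduce the published summary structure of the system, so every
downstream stage can be exercised and tested end to end.

## Coordinate and raster conventions

All files carry WGS84 lon/lat degrees; all timestamps are UTC (ISO-8601).
Metric quantities use the mid-latitude flat-ellipsoid formula (north/east
offsets scaled by the meridional and prime-vertical curvature radii at the
mean latitude).  For separations under 100 km this agrees with a full
geodesic solution to well within 0.1% — the tests verify it against an
independently coded Vincenty inverse — and inputs beyond ~5° of arc are
rejected rather than silently degraded.

Rasters are ESRI ASCII grids georeferenced in degrees, as nocturnal satellite
composites are distributed.  Cells are half-open, `[x, x+cell)` ×
`(y−cell, y]`, so a point on a shared edge belongs to exactly one cell
(deterministic boundary behaviour); fractional indices within 1e-9 of an
integer are snapped before flooring so constructed edge points are not thrown
off by float noise.  A "25 m" DEM cell is 25 m of latitude; the east–west
footprint is smaller by cos(latitude) (~12% at 28°N).  GeoTIFF input is
detected by magic bytes and refused with an explicit message; the text grid
carries the same information for this pipeline.

Three extraction primitives feed the analysis:

* **point exposure** — the value of the single containing cell, no
  interpolation (colony exposure is defined as the pixel intersecting the
  colony centre);
* **track exposure** — mean/max over the *distinct* cells the track polyline
  traverses.  Traversal subdivides each segment at exact gridline crossings
  and assigns each sub-segment by its midpoint; each traversed cell counts
  once regardless of dwell length (a length-weighted mean is available via
  `weighted=True`-style post-processing of the cell set but the unweighted
  version is canonical).  The tests check the traversal against an exact
  Liang–Barsky rectangle-clipping oracle on 1,000 random cases; dense
  sampling along the segment is additionally checked as a subset, since any
  finite sampling step can miss corner slivers that the exact walk includes;
* **buffer exposure** — mean/max over cells whose centres fall within the
  buffer radius (3 km by default) of the colony centre.  Membership is by
  cell centre, not partial-area weighting; the containing cell is always
  included, so a radius smaller than half a cell degenerates to that single
  cell.

Distance to sea is the minimum distance to the centre of any sea cell, where
sea is DEM nodata or elevation ≤ 0 — a single-raster definition of the world.
Burrows are grouped into colonies by single-linkage clustering at a 1-km
threshold: two burrows share a colony iff a chain of pairwise links ≤ 1 km
connects them.  Chaining is deliberate and documented; the partition is
invariant to input order, and colonies are labelled west-to-east for
determinism.

## Flight metrics

For each flight the summary variables are: timing (minutes from apparent
sunset to the first fix; negative values are kept and logged), duration
(first to last fix, min), cumulative path length L (m), straight length S
(first to last fix, m), tortuosity T = 1 − S/L (0 = straight, 1 = fully
convoluted; bounded in [0,1] by construction since S ≤ L), mean ground speed
(km/h), and the radiance statistics above plus the colony/grounding radiance
ratio (single-pixel values; < 1 when the grounding site is brighter).

Speed is computed over the segment ending at the first on-water rest,
detected as the first fix over sea whose incoming segment speed falls below
5 km/h (configurable).  No published definition of "rest" exists; this
threshold is far below flight speed (~45 km/h) and above GPS jitter drift.
For band-only birds without GPS, the straight distance is colony centre to
rescue point, and outputs keep the two provenances distinguishable.

Apparent sunset uses the NOAA solar-calculator equations (Meeus-style
truncated series) at solar zenith 90.833°, which folds in refraction and the
solar semidiameter.  The iteration re-evaluates the solar series at the
current sunset estimate three times; accuracy is within ±2 min of an
independently coded low-precision ephemeris in the tests.  Latitudes at or
above 66° are rejected (no polar day/night handling).

## Statistical inference

* **Two-group randomisation tests** on the difference of group means.  When
  the number of distinct reassignments C(n, n1) is at most 200,000 the null
  distribution is enumerated exactly and the p-value is a rational with that
  denominator; otherwise the test samples 9,999 reassignments and reports the
  add-one Monte-Carlo p (b+1)/(m+1), which includes the observed arrangement
  and never reaches zero.  The 200,000 threshold means an 18/13 split
  (8,568 arrangements) enumerates while a 32/20 split (225,792,840) samples.
  The two-group tests default to two-sided; the Spearman tests are the
  one-tailed ones.
* **Monte-Carlo Spearman tests**: rho on average ranks (ties allowed), null
  built by permuting one margin 9,999 times, one-tailed add-one p.
* **Yates 2×2 chi-square** with the 0.5 continuity correction clamped at
  |O−E| so near-proportional tables cannot produce a negative statistic;
  p from chi-square with 1 df.
* **Grounding-rate GLMs**: grouped-binomial response (recovered,
  not-recovered per colony), logit link, IRLS maximum likelihood
  (statsmodels backend; the tests verify the optimum against direct
  numerical likelihood maximisation to 1e-6 and the intercept-only model
  against the pooled proportion in closed form).  Models are univariate by
  design — the covariates are strongly collinear (VIF screening is provided)
  — and ranked by AICc with k counting intercept and slope, n = number of
  colonies (not birds), and ΔAICc against the best candidate.  Deviance
  explained is 100 × (null − residual)/null.  Confidence intervals are Wald
  (±1.96 SE); profile intervals can be asymmetric where the published ones
  are, and no reconciliation is attempted.  Complete separation raises an
  error naming the covariate.
* **Population back-calculation**: pairs = rescued / (grounding rate ×
  breeding success), floored to the nearest hundred (the raw value is also
  returned).  With the study's printed inputs (863 and 1,751 rescued, rate
  0.14, success 0.75) this yields 8,200 and 16,600 pairs.

## The synthetic nightscape

The generator emulates the statistical structure the analysis assumes, not
any particular island's geography.

**Island.** A radial cone with coast at 0 m and a 3,718 m peak, 25-m cells,
default radius 20 km — the aspect ratio matters: with a much smaller radius
the sub-1,000 m colony band collapses into the coastal light ring and
colonies sit under the lights, which contradicts the system being emulated.
Smooth multiplicative Gaussian-bump noise (12 bumps, ±12%) vanishes at the
coastline; sea cells are nodata.  Radiance is a 0.5 nW/(sr·cm²) background
plus 30 Gaussian point lights (σ = 500 m, amplitudes 0.3–1.0 of the 103.6
maximum, clipped there) placed in a 0.93–0.99 R coastal ring, emulating
towns on the coastal slopes.

**Colonies** are placed uniformly over land cells with elevation in
(0, 1000] m.  **Departures** follow a zero-truncated normal with underlying
mean 161.2 and SD 153.8 min after sunset.  Note that this law puts ~47% (not
a majority) of departures inside the first three hours; what it does
reproduce is the published histogram shape — the modal 3-h bin is the first
one — and that is what the tests assert.

**Flights** are biased correlated random walks at 44.79 km/h in 30-s steps
(~373 m).  Each step's heading is a weighted circular mixture of the
previous heading (weight = persistence, default 0.7), the seaward bearing
(steepest DEM descent, weight 1.0; radially outward on flat ground), and the
bearing to the most *salient* light (weight 2.0, saturating).  Salience
follows the inverse-square law: apparent brightness = source radiance /
distance², so a bright city captures birds from proportionally farther than
a dim village.  This is the package's perception model, chosen because the
attraction-radius–intensity relationship is the mechanism inferred from the
data being emulated, and because it makes the positive flight-distance ×
radiance-differential correlation a property of the mechanism rather than of
a particular random light layout (across eight island seeds the cohort
Spearman rho spans +0.18 to +0.66; with local-radiance gating it spanned
−0.03 to +0.70).  Heading noise is Gaussian with SD 0.8 × (1 − persistence)
rad, so persistence = 1 gives a deterministic straight seaward flight.
Grounding is a per-step Bernoulli event with probability hazard_scale ×
max(0, radiance − 18)/18 (clamped at 1, hazard_scale default 0.25), applied
over land; a flight ends at grounding, on leaving the mapped extent, over sea
more than 1 km from land, or at a 10,000-step cap (logged and treated as
reached-sea).  Each bird owns an RNG stream derived from (seed, bird index),
so enlarging a cohort never perturbs earlier birds.

Under the defaults a 500-bird cohort grounds with median colony-to-grounding
distance ~2–3 km, maximum well under 16 km, mean grounding-site radiance far
above mean colony radiance, and positive distance–radiance-differential
correlation — the qualitative bands the published system exhibits.

**Colony outcomes** are binomial draws with logit⁻¹(β₀ + β_d·distance-to-sea
+ β_e·elevation), defaults β₀ = −4.0, β_d = 0.0004 per m, β_e = 0.0036 per m
— the reference slope values — with β₀ set so that typical covariate values
give a pooled recovery rate near 14%.  Parameter recovery is verified by
simulation: at 200 colonies × 50 banded birds the refit slope falls within
±2 estimated SE of truth in ≥ 90% of 100 replicates.

What the generator does *not* emulate: wind and aerodynamics, moonlight,
multi-night behaviour (groundings are same-night by construction), terrain
shielding of light visibility, and observer effort in rescues.  Passing
tests therefore demonstrate that the estimators recover the structure this
generator encodes, not that the generator is a faithful model of any real
island.

## Problem sizes and determinism

The test suite runs a 500-bird cohort on the full-resolution default island
(one session-scoped build), 100-replicate slope-recovery simulations, a
60-replicate Spearman power check, 1,000-case raster-traversal oracles, and
exhaustive permutation sweeps for all splits with n ≤ 10 — about half a
minute on one CPU.  `scripts/acceptance.py` recomputes the headline
quantities from scratch in a few minutes.  Every stochastic component takes
an explicit seed; the pipeline writes byte-identical outputs for identical
config + seed, and the manifest records the config hash and library
versions.

## Known limitations

* The flat-ellipsoid distance is a local formula; it refuses rather than
  degrades beyond ~5° of arc.
* Track–raster intersection treats the trajectory as a polyline between
  fixes; at 30-s sampling a real bird can cut corners between fixes.
* The buffer statistic's cell-centre membership makes the 3-km buffer
  slightly jagged at 25-m resolution (sub-0.1% area error).
* Wald intervals understate asymmetry near separation; profile likelihood is
  not implemented.
* The grounded-bird sample in cohort statistics is, as in the emulated
  study, conditioned on grounding — estimates inherit that selection.
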