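# Methods

This note documents the modelling choices behind `peatfire`: the
procedure each stage implements, the parameters that matter, what the
synthetic generator does and does not emulate, and the numerical
conventions that make results reproducible.

## Problem setting

Degraded tropical peatlands burn nearly every dry season. The analysis
supported here treats fire occurrence as a per-pixel binary outcome and
asks which landscape drivers — proximity to settlements and canals,
land-cover state and history, vegetation and drought indices, terrain,
peat depth, and the El Niño state (ONI) — best explain where satellite
fire hotspots occur, using gradient-boosted tree ensembles as the
classifier and gain importance as the attribution metric.

All spatial data live on a regular grid in a projected metric CRS
(row 0 = north, cell values refer to whole cells, points sampled at cell
centres, half-open cell assignment). The analysis resolution used
throughout the tests is 250 m; nothing in the code assumes that value.

## Label construction from hotspot points

Satellite hotspots are detections at sensor-cell centres (1 km MODIS,
375 m VIIRS), not fire perimeters, and isolated detections carry real
false-positive risk. Labels are therefore built in two steps:

1. **Confidence classification.** A 500 m QC grid (anchored at the
   analysis grid origin) is overlaid; a hotspot is *high-confidence* iff
   another hotspot falls in the same QC cell within 30 days (inclusive).
   Everything else — singleton cells, or companions further apart in
   time — is *low-confidence*. The rule is scoped to the QC cell:
   neighbours across a cell boundary never confer confidence. Within a
   cell, only adjacent dates in sorted order need checking, so the
   implementation is O(n log n) while matching the all-pairs definition.
2. **Occurrence spaces.** Each subgroup is buffered by 500 m (the
   nominal MODIS geolocation error) and dissolved. The high-confidence
   union (clipped to the study bounds) is the positive sampling space;
   the low-confidence union minus the high space is an exclusion zone;
   the remainder is the high-confidence non-occurrence space. Low
   buffers are subtracted from high (not vice versa) so positives keep
   priority and the three spaces exactly partition the bounds. Buffers
   are polygonal circles with 16 segments per quarter arc
   (`BUFFER_QUAD_SEGS`); the area error against a true circle is below
   0.1%, well inside the 1e-6 relative conservation tolerance used on
   the partition, which is exact by construction.

Training points are drawn uniformly (rejection sampling, seeded) from
the high-fire and non-occurrence spaces. The number of points per year
and the positive:negative ratio are free parameters — no canonical value
exists — and the tests use 300–500 per class per year.

Validation uses a different observation: the yearly **density map**
(detections per km² per cell) built from *all* hotspots without QC, so
the evaluation target is not the training label.

## Predictor layers

- **Land cover** enters as 8 binary indicator rasters (dry forest, swamp
  forest, swamp scrubland, scrub/bare, riceland, plantation, settlement,
  water/cloud); a single categorical raster is also supported. Raw maps
  with richer legends are regrouped through an explicit mapping; an
  unmapped class present in the raster is an error.
- **Forest clearance index**: maps are binarized to forest/non-forest
  (default forest classes: dry forest, swamp forest). A pixel flipping
  forest→non-forest at a map iteration is assigned −10 (+10 for
  regrowth); at each subsequent map iteration in its new state the index
  moves one step toward zero; a fresh transition overwrites the running
  value. Decay counts *map iterations*, not calendar years, so the
  irregular map dates (1996, 2000, 2003, 2006, 2009, 2011, 2012, 2013,
  2015) are reflected as-is: a pixel cleared between the 2000 and 2003
  maps is −10 at 2003 and −4 at 2015.
- **Vegetation**: monthly NDVI, EVI, ET and PET rasters are gap-filled
  (each missing pixel replaced by the mean of the valid values in its
  5×5 window, truncated at edges; pixels with an all-missing window stay
  nodata; the operation is idempotent). The model consumes the ET:PET
  ratio — a soil-moisture-deficiency proxy — with nodata where PET ≤ 0.
  An optional reference-area normalization divides any layer by its mean
  over a supplied polygon (e.g. intact forest); it is off by default.
- **SPEI** (3- and 12-month): the water balance D = P − PET is
  accumulated over a trailing window that *ends with the month before*
  the labelled month, so the index is strictly antecedent. Per calendar
  month and pixel, a three-parameter log-logistic is fitted to the
  accumulations over the reference period by unbiased probability-
  weighted moments; SPEI = Φ⁻¹(F(D)). Fits with an invalid shape
  (β ≤ 1, e.g. constant or left-skewed samples — the log-logistic cannot
  represent negative skew) are flagged undefined and transform to NaN
  rather than a fabricated value. The CDF is clipped to [1e-4, 1−1e-4],
  bounding the index at about ±3.7. At least ~15 reference years are
  recommended; fits are accepted from 4 years with wider uncertainty.
- **Precipitation downscaling**: coarse rainfall is bilinearly
  interpolated between cell centres onto the analysis grid; coincident
  centres are reproduced exactly, and fine centres inside the half-cell
  margin are clamped to the coarse-centre hull.
- **Distances** to settlements, canals and roads are Euclidean distances
  from cell centres to the nearest vector feature, computed natively at
  the analysis resolution. Infrastructure is static across years,
  mirroring the practice (and acknowledged limitation) of using a single
  undated infrastructure snapshot.
- **Terrain**: slope and aspect from 4-neighbour central differences
  (one-sided at edges). Aspect is the downslope azimuth in degrees
  clockwise from north (a plane rising to the east drains west: 270°);
  cells with gradient magnitude < 1e-6 are flagged flat (NaN aspect).
  The end-to-end pipeline maps flat aspect to 0° so a meaningless
  degenerate feature does not discard rows.
- **ONI** is a spatially constant layer holding the year's
  July–September value — the only purely temporal predictor.
- **Seasonal aggregation**: pre-fire-season = May–July mean,
  fire season = August–October mean, plus August-minus-pre-season delta
  layers for the vegetation ratios.
- **Cross-year normalization**: every layer is min-max scaled with the
  min/max pooled across all training years, so inter-annual signal
  survives. Parameters are persisted (JSON) for reuse on held-out years,
  where values outside [0, 1] are legitimate. Constant layers error
  unless explicitly passed through.

A pixel that is nodata in any required input stays nodata in derived
layers, assembled table rows containing it are dropped (and counted),
and predicted maps are nodata there.

## Models

Three variants share the static layers (distances, land cover, clearance
index, ONI, elevation/slope/aspect, peat depth, SPEI-3/12) and differ in
the seasonal ones: `M_pre` adds pre-season means and the Aug−pre-season
deltas; `M_fire` adds fire-season means; `M_pre_and_fire` is the union.
Fire-season vegetation carries the scars of the fires themselves, so
`M_pre` is the "predictive" configuration and the other two are
descriptive.

Training is XGBoost binary classification (`tree_method="hist"`,
single-threaded, seeded — the test default, chosen for exact
reproducibility). Rows are sorted canonically before the 70:30
stratified split so the fit is invariant to assembly order. Every
combination in the hyper-parameter grid is fitted on the 70% portion and
scored by log-loss on the 30% portion; the winner is refitted on the
full table. The default grid spans max_depth {3, 5, 7}, learning rate
{0.05, 0.1, 0.3}, 100/300 rounds, and subsampling {0.8, 1.0}; the paper
trail for this analysis type records no canonical ranges or scoring
metric, so these are explicit package choices, and the heavier tests use
a single-combination grid for speed.

Importances are split-gain totals normalized to proportions, aggregated
into four driver groups: environmental (terrain, peat depth, ONI, SPEI),
anthropogenic proximity (the distances), vegetation indices, and land
cover (indicators plus the clearance index).

## Validation

Probability maps are binarized at a threshold (default 0.75, inclusive).
The observation mask takes the year's 90th percentile of per-pixel
density (zeros included) as the threshold, computed as an order
statistic (no interpolation between observed values); comparison is
inclusive, except that a zero threshold (a near-zero-fire year) switches
to strict-greater so the whole map is not declared burnt. Accuracy,
precision and recall are confusion-matrix proportions × 100; undefined
ratios (zero denominators) are reported as flagged `None`, never 0 or
100, so low-fire years cannot silently distort summaries. Threshold
sweeps evaluate a probability range (default 0.5–0.9) against an
absolute density-threshold range (default 1–10 hotspots/km²).

Leave-one-year-out retrains the chosen variant once per year on the
remaining years and evaluates on the held-out year; summaries report
median, quartiles, IQR and 1.5·IQR outliers per metric. A held-out year
with no usable positives still gets a row with flagged metrics.

## The synthetic generator

The generator emulates the *structure* of the real record, not its
values: categorical land-cover maps on the nine irregular map dates,
with forest cleared to swamp scrubland at a per-interval rate (2% by
default; forest never regrows in default scenarios); smooth elevation
and peat-depth fields; settlements as points and canals/roads as chords
across the region; monthly weather from a sinusoidal climatology with a
wet-season (Nov–Apr) peak (~310 mm/month) and dry-season trough
(~110 mm/month), PET peaking in the dry season (~155 mm/month); and
vegetation indices set by land-cover class, depressed for two years in
burned cells, with 2% of pixels missing per month to exercise gap
filling.

Two forcing choices matter:

- **ENSO forcing**: dry-season rainfall is scaled by (1 − 0.35·ONI), so
  El Niño years dry out. Spin-up weather years (the default record
  starts 14 years before the first study year, giving a 19-year SPEI
  reference) take a deterministic pseudo-ENSO cycle when no ONI value is
  supplied.
- **Rainfall noise**: monthly precipitation carries multiplicative gamma
  noise (CV 0.5 by default) per coarse pixel — tropical monthly rainfall
  is strongly right-skewed, and a right-skewed water balance is also the
  regime in which the log-logistic SPEI fit is well posed. With the
  noise disabled and all-zero ONI the climatology repeats identically
  every year.

Fires occur per cell and fire-season month (Aug–Oct) with the logistic
probability given in the README; the intercept is set so a cell with all
drivers at mid-range burns at `base_rate` (default 3% per month), making
the zero-weight case exactly Bernoulli(base_rate). Default planted
weights: distance to settlements −3, distance to canals −2, ONI +1.5,
pre-season NDVI −1 (log-odds on min-max normalized drivers). Each fire
has one true location inside its cell and one observing sensor (VIIRS
available from 2012, 50/50 thereafter) and emits 1 + Poisson(mean 1)
detections snapped from that location to the sensor's cell centre, with
dates inside the burning month — so repeated detections of one fire
share a QC cell, as real revisits do, and both singleton and
multi-detection cells occur. An optional uniform drop rate emulates
missed detections; it is a free parameter, not an estimate of sensor
efficiency. Ground-truth burned masks are returned for oracle tests.
Randomness is organised as one seeded stream per stage (landscape,
series, hotspots, clouds), so outputs are bit-identical given a seed and
regenerating one stage never perturbs another. Simulated cloud masks are
per-pixel Bernoulli draws around a smoothly varying daily cloudiness
level over the 123-day July–October season.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: spatially coherent burn scars and
fire spread (cells ignite independently), smoke obscuration correlated
with fire intensity, sensor-specific detection efficiencies and view
geometry, land-cover confusion between classes, rainfall fields with
realistic spatial correlation at fine scale, or any social/behavioural
driver. Tests against the generator certify the *mechanics* of the
pipeline and the recoverability of planted effects, not real-world skill.

## Problem sizes and numerical conventions

The shipped tests run at desk scale: 50×50 to 60×60 grids of 250 m
cells, 5 study years plus 14 spin-up weather years, 500–1000 training
points per year, and single-combination hyper-parameter grids for the
multi-scenario experiments (ten seeded scenarios for driver recovery;
five-year leave-one-year-out with one planted near-zero-fire year).
These sizes were chosen so the full suite exercises every stage in
minutes while leaving the statistical checks (binomial counts, oracle
comparisons, ≥8/10 seed criteria) well-powered.

Other conventions, fixed because the results depend on them: half-open
cell membership (edge points belong right/below); inclusive threshold
comparisons (≥) for probability and density, except the zero-density
degenerate case; inclusive 30-day QC window ("more than 30 days"
defines the low side strictly); ties in grid search broken by grid
order; distance rasters computed against the union of features;
interpolation clamped to the coarse-centre hull; SPEI CDF clipping at
1e-4.

## Known limitations

- SPEI fits on interpolated coarse rainfall lose skewness at the
  12-month scale (accumulation averaging symmetrizes the sample), so a
  minority of pixels carry undefined fits there; the pipeline infills
  them from their neighbourhood, which smooths but does not bias the
  layer.
- The low/high occurrence-space precedence (low buffers subtracted from
  high) is one of two defensible readings of the partition; the choice
  is fixed and tested, not derivable.
- Probability calibration reflects the balanced training sample, not the
  landscape base rate, so absolute probability thresholds (0.75) select
  different positive fractions than they would on real, imbalanced data;
  comparisons across variants and years remain meaningful.
- Static infrastructure across years reproduces a known source of error
  in the original analysis design rather than fixing it.
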