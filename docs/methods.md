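# Methods

`dasypop` estimates how many people live on low-lying coastal land or in
mapped floodplains, how that number changes as the sea rises and as
people move, and whether particular racial subgroups bear a
disproportionate share of the exposure.  This note records the models,
the defaults and the judgement calls.

## 1. Elevation relative to a year's sea level

Ground elevation `E(x)` is referenced to a fixed vertical datum.  "Sea
level" means the local mean higher high water (MHHW) tidal datum.  Two
surfaces convert one to the other: the tidal offset `T(x)` (height of
reference-epoch MHHW above the fixed datum; the epoch midpoint is 1992)
and the local relative sea-level rise rate `r(x)` in mm/yr.  The
elevation of a cell relative to the sea level of year `y` is

    rel(x, y) = E(x) − T(x) − r(x) · (y − 1992) / 1000.

Nodata in any input propagates.  Grids must be co-registered; the
pipeline takes one pre-merged elevation grid and a precomputed rate
surface (an inverse-distance interpolation from gauge points is
provided as a convenience but is not a validated substitute for an
official product).

## 2. Hazard zones

An **elevation zone** at threshold `z` (default 1 m) is the set of grid
cells with `rel < z`, excluding water/wetland cells.  Conventions,
chosen once and used everywhere:

* cell membership by the **cell-center** value;
* **strict** inequality — land exactly at `z` is outside ("below 1 m");
* polygonization dissolves member cells exactly, so polygon area equals
  cell-count area to float rounding;
* point-in-zone queries use the defining cell mask, which keeps point
  and polygon views consistent at zone edges.

Zones are therefore monotone: growing `z`, or moving the sea-level year
forward under positive rise rates, can only enlarge the zone.

**Floodplain zones** are taken as mapped polygons with categories `A`
(100-year) and `X500` (500-year).  Each polygon is classified *coastal*
if the area-majority of its cells has ground elevation at or below the
base flood elevation (BFE, default 2 m), else *inland*.  The spatial
unit of that comparison is genuinely open; per-polygon area majority
was chosen because it is reproducible and respects mapped geometry.
Polygons outside the grid default to inland with a warning.

## 3. Dasymetric interpolation

Census counts exist per block; the zone cuts through blocks.  For each
block the package computes

* `frac_area` — dry-land area in the zone over total dry land
  ("uniform density"), and
* `frac_buildings` — buildings with footprint centroid in the zone over
  all the block's buildings ("building-based density"),

and multiplies block populations by the chosen fraction.  Buildings are
counted equally (not weighted by footprint area) and assigned to blocks
spatially by centroid, so one building layer serves every census year's
block frame.  Design choices:

* a partial block with **no buildings** falls back to the uniform
  fraction under the building method (building layers are incomplete in
  reality); occurrences are logged;
* a block with **no dry land** gets fraction 0 with a warning;
* **subgroup** estimates reuse the block's total fraction — blocks are
  the finest resolution at which racial composition is known, so
  within-block homogeneity is an explicit assumption, not a finding;
* estimates stay real-valued; rounding happens only in reports.

The building-based estimator is invariant under block *remapping*:
when a census splits a block into a developed part (all buildings,
hence all residents) and an empty remainder, every building fraction is
unchanged, so the total is unchanged exactly; the uniform total is not.

## 4. Survey validation: combined ratio estimators

To validate an estimator, blocks that are only partly in the zone (the
only ones with interpolation error) are stratified by housing-unit
density (>10, 3–10, <3 units/ha), with a "tiny block" stratum below
0.25 ha and optional user-defined special strata; a stratified simple
random sample is drawn without replacement; and the true unit count is
observed for sampled blocks.  With `y` observed and `x` estimated
units, the combined ratio estimator and its large-sample variance
(with finite-population correction) are

    R = Σ_h N_h ȳ_h / Σ_h N_h x̄_h,
    V(R) = X̂⁻² Σ_h N_h² (1−f_h)/n_h (s²_yh + R² s²_xh − 2 R s_yxh),

with `f_h = n_h/N_h` and `X̂ = Σ_h N_h x̄_h`.  The ratio-adjusted total
is the method's full-frame estimated total times `R`; its coefficient
of variation (se/estimate) is read as a 66% confidence range.  Numerical
edge cases: a stratum with `n_h = 1` contributes zero variance (logged);
a stratum whose sample-mean estimate is zero while observations are not
cannot enter a ratio and is excluded with a warning; the formula was
verified against an independent hand evaluation on a two-stratum toy
before integration.

The package's Monte-Carlo calibration of this machinery uses a
4-county, 10 000-person region (≈40 partially vulnerable blocks) and
samples **50% of each stratum (minimum 8)**.  The heavy sampling
fraction mirrors practice for small frames and keeps the ratio
estimator's O(1/n) small-sample bias negligible relative to its
Monte-Carlo error; with light sampling (n_h ≈ 8) the bias is detectable
at 500 replicates even though coverage is already nominal.

## 5. Trend decomposition and apparent emigration

Let `C(c, s)` be the estimated population of census year `c` inside the
zone of sea-level year `s`.  The change between years `y0 < y1`
decomposes as

    Δcensus    = C(y1, y1) − C(y0, y1)   (people changed, zone fixed)
    Δsea-level = C(y1, y1) − C(y1, y0)   (zone changed, people fixed)
    actual     = C(y1, y1) − C(y0, y0)
    cross      = Δcensus + Δsea-level − actual,

with the cross term (interaction of population change with zone
growth) reported explicitly, never absorbed.  Both deltas anchor at the
later year; the base-anchored convention yields the same cross term.

**Apparent emigration** for a county is the decline of its zone
population, always measured against a single zone definition (terminal
sea-level year) so that zone growth is not misread as migration, and
"apparent" because deaths minus births cannot be separated from moves.
The full-period change is the exact sum of decadal changes.  The
national apparent-emigration total, per subgroup, sums the full-period
change over the counties where *that subgroup's* change is negative.
Percent columns divide by base-year county populations (subgroup
percentages by subgroup base populations); counties are flagged when
the total percent magnitude exceeds a configurable threshold (default
1%).

## 6. Disproportionality

For subgroup share `s_zone` of zone population and `s_ref` of the
reference population,

* **nationwide ratio** = `s_zone / s_ref`;
* **county-weighted ratio** = observed national subgroup zone total
  divided by the expected total if, within every county, subgroup
  presence in the zone were proportional to the subgroup's county
  share: `Σ_c z_gc / Σ_c (z_c · p_gc)` with `z_c` the county zone
  total and `p_gc` the subgroup's county share.  Counties with no zone
  population contribute zero to both sums; algebraically the measure is
  an inverse weighted average of county-specific ratios.

Reference populations: terminal census for residence ratios, base year
for emigration ratios.  Counties wholly outside the zone still count in
nationwide shares.  For the county-weighted *emigration* analogue, the
per-county inputs are the magnitudes of negative full-period changes
(counties with net in-migration contribute zero); the aggregation rule
for mixed-sign county tables is not canonical, and this choice keeps
both sums non-negative and the proportional-emigration identity exact.
Subgroup semantics throughout: "Black" means non-Hispanic Black,
"Hispanic" means Hispanic of any race, so the two are mutually
exclusive and each nests inside the total.

The same machinery supports a categorical polygon overlay (e.g.
historical lending-risk maps): block populations are apportioned into
each category (and category ∩ zone) by the chosen method, giving each
category's zone share and its ratio to the overall share.  Under the
building method each building carries an equal share of its block's
population, so blocks without buildings contribute nothing to overlay
categories.

## 7. The synthetic-region generator

Every statistical claim in the test suite is checked against regions
with *person-level ground truth*.  A region is:

* **counties and blocks** — rectangular counties stacked along y, each
  tiled by a grid of square blocks (default 2 counties × 100 blocks of
  250 m);
* **terrain** — a plane rising inland (2 m/km) from −0.5 m at the
  shore edge plus smooth seeded sinusoidal noise (amplitude 0.25 m,
  wavelength ≈900 m); the plane gives closed-form strip areas for
  delineation checks, the noise breaks symmetry;
* **water** — cells below reference-epoch sea level, forming a
  contiguous shore fringe; tidal offset 0.2 m; rise rate 4 mm/yr
  (constant or gauge-interpolated);
* **buildings** — Poisson count per block (mean 12); each building
  picks a dry cell uniformly from the cells *strictly above the block's
  median dry elevation* with probability `placement_bias` (default
  0.7), else from all dry cells.  Bias 0 is uniform placement; bias 1
  puts nothing below the block median — the mechanism behind the
  uniform-density overestimate;
* **persons** — 5 000 by default, placed *exactly at building
  centroids* (multinomial over buildings), so the building fraction is
  the true generative model and the building estimator's residual error
  isolates interpolation noise.  An adversarial mode scatters persons
  uniformly over dry land instead, exercising the uniform assumption;
* **subgroups** — per-county Hispanic and Black baseline proportions
  (defaults 10%/35% and 20%/10% alternating) with an elevation gradient
  (+0.04 Black probability per meter below the county mean), mimicking
  racially uneven settlement of low ground;
* **decades** — each census advance removes persons with probability
  `county_mult · (base + low·1[elev<1 m]·m_black)` (defaults 0.02,
  0.10, Black low-elevation multiplier 1.5) and logs every removal, so
  emigration accounting can be audited against the generative truth;
  then a fraction of blocks (default 5%) is split into a developed and
  an empty child in the gap between the buildings and a block edge —
  people and buildings never move, which is exactly the remapping that
  building-based estimates must ignore;
* **floodplains** — a coastal elevation band (0–1.2 m, with a 1.2–1.8 m
  500-year fringe) plus an inland river band over high ground, so the
  coastal/inland BFE classification has both outcomes.

One seed determines everything; independent numpy `SeedSequence`
streams per stage keep outputs byte-identical and stages decoupled.
Housing units are taken as occupied buildings (persons and units are
treated as proportional; no household model).

**What the generator does not emulate** — and therefore what passing
tests cannot certify about real data: realistic urban morphology and
block-size heterogeneity, incomplete or misregistered building layers
(beyond the zero-building fallback), population growth or immigration
(dynamics are emigration-only), hydrologic connectivity of flood
zones, vertical-datum transformation error, and census undercount.
Tests show the *estimators and accounting are correct given their
assumptions*, not that the assumptions hold anywhere in particular.

## 8. Problem sizes and runtime choices

Defaults were sized so a full synthetic study (4 censuses, 4 zone
years, both methods) runs in seconds: 200 blocks / 5 000 persons for
estimator-vs-truth comparisons (20 seeds), 400 blocks / 10 000 persons
for ratio-estimator calibration (500 replicate samples), 25 m grid
cells.  These are the package's standard experiment sizes; all are
config fields.

## 9. Known limitations

* The uniform-density comparison inherits the generator's building-led
  truth; with persons placed uniformly, the roles reverse by design.
* Combined-ratio variance is a large-sample form; with very few
  candidate blocks the CV is itself noisy.
* Floodplain coastal/inland classification uses one BFE per call, not
  per-state tables.
* Only building footprints are implemented as the ancillary layer
  (road-centerline or parcel interpolation would slot into the same
  fraction interface).
* GeoJSON/ASCII-grid serialization carries no CRS metadata; the
  pipeline assumes one consistent projected CRS end to end.
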