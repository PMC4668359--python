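# Methods

## The analysis

The package measures how well a network of marine protected areas (MPAs)
represents marine species. The protection side is a polygon register with
two attributes per record: a 'marine' flag and an IUCN management category
(Ia–VI, often missing). The biodiversity side is a set of per-species
occurrence-probability tables on a regular 0.5° latitude–longitude grid, in
the style of suitability-model output: probability 1 in a preferred core,
0 outside the range limits, decaying linearly in between.

The pipeline has four stages:

1. **Subset selection.** Four readings of "what counts as an MPA":
   (1) geometric overlap with any ocean cell; (2) the marine flag;
   (3) marine flag ∧ IUCN I–IV; (4) ocean overlap ∧ IUCN I–IV. A missing
   flag is treated as not marine and a missing category as UNASSIGNED,
   which never passes the I–IV test — the conservative reading of an
   incomplete attribute table. By construction subset 3 ⊆ 2 and 4 ⊆ 1,
   which orders per-species coverage and subset totals; the suite asserts
   this on randomized inputs.
2. **Rasterization.** The selected records are dissolved (set union, so
   overlapping designations are not double counted) and converted to
   per-cell protected fractions: spherical area of geometry ∩ cell over
   the full spherical cell area. The full-cell denominator keeps
   `fraction × area` arithmetic exact downstream; the ocean mask only
   enters the subset-1/4 overlap predicate. An ocean-denominator variant
   would be a local change in `rasterize_protection`.
3. **Thresholding.** A species' binary range at threshold *t* is the set of
   cells with probability ≥ *t* (for *t* > 0) or > 0 (at *t* = 0 — the only
   reading under which a zero threshold leaves range sizes finite). Ranges
   are nested in *t*, so gap counts are non-decreasing and median range
   sizes non-increasing across a sweep — theorems the suite checks rather
   than assumptions.
4. **Coverage and aggregation.** Coverage is the area-weighted mean of the
   protected fractions over the range's cells. Gap status is exact
   emptiness of the range ∩ {cells with nonzero fraction} — topological,
   never a ratio-to-zero comparison. Bins are Gap / 0–2 / 2–5 / 5–10 / >10%
   with left-closed boundaries from 2% up and 10% in the top bin; "very
   low" coverage (<2%) includes gap species. Summaries are produced per
   subset, per threshold, and per taxonomic group (phyla, with the largest
   phylum split into classes); density maps count selected species per
   cell; EEZ attribution tests whether any range-cell center falls inside a
   region polygon.

## Geometry and numerics

* **Spherical Earth, R = 6371 km.** Cell areas use the exact band formula
  a = R²·Δλ·(sin φ_max − sin φ_min); sphere-vs-ellipsoid differences
  (<0.4%) are far below the 0.5° discretization error. The full area field
  sums to 4πR² to 1e−6 relative (asserted).
* **Grid convention.** Rows north→south from +90°, columns west→east from
  −180°; half-open cells; the +90°/+180° edges clamp into the last
  row/column. `point_to_cell(cell_center)` is an exact inverse (property
  test).
* **Polygon areas.** Cell–polygon intersections are measured through an
  authalic transform (longitude→radians, latitude→sin latitude), under
  which the planar shoelace area × R² is exact for constant-latitude and
  constant-longitude edges and accurate to ~1e−5 relative for short
  oblique edges; geometries are segmentized (≤ cell/8) before measuring.
  This replaces per-cell equal-area projection with a closed form of the
  same accuracy class.
* **Geometry repair.** Invalid polygons are repaired with `make_valid`
  rather than zero-width buffering: buffering silently discards one lobe of
  a self-intersecting ring, losing protected area; `make_valid` keeps all
  lobes. Unrepairable geometries are dropped, logged, and counted.
  Antimeridian-crossing geometries are split at ±180° on ingest.
  Point-only records are rejected (no buffering rule is defined for them).
* **Tolerances.** The rasterizer is validated two ways: against geometry
  snapped to the 1/50-cell sub-lattice, where a 50×50 midpoint
  point-sampling oracle is exact and the rasterizer must agree within
  3/2500 absolute; and against oblique free polygons at 1.5×10⁻²,
  the intrinsic accuracy limit of a 50-point lattice oracle when a polygon
  edge runs near-parallel to a sample row (the rasterizer itself agrees
  with a 400×400 reference to ~3×10⁻⁵). Coverage arithmetic matches a
  brute-force per-cell summation to 1e−12 relative.
* **Degenerate inputs.** An empty protected-area set rasterizes to an
  all-zero field ("no MPAs" is a valid state); species whose range is empty
  at a threshold are excluded from that threshold's summary and counted;
  empty coverage-result lists and mixed subset/threshold batches are
  rejected.

## The synthetic-world generator

Real inputs (a WDPA snapshot, AquaMaps predictions) are licensed downloads,
so worlds are generated with a seeded, component-substreamed RNG (changing
the MPA count does not perturb species draws; identical config + seed give
byte-identical files).

* **Ocean.** Blocky continents placed until the land target is met, plus
  small scattered islands that seed coastal habitat and EEZs far from the
  continents, as real archipelagos do. Default ocean fraction 0.70.
* **Species.** Ranges grow by breadth-first accretion from a start cell
  over ocean cells; sizes are log-uniform per taxonomic group (heavy-tailed,
  fishes numerous and mammals few but wide-ranging); probability is 1 on
  the core (first 30% of BFS layers by default) and decays linearly with
  layer distance to the range edge. Start cells are biased toward the
  coastal band (weight 60 by default) because most marine species are
  shelf-associated.
* **MPAs.** Rectangles with log-uniform sizes (0.02–2°), coastally biased
  placement (weight 5), an IUCN category drawn from a mix that includes a
  15% UNASSIGNED share, and a marine flag that is wrongly missing at rate
  0.1 — the register's documented incompleteness and inconsistency.
* **EEZs.** A coastal band 6 cells wide (~330 km at 0.5°, approximating the
  200-nautical-mile reach) split into longitude sectors per region.
* **Scale.** Defaults (300 species, 4000 MPAs on the 0.5° grid) are the
  package's desk-scale operating point. Range-size bounds, MPA sizes and
  counts were chosen once so that the generated world reproduces the
  magnitudes such analyses report: a strict-subset estate of ~2.5M km²
  (<1% of the ocean), subset totals ordered 3 < 4 < 2 < 1, and median
  thresholded ranges falling from ~3.5M km² at t=0 to ~0.35M km² at t=1.

**Known-coverage worlds** for parameter recovery are built differently:
each range is a run of consecutive cells along one latitude row (cell areas
within a run are equal) at probability 1, and the matching MPA is either a
union of the first k whole range cells (achieved coverage exactly k/n,
equal to the target whenever target·n is an integer; the nearest achievable
value is recorded otherwise) or, in free-polygon mode, a rectangle covering
exactly the target fraction of the run's longitude extent (coverage equals
the target analytically, since area within a latitude band is proportional
to longitude span). Truth — including per-region gap membership computed
from the generator's own cell bookkeeping — is recorded alongside the
world and recovered by the full pipeline to 1e−12 (cell-aligned) or within
the rasterization tolerance (free polygons).

## What passing tests do and do not show

The generator emulates the *structure* of the real inputs, not their
geography: coastlines are blocky, taxonomic richness patterns are
schematic, and MPA polygons are rectangles rather than the real register's
intricate shapes. Consequently the pipeline's correctness claims (oracle
equivalence, recovery, monotonicity theorems, determinism) transfer to real
data, but the *values* produced on synthetic worlds do not: the synthetic
gap share at the focal threshold runs a few percent (real-data analyses
report ~1.4%), the share of gap species inside EEZs is lower than the
~95% reported globally (synthetic high-seas blobs are more common than real
ones), and the 0–2% bin absorbs mass that real data place in 2–5%.

## Design choices where the design was open

* Coverage denominators use full spherical cell areas (consistent with the
  protection raster), slightly overestimating coastal range areas — the
  coarse-grid overestimation caveat inherent to this analysis.
* EEZ membership is by cell-center inclusion, not polygon–cell overlap:
  unambiguous and cheap at 0.5°, recorded as an approximation.
* The threshold sweep reuses one protection raster across thresholds
  (rasterization is threshold-independent) — an efficiency contract only.
* Whether sweep medians are over all species or only those with non-empty
  ranges at each threshold is a free choice; the package uses non-empty
  ranges and logs exclusions.
* `region_cover_potential` exposes a `HIGH_SEAS` sentinel so that "all
  regions plus the high seas" reaches every gap species.

## Known limitations

* No management-effectiveness or enforcement weighting (not in the data).
* No species-distribution modelling: probabilities are consumed as given.
* Point-only protected-area records are rejected rather than buffered.
* Synthetic EEZ sectors are longitude bands, not national boundaries; the
  per-region counts exercise the mechanism, not real-world jurisdictions.
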