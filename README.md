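# mpagap

Gap analysis of how well marine protected areas (MPAs) represent marine
biodiversity: given a protected-area polygon register and per-cell species
occurrence probabilities on a global 0.5° grid, the package computes, for
every species, the fraction of its range that lies inside protected areas,
classifies it into representation bins, and aggregates the results into
subset comparisons, threshold-sensitivity tables, gap-species density maps,
and attribution of gap species to exclusive economic zones (EEZs).

It is written for conservation scientists who want a tested, reproducible
implementation of this analysis. Because the global inputs (a World Database
on Protected Areas snapshot; AquaMaps range predictions) are licensed
downloads, the package ships a seeded synthetic-world generator that
emulates their structure — including constructions with analytically known
coverage for end-to-end verification.

## The statistic

For species *s* with binary range *R(s, t)* — the set of grid cells whose
occurrence probability is ≥ *t* (cells with probability > 0 when *t* = 0) —
and a protected-area subset rasterized to per-cell protected fractions
*f(i)*, the coverage of *s* is the area-weighted fraction

```
c(s) = Σ_{i ∈ R(s,t)} f(i)·a(i)  /  Σ_{i ∈ R(s,t)} a(i)
```

where *a(i)* is the spherical area of cell *i*,
*a = R²·Δλ·(sin φ_max − sin φ_min)* with *R* = 6371 km. A species is a
**gap species** when every cell of its range has *f(i) = 0* — an exact
emptiness test, not a floating-point comparison. Coverage bins follow the
convention Gap / 0–2% / 2–5% / 5–10% / >10%, closed on the left from 2% up,
with the 10% boundary in the top bin.

Four subsets of the register are analysed: (1) any record overlapping an
ocean cell; (2) records flagged 'marine'; (3) marine-flagged records in
the stricter IUCN management categories I–IV; (4) ocean-overlapping records
in IUCN I–IV. Records without a category never pass the I–IV test.

## Worked example

```python
from mpagap import (SyntheticWorldConfig, generate_world, cell_areas,
                    build_protection_raster, run_threshold_sweep, SweepConfig)

config = SyntheticWorldConfig(seed=1)          # 0.5° grid, 300 species
world = generate_world(config)
areas = cell_areas(config.grid)
raster = build_protection_raster(world.mpa_records, 4,
                                 world.ocean_mask, config.grid)
table = run_threshold_sweep(world.species_maps, raster, areas, SweepConfig())
print(table[["threshold", "median_range_km2", "pct_gap", "pct_10_plus"]])
```

prints

```
   threshold  median_range_km2    pct_gap  pct_10_plus
0        0.0      3.513300e+06   1.000000     0.000000
1        0.2      2.771796e+06   2.000000     0.000000
2        0.4      2.027219e+06   3.333333     0.000000
3        0.5      1.600219e+06   4.333333     0.000000
4        0.6      1.266185e+06   6.333333     0.000000
5        0.8      7.123149e+05  12.000000     0.000000
6        1.0      3.534126e+05  20.666667     0.333333
```

Reading the table: as the probability threshold required for "presence"
rises, ranges shrink (the median falls from 3.5 to 0.35 million km²), so
more species lose all overlap with protected cells (the gap share climbs
from 1% to 21%) — the qualitative signature of threshold sensitivity in
this analysis. At the focal threshold 0.5, the strict ocean-overlapping
subset (4) protects 2.54 million km² in this world, and every species has
less than 10% of its range represented.

The same pipeline runs from the shell:

```
mpagap simulate --config sim.yaml --seed 1 --out world/
mpagap coverage --config run.yaml --subset 4 --threshold 0.5 --out out/
mpagap sweep    --config run.yaml --out out/
mpagap report   --config run.yaml --out out/
```

where `run.yaml` contains `world_dir: world/`. All commands are
deterministic: identical config and seed give byte-identical outputs, and
each output directory carries a checksum manifest.

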