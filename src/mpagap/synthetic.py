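"""Seeded synthetic worlds: ocean, species ranges, MPA polygons, EEZs.

The real analysis consumes two licensed global datasets — a protected-area
polygon register and per-cell occurrence probabilities for ~17k species.
This module generates structurally faithful stand-ins with known ground
truth:

* an ocean mask with blocky continents (no attempt at real coastlines);
* species ranges grown by seeded breadth-first accretion from a random
  ocean cell, with a contiguous core at probability 1 and probabilities
  decaying linearly with BFS-layer distance to 0 at the range edge — the
  stated structure of suitability-model output;
* heavy-tailed (log-uniform) range sizes differing by taxonomic group;
* rectangular MPA polygons placed with a coastal bias, carrying a
  WDPA-style incomplete attribute table (a marine flag that is sometimes
  wrongly absent, an IUCN category field with an UNASSIGNED share);
* EEZ polygons as coastal bands split into longitude sectors per region.

A single root seed drives independent sub-streams per component, so
changing the MPA count does not perturb the species draws.

``generate_with_known_coverage`` builds a parameter-recovery world instead:
each range is a run of cells along a single latitude row (equal cell
areas), and the MPAs are unions of whole range cells (or an analytic
longitude fraction in free-polygon mode), so every species' true coverage
is known exactly and recorded in ``truth``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .errors import ConfigError
from .gap_analysis import EezRegion
from .grid import GridSpec, cell_areas
from .mpa_subsets import IUCN_CATEGORIES, ProtectedAreaRecord, split_antimeridian
from .species_ranges import SpeciesProbabilityMap, maps_to_frame

__all__ = [
    "TaxonGroup",
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "generate_world",
    "generate_with_known_coverage",
]


@dataclass(frozen=True)
class TaxonGroup:
    """A taxonomic group with its own range-size regime (bounds in cells)."""

    kingdom: str
    phylum: str
    class_name: str
    weight: float
    range_cells: tuple[int, int]


# Default mix loosely mirrors the composition of global marine species
# lists: ray-finned fishes dominate, mammals are few but wide-ranging.
# Range bounds (in half-degree cells) are set so that the median thresholded
# range is of order 10^6 km², the magnitude of real suitability-model output.
DEFAULT_TAXA = (
    TaxonGroup("Animalia", "Chordata", "Actinopterygii", 0.45, (320, 32000)),
    TaxonGroup("Animalia", "Chordata", "Chondrichthyes", 0.06, (800, 48000)),
    TaxonGroup("Animalia", "Chordata", "Mammalia", 0.02, (3200, 128000)),
    TaxonGroup("Animalia", "Chordata", "Reptilia", 0.01, (1600, 48000)),
    TaxonGroup("Animalia", "Mollusca", "Gastropoda", 0.18, (160, 12800)),
    TaxonGroup("Animalia", "Arthropoda", "Malacostraca", 0.14, (160, 12800)),
    TaxonGroup("Animalia", "Cnidaria", "Anthozoa", 0.08, (80, 8000)),
    TaxonGroup("Animalia", "Echinodermata", "Asteroidea", 0.04, (128, 9600)),
    TaxonGroup("Plantae", "Rhodophyta", "Florideophyceae", 0.02, (80, 4800)),
)

DEFAULT_IUCN_MIX = {
    "Ia": 0.05,
    "Ib": 0.03,
    "II": 0.17,
    "III": 0.05,
    "IV": 0.15,
    "V": 0.20,
    "VI": 0.20,
    "UNASSIGNED": 0.15,
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    ocean_fraction: float = 0.70
    n_islands: int = 80
    n_regions: int = 8
    n_species: int = 300
    taxa: tuple[TaxonGroup, ...] = DEFAULT_TAXA
    core_fraction: float = 0.3
    n_mpas: int = 4000
    mpa_size_deg: tuple[float, float] = (0.02, 2.0)
    coastal_bias: float = 5.0
    species_coastal_bias: float = 60.0
    eez_band_cells: int = 6
    iucn_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IUCN_MIX)
    )
    marine_flag_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.ocean_fraction <= 1.0:
            raise ConfigError("ocean_fraction must lie in (0, 1]")
        if self.n_species <= 0 or self.n_regions <= 0:
            raise ConfigError("counts must be positive")
        if self.n_islands < 0:
            raise ConfigError("n_islands must be non-negative")
        if self.n_mpas < 0:
            raise ConfigError("n_mpas must be non-negative")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ConfigError("core_fraction must lie in [0, 1]")
        if not 0.0 <= self.marine_flag_error_rate <= 1.0:
            raise ConfigError("marine_flag_error_rate must lie in [0, 1]")
        if self.coastal_bias < 1.0 or self.species_coastal_bias < 1.0:
            raise ConfigError("coastal bias weights must be >= 1")
        if self.eez_band_cells < 1:
            raise ConfigError("eez_band_cells must be >= 1")
        if self.mpa_size_deg[0] <= 0 or self.mpa_size_deg[1] < self.mpa_size_deg[0]:
            raise ConfigError("mpa_size_deg bounds must be positive and ordered")
        total = sum(self.iucn_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("iucn_mix probabilities must sum to 1")
        if any(k not in IUCN_CATEGORIES for k in self.iucn_mix):
            raise ConfigError("iucn_mix contains unknown categories")
        for g in self.taxa:
            if g.range_cells[0] < 1 or g.range_cells[1] < g.range_cells[0]:
                raise ConfigError(f"bad range bounds for group {g.phylum}/{g.class_name}")


@dataclass
class SyntheticWorld:
    """A seeded bundle of all pipeline inputs, plus truth when constructed."""

    config: SyntheticWorldConfig
    ocean_mask: np.ndarray
    species_maps: list[SpeciesProbabilityMap]
    mpa_records: list[ProtectedAreaRecord]
    eez_regions: list[EezRegion]
    truth: dict | None = None

    def species_table(self) -> pd.DataFrame:
        return maps_to_frame(self.species_maps, self.config.grid)


# ---------------------------------------------------------------------------
# component builders (each takes its own rng sub-stream)

def _substream(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, component])


def _dilate(mask: np.ndarray) -> np.ndarray:
    """8-neighborhood dilation, wrapping longitude but not latitude."""
    out = mask.copy()
    for m in (mask, np.roll(mask, 1, axis=1), np.roll(mask, -1, axis=1)):
        out |= m
        out[1:] |= m[:-1]
        out[:-1] |= m[1:]
    return out


def _make_ocean_mask(cfg: SyntheticWorldConfig, rng: np.random.Generator) -> np.ndarray:
    spec = cfg.grid
    land = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    target = round((1.0 - cfg.ocean_fraction) * land.size)
    attempts = 0
    while land.sum() < target and attempts < 200:
        attempts += 1
        h = int(rng.integers(max(1, spec.n_rows // 12), max(2, spec.n_rows // 3) + 1))
        w = int(rng.integers(max(1, spec.n_cols // 16), max(2, spec.n_cols // 4) + 1))
        top = int(rng.integers(0, spec.n_rows - h + 1))
        left = int(rng.integers(0, spec.n_cols))
        cols = (left + np.arange(w)) % spec.n_cols
        land[np.ix_(range(top, top + h), cols)] = True
    # small islands scattered over the remaining ocean: they seed coastal
    # habitat (and EEZs) far from the continents, as real archipelagos do
    ocean_cells = np.argwhere(~land)
    n_isl = min(cfg.n_islands, len(ocean_cells))
    if n_isl:
        picks = rng.choice(len(ocean_cells), size=n_isl, replace=False)
        for r, c in ocean_cells[picks]:
            land[r, c] = True
    return ~land


_NEIGHBOR_STEPS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _grow_range_bfs(
    ocean: np.ndarray,
    start: tuple[int, int],
    size: int,
    rng: np.random.Generator,
) -> dict[tuple[int, int], int]:
    """BFS accretion over ocean cells; returns cell → BFS layer."""
    n_rows, n_cols = ocean.shape
    layers = {start: 0}
    queue = deque([start])
    while queue and len(layers) < size:
        r, c = queue.popleft()
        steps = list(_NEIGHBOR_STEPS)
        rng.shuffle(steps)
        for dr, dc in steps:
            nr, nc = r + dr, (c + dc) % n_cols
            if not 0 <= nr < n_rows:
                continue
            cell = (nr, nc)
            if cell in layers or not ocean[nr, nc]:
                continue
            layers[cell] = layers[(r, c)] + 1
            queue.append(cell)
            if len(layers) >= size:
                break
    return layers


def _layer_probabilities(layers: Mapping[tuple[int, int], int],
                         core_fraction: float) -> dict[tuple[int, int], float]:
    """Probability 1 in the core layers, linear decay to the range edge."""
    lmax = max(layers.values())
    core_layer = math.floor(core_fraction * lmax)
    span = lmax - core_layer + 1
    return {
        cell: 1.0 if layer <= core_layer else 1.0 - (layer - core_layer) / span
        for cell, layer in layers.items()
    }


def _make_species(
    cfg: SyntheticWorldConfig, ocean: np.ndarray, rng: np.random.Generator
) -> list[SpeciesProbabilityMap]:
    ocean_cells = np.argwhere(ocean)
    n_ocean = len(ocean_cells)
    max_bound = max(g.range_cells[1] for g in cfg.taxa)
    if max_bound > n_ocean:
        raise ConfigError(
            f"infeasible config: range bound {max_bound} cells exceeds the "
            f"{n_ocean} ocean cells available"
        )
    weights = np.array([g.weight for g in cfg.taxa], dtype=float)
    weights /= weights.sum()
    # most marine species are shelf species: bias range origins toward the
    # coastal band, like suitability models anchored to shelf environments
    coast = _dilate(~ocean) & ocean
    start_w = np.where(
        coast[ocean_cells[:, 0], ocean_cells[:, 1]], cfg.species_coastal_bias, 1.0
    )
    start_w /= start_w.sum()
    maps = []
    for i in range(cfg.n_species):
        group = cfg.taxa[int(rng.choice(len(cfg.taxa), p=weights))]
        lo, hi = group.range_cells
        size = max(1, round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        start = tuple(ocean_cells[int(rng.choice(n_ocean, p=start_w))])
        layers = _grow_range_bfs(ocean, (int(start[0]), int(start[1])), size, rng)
        maps.append(
            SpeciesProbabilityMap(
                species_id=f"SP{i:05d}",
                kingdom=group.kingdom,
                phylum=group.phylum,
                class_name=group.class_name,
                cells=_layer_probabilities(layers, cfg.core_fraction),
            )
        )
    return maps


def _make_mpas(
    cfg: SyntheticWorldConfig, ocean: np.ndarray, rng: np.random.Generator
) -> list[ProtectedAreaRecord]:
    spec = cfg.grid
    res = spec.resolution_deg
    coast = _dilate(~ocean) & ocean
    ocean_cells = np.argwhere(ocean)
    w = np.where(coast[ocean_cells[:, 0], ocean_cells[:, 1]], cfg.coastal_bias, 1.0)
    w /= w.sum()
    categories = list(cfg.iucn_mix)
    probs = np.array([cfg.iucn_mix[k] for k in categories])
    records = []
    lo, hi = cfg.mpa_size_deg
    for i in range(cfg.n_mpas):
        r, c = ocean_cells[int(rng.choice(len(ocean_cells), p=w))]
        lat = 90.0 - (r + rng.uniform()) * res
        lon = -180.0 + (c + rng.uniform()) * res
        width = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        height = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        geom = box(
            lon - width / 2.0,
            max(lat - height / 2.0, -90.0),
            lon + width / 2.0,
            min(lat + height / 2.0, 90.0),
        )
        geom = split_antimeridian(geom)
        marine = bool(rng.uniform() >= cfg.marine_flag_error_rate)
        records.append(
            ProtectedAreaRecord(
                pa_id=f"MPA{i:05d}",
                geometry=geom,
                marine_flag=True if marine else None,
                iucn_category=str(rng.choice(categories, p=probs)),
                name=f"Synthetic MPA {i}",
            )
        )
    return records


def _cells_to_geometry(cells: Sequence[tuple[int, int]], spec: GridSpec):
    """Union of cell boxes, merging longitude runs within rows first."""
    res = spec.resolution_deg
    by_row: dict[int, list[int]] = {}
    for r, c in cells:
        by_row.setdefault(r, []).append(c)
    boxes = []
    for r, cols in sorted(by_row.items()):
        cols = sorted(cols)
        run_start = prev = cols[0]
        lat_max = 90.0 - r * res
        for c in cols[1:] + [None]:
            if c is not None and c == prev + 1:
                prev = c
                continue
            boxes.append(
                box(
                    -180.0 + run_start * res,
                    lat_max - res,
                    -180.0 + (prev + 1) * res,
                    lat_max,
                )
            )
            if c is not None:
                run_start = prev = c
    return unary_union(boxes)


def _make_eez(
    cfg: SyntheticWorldConfig, ocean: np.ndarray
) -> tuple[list[EezRegion], dict[str, set[tuple[int, int]]]]:
    """Coastal-band EEZ polygons split into longitude sectors.

    The band width (``eez_band_cells``, default 6 cells ≈ 330 km at 0.5°)
    approximates the 200-nautical-mile reach of real exclusive economic
    zones. Also returns the cell sets behind each region (generator-side
    truth).
    """
    spec = cfg.grid
    band = ~ocean
    for _ in range(cfg.eez_band_cells):
        band = _dilate(band)
    band &= ocean
    region_cells: dict[str, set[tuple[int, int]]] = {}
    for r, c in np.argwhere(band):
        rid = f"R{int(c) * cfg.n_regions // spec.n_cols:02d}"
        region_cells.setdefault(rid, set()).add((int(r), int(c)))
    regions = [
        EezRegion(region_id=rid, geometry=_cells_to_geometry(sorted(cells), spec))
        for rid, cells in sorted(region_cells.items())
    ]
    return regions, region_cells


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a full synthetic world; identical config + seed ⇒ identical world."""
    ocean = _make_ocean_mask(config, _substream(config.seed, 0))
    if not ocean.any():
        raise ConfigError("generated world has no ocean cells")
    species = _make_species(config, ocean, _substream(config.seed, 1))
    mpas = _make_mpas(config, ocean, _substream(config.seed, 2))
    eez, _ = _make_eez(config, ocean)
    return SyntheticWorld(
        config=config,
        ocean_mask=ocean,
        species_maps=species,
        mpa_records=mpas,
        eez_regions=eez,
        truth=None,
    )


# ---------------------------------------------------------------------------
# known-coverage construction (parameter recovery)

def generate_with_known_coverage(
    config: SyntheticWorldConfig,
    target_coverages: Sequence[float],
    mode: str = "cells",
) -> SyntheticWorld:
    """World whose per-species true coverage is known by construction.

    Each species' range is a run of consecutive cells along one latitude
    row (equal areas within the run), at probability 1 everywhere, so the
    range is threshold-invariant for t in (0, 1]. In ``cells`` mode the MPA
    for species j is the union of the first k whole range cells with
    k = round(target × n): achieved coverage is exactly k/n (recorded in
    ``truth``; it equals the target whenever target × n is an integer). In
    ``polygon`` mode the MPA is a free rectangle covering exactly the target
    fraction of the run's longitude extent, so true coverage equals the
    target analytically and the pipeline recovers it within rasterization
    tolerance.
    """
    if mode not in ("cells", "polygon"):
        raise ConfigError(f"unknown known-coverage mode {mode!r}")
    targets = list(target_coverages)
    if any(not 0.0 <= t <= 1.0 for t in targets):
        raise ConfigError("target coverages must lie in [0, 1]")
    if len(targets) > config.n_species:
        raise ConfigError("more targets than species")

    spec = config.grid
    res = spec.resolution_deg
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 9])
    ocean = _make_ocean_mask(config, _substream(config.seed, 0))
    used = np.zeros_like(ocean)
    weights = np.array([g.weight for g in config.taxa], dtype=float)
    weights /= weights.sum()

    maps: list[SpeciesProbabilityMap] = []
    records: list[ProtectedAreaRecord] = []
    truth_species: dict[str, dict] = {}

    for j, target in enumerate(targets):
        group = config.taxa[int(rng.choice(len(config.taxa), p=weights))]
        lo, hi = group.range_cells
        size = max(2, round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        free = ocean & ~used
        # runs cannot wrap or leave the row: cap the draw at what fits
        size = min(size, _longest_row_run(free))
        if size < 2:
            raise ConfigError(
                f"species {j}: no free single-row ocean run of >= 2 cells; "
                "reduce n_species or raise ocean_fraction"
            )
        run = _find_row_run(free, size, rng)
        row, col0 = run
        cells = [(row, col0 + k) for k in range(size)]
        for r, c in cells:
            used[r, c] = True
        sid = f"SP{j:05d}"
        maps.append(
            SpeciesProbabilityMap(
                species_id=sid,
                kingdom=group.kingdom,
                phylum=group.phylum,
                class_name=group.class_name,
                cells={cell: 1.0 for cell in cells},
            )
        )
        if mode == "cells":
            k = round(target * size)
            achieved = k / size
            geom = _cells_to_geometry(cells[:k], spec) if k else None
        else:
            achieved = target
            if target > 0:
                lon0 = -180.0 + col0 * res
                lat_max = 90.0 - row * res
                geom = box(lon0, lat_max - res, lon0 + target * size * res, lat_max)
            else:
                geom = None
        if geom is not None and not geom.is_empty:
            records.append(
                ProtectedAreaRecord(
                    pa_id=f"MPA{j:05d}",
                    geometry=geom,
                    marine_flag=True,
                    iucn_category="II",
                    name=f"Known-coverage MPA {j}",
                )
            )
        truth_species[sid] = {
            "target": float(target),
            "achieved": float(achieved),
            "is_gap": achieved == 0.0,
        }

    eez, region_cells = _make_eez(config, ocean)
    gap_sids = {s for s, t in truth_species.items() if t["is_gap"]}
    region_gap_counts = {}
    species_regions: dict[str, list[str]] = {s: [] for s in truth_species}
    for rid, cells in sorted(region_cells.items()):
        count = 0
        for m in maps:
            if cells & set(m.cells):
                species_regions[m.species_id].append(rid)
                if m.species_id in gap_sids:
                    count += 1
        region_gap_counts[rid] = count

    truth = {
        "mode": mode,
        "species": truth_species,
        "species_regions": species_regions,
        "region_gap_counts": region_gap_counts,
    }
    return SyntheticWorld(
        config=config,
        ocean_mask=ocean,
        species_maps=maps,
        mpa_records=records,
        eez_regions=eez,
        truth=truth,
    )


def _longest_row_run(free: np.ndarray) -> int:
    best = 0
    for r in range(free.shape[0]):
        run = 0
        for cell in free[r]:
            run = run + 1 if cell else 0
            best = max(best, run)
    return best


def _find_row_run(
    free: np.ndarray, size: int, rng: np.random.Generator
) -> tuple[int, int] | None:
    """A random (row, start_col) whose next ``size`` cells are free ocean."""
    n_rows, n_cols = free.shape
    candidates = []
    for r in range(n_rows):
        row = free[r]
        run = 0
        for c in range(n_cols):
            run = run + 1 if row[c] else 0
            if run >= size:
                candidates.append((r, c - size + 1))
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]
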