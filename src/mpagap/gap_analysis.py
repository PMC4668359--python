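"""Species representation in protected areas: coverage, bins, summaries.

A species' coverage is the area-weighted fraction of its range lying in
protected cells: since the species data are coarse (half-degree cells) and
the protected-area data fine, the protected amount of a range is taken to
be the protected area of the cells the species occupies — an assumption
that tends to overestimate representation when a species uses only part of
a cell.

A species is a *gap species* when its range has exactly zero overlap with
the protected-area subset. Gap status is an emptiness test on the set of
range cells with nonzero protected fraction — a topological test, never a
floating-point comparison of the coverage ratio with zero.

Representation bins follow the reporting convention Gap / 0–2% / 2–5% /
5–10% / >10%, closed on the left from 2% up (0.02 → the 2–5% bin) and with
the 10% boundary in the top bin. "Very low" coverage (<2%) includes gap
species.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import ConfigError, DataError, InvariantError
from .grid import GridSpec, cell_center
from .mpa_subsets import ProtectionRaster
from .species_ranges import SpeciesRange, median_range_size

__all__ = [
    "CoverageBin",
    "CoverageResult",
    "BinSummary",
    "GroupSummary",
    "EezRegion",
    "EezAttribution",
    "classify_coverage",
    "species_coverage",
    "classify_bin",
    "summarize_bins",
    "group_summaries",
    "density_map",
    "eez_attribution",
    "region_cover_potential",
]


class CoverageBin(str, Enum):
    GAP = "GAP"
    C0_2 = "C0_2"
    C2_5 = "C2_5"
    C5_10 = "C5_10"
    C10_PLUS = "C10_PLUS"


BIN_ORDER = [CoverageBin.GAP, CoverageBin.C0_2, CoverageBin.C2_5,
             CoverageBin.C5_10, CoverageBin.C10_PLUS]


@dataclass(frozen=True)
class CoverageResult:
    """Coverage of one species under one subset and threshold."""

    species_id: str
    subset: int
    threshold: float
    covered_area_km2: float
    range_area_km2: float
    coverage_fraction: float
    is_gap: bool
    bin: CoverageBin


@dataclass(frozen=True)
class BinSummary:
    """Percentage of species per representation bin for one configuration."""

    subset: int
    threshold: float
    n_species: int
    total_mpa_area_km2: float
    proportions: Mapping[CoverageBin, float]


@dataclass(frozen=True)
class GroupSummary:
    """Bin proportions and median range size for one taxonomic group."""

    group: str
    n_species: int
    proportions: Mapping[CoverageBin, float]
    median_range_km2: float


@dataclass(frozen=True)
class EezRegion:
    region_id: str
    geometry: BaseGeometry


@dataclass(frozen=True)
class EezAttribution:
    in_eez: Mapping[str, bool]
    region_counts: Mapping[str, int]
    proportion_in_eez: float
    n_gap_species: int


def classify_coverage(coverage: float, is_gap: bool) -> CoverageBin:
    """Bin a coverage fraction; GAP takes precedence at zero overlap."""
    if is_gap:
        return CoverageBin.GAP
    if coverage < 0.02:
        return CoverageBin.C0_2
    if coverage < 0.05:
        return CoverageBin.C2_5
    if coverage < 0.10:
        return CoverageBin.C5_10
    return CoverageBin.C10_PLUS


def classify_bin(result: CoverageResult) -> CoverageBin:
    """Bin of an existing result (re-derived from its fields)."""
    return classify_coverage(result.coverage_fraction, result.is_gap)


def species_coverage(
    rng: SpeciesRange, raster: ProtectionRaster, areas: np.ndarray
) -> CoverageResult:
    """Area-weighted coverage of one species' range by one subset's raster.

    covered = Σ fraction_i × area_i over range cells; range = Σ area_i.
    """
    if not rng.cells:
        raise DataError(f"species {rng.species_id}: empty range has no coverage")
    if raster.fractions.shape != areas.shape:
        raise DataError("raster and area field grids do not match")
    idx = np.array(sorted(rng.cells))
    frac = raster.fractions[idx[:, 0], idx[:, 1]]
    cell_a = areas[idx[:, 0], idx[:, 1]]
    covered = float(np.sum(frac * cell_a))
    range_area = float(np.sum(cell_a))
    is_gap = bool(np.all(frac == 0.0))
    coverage = 0.0 if is_gap else covered / range_area
    return CoverageResult(
        species_id=rng.species_id,
        subset=raster.subset,
        threshold=rng.threshold,
        covered_area_km2=0.0 if is_gap else covered,
        range_area_km2=range_area,
        coverage_fraction=coverage,
        is_gap=is_gap,
        bin=classify_coverage(coverage, is_gap),
    )


def _bin_percentages(results: Sequence[CoverageResult]) -> dict[CoverageBin, float]:
    counts = {b: 0 for b in BIN_ORDER}
    for res in results:
        counts[res.bin] += 1
    n = len(results)
    pct = {b: 100.0 * counts[b] / n for b in BIN_ORDER}
    if abs(sum(pct.values()) - 100.0) > 1e-9:
        raise InvariantError("bin percentages do not sum to 100")
    return pct


def summarize_bins(
    results: Sequence[CoverageResult], total_area: float
) -> BinSummary:
    """Tally results into per-bin percentages (one subset, one threshold)."""
    if not results:
        raise DataError("summarize_bins: no coverage results")
    subsets = {r.subset for r in results}
    thresholds = {r.threshold for r in results}
    if len(subsets) != 1 or len(thresholds) != 1:
        raise DataError("summarize_bins: results mix subsets or thresholds")
    return BinSummary(
        subset=subsets.pop(),
        threshold=thresholds.pop(),
        n_species=len(results),
        total_mpa_area_km2=total_area,
        proportions=_bin_percentages(results),
    )


def group_summaries(
    results: Sequence[CoverageResult],
    taxonomy: Mapping[str, tuple[str, str]],
    ranges: Mapping[str, SpeciesRange],
    split_largest_phylum: bool = True,
) -> list[GroupSummary]:
    """Bin proportions and median range size per taxonomic group.

    Groups are phyla; when requested, the largest phylum (by species count)
    is split into its classes. Species without taxonomy go to ``UNKNOWN``,
    never dropped silently.
    """
    if not results:
        raise DataError("group_summaries: no coverage results")
    phylum_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    for res in results:
        tax = taxonomy.get(res.species_id)
        phylum_of[res.species_id] = tax[0] if tax and tax[0] else "UNKNOWN"
        class_of[res.species_id] = tax[1] if tax and tax[1] else "UNKNOWN"

    counts: dict[str, int] = {}
    for res in results:
        counts[phylum_of[res.species_id]] = counts.get(phylum_of[res.species_id], 0) + 1
    largest = max(counts, key=lambda k: (counts[k], k)) if split_largest_phylum else None

    def group_of(sid: str) -> str:
        ph = phylum_of[sid]
        if ph == largest and ph != "UNKNOWN":
            return f"{ph}/{class_of[sid]}"
        return ph

    grouped: dict[str, list[CoverageResult]] = {}
    for res in results:
        grouped.setdefault(group_of(res.species_id), []).append(res)

    out = []
    for name in sorted(grouped):
        members = grouped[name]
        member_ranges = [ranges[r.species_id] for r in members if r.species_id in ranges]
        if len(member_ranges) != len(members):
            raise DataError(f"group {name}: some species lack a range object")
        out.append(
            GroupSummary(
                group=name,
                n_species=len(members),
                proportions=_bin_percentages(members),
                median_range_km2=median_range_size(member_ranges),
            )
        )
    return out


def density_map(
    results: Sequence[CoverageResult],
    ranges: Mapping[str, SpeciesRange],
    selector: str,
    spec: GridSpec,
) -> np.ndarray:
    """Per-cell count of selected species (``GAP`` or ``VERY_LOW``).

    ``VERY_LOW`` selects coverage < 2% *including* gap species. The map's
    total mass equals the summed range sizes (in cells) of selected species.
    """
    if selector not in ("GAP", "VERY_LOW"):
        raise ConfigError(f"unknown density selector {selector!r}")
    counts = np.zeros((spec.n_rows, spec.n_cols), dtype=int)
    for res in results:
        if selector == "GAP":
            selected = res.is_gap
        else:
            selected = res.is_gap or res.coverage_fraction < 0.02
        if not selected:
            continue
        rng = ranges.get(res.species_id)
        if rng is None:
            raise DataError(f"density_map: no range for species {res.species_id}")
        idx = np.array(sorted(rng.cells))
        counts[idx[:, 0], idx[:, 1]] += 1
    return counts


def _range_centers(rng: SpeciesRange, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    cells = sorted(rng.cells)
    lats, lons = zip(*(cell_center(r, c, spec) for r, c in cells))
    return np.asarray(lons), np.asarray(lats)


def eez_attribution(
    gap_results: Sequence[CoverageResult],
    ranges: Mapping[str, SpeciesRange],
    eez_regions: Sequence[EezRegion],
    spec: GridSpec,
) -> EezAttribution:
    """Attribute gap species to exclusive economic zones.

    A species is "found inside" an EEZ when at least one of its range-cell
    centers falls inside any region polygon; a species straddling regions
    counts once in the overall proportion but in every straddled region's
    tally.
    """
    for region in eez_regions:
        if not region.region_id:
            raise DataError("EEZ region without a region identifier")
    gaps = [r for r in gap_results if r.is_gap]
    in_eez: dict[str, bool] = {}
    region_counts = {region.region_id: 0 for region in eez_regions}
    for res in gaps:
        rng = ranges.get(res.species_id)
        if rng is None:
            raise DataError(f"eez_attribution: no range for species {res.species_id}")
        lons, lats = _range_centers(rng, spec)
        inside_any = False
        for region in eez_regions:
            if shapely.contains_xy(region.geometry, lons, lats).any():
                region_counts[region.region_id] += 1
                inside_any = True
        in_eez[res.species_id] = inside_any
    proportion = (sum(in_eez.values()) / len(gaps)) if gaps else 0.0
    return EezAttribution(
        in_eez=in_eez,
        region_counts=region_counts,
        proportion_in_eez=proportion,
        n_gap_species=len(gaps),
    )


def region_cover_potential(
    gap_results: Sequence[CoverageResult],
    ranges: Mapping[str, SpeciesRange],
    region_set: Iterable[str],
    eez_regions: Sequence[EezRegion],
    spec: GridSpec,
) -> int:
    """Gap species that would gain coverage were the named regions protected.

    Counts gap species with at least one range-cell center in any region of
    ``region_set``; monotone non-decreasing as regions are added. The
    sentinel region ``HIGH_SEAS`` selects cells outside every EEZ polygon,
    so all regions plus the high seas reach every gap species.
    """
    known = {region.region_id: region for region in eez_regions}
    wanted = list(region_set)
    unknown = [r for r in wanted if r not in known and r != "HIGH_SEAS"]
    if unknown:
        raise ConfigError(f"unknown region names: {unknown}")
    if not wanted:
        return 0
    high_seas = "HIGH_SEAS" in wanted
    geoms = [known[r].geometry for r in wanted if r != "HIGH_SEAS"]
    all_geoms = [region.geometry for region in eez_regions]
    count = 0
    for res in gap_results:
        if not res.is_gap:
            continue
        rng = ranges.get(res.species_id)
        if rng is None:
            raise DataError(f"region_cover_potential: no range for {res.species_id}")
        lons, lats = _range_centers(rng, spec)
        hit = any(shapely.contains_xy(g, lons, lats).any() for g in geoms)
        if not hit and high_seas:
            inside = np.zeros(len(lons), dtype=bool)
            for g in all_geoms:
                inside |= shapely.contains_xy(g, lons, lats)
            hit = bool((~inside).any())
        if hit:
            count += 1
    return count
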