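"""Protected-area subsets and polygon-to-grid protection fractions.

The protected-area register is filtered into four subsets that reflect
different readings of "what counts as a marine protected area":

1. any record whose geometry overlaps an ocean cell;
2. any record carrying the database's 'marine' flag;
3. marine-flagged records in the stricter IUCN management categories I–IV;
4. ocean-overlapping records in IUCN I–IV.

Records missing the marine flag are treated as not marine; records missing
an IUCN category are UNASSIGNED and never pass the I–IV test — the
conservative reading of an incomplete category field.

Each subset is dissolved (set union, so overlapping designations are not
double counted) and rasterized to a per-cell protected fraction: the
spherical area of ``geometry ∩ cell`` divided by the full spherical cell
area. The full cell (not its ocean portion) is the denominator, which keeps
``fraction × area`` arithmetic exact downstream; the ocean mask enters only
through the subset-1/4 overlap predicate.

Cell–polygon intersection areas use an authalic transform — longitude to
radians, latitude to its sine — under which the planar shoelace area times
R² equals the spherical area exactly for edges of constant latitude or
longitude, and to high accuracy for short oblique edges (geometries are
segmentized before measuring). Exact spherical polygon area is overkill at
half-degree resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
import shapely.affinity
import shapely.prepared
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ConfigError, DataError
from .grid import GridSpec, cell_areas, window_for_bounds

logger = logging.getLogger(__name__)

IUCN_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI", "UNASSIGNED")
STRICT_CATEGORIES = frozenset({"Ia", "Ib", "II", "III", "IV"})
SUBSET_IDS = (1, 2, 3, 4)

__all__ = [
    "IUCN_CATEGORIES",
    "STRICT_CATEGORIES",
    "SUBSET_IDS",
    "ProtectedAreaRecord",
    "ProtectionRaster",
    "normalize_iucn",
    "split_antimeridian",
    "repair_geometry",
    "spherical_area_km2",
    "ocean_overlaps",
    "select_subset",
    "dissolve",
    "rasterize_protection",
    "total_protected_area",
    "build_protection_raster",
]


@dataclass
class ProtectedAreaRecord:
    """One protected-area polygon with the register attributes we consume.

    ``marine_flag`` may be None (missing in the register → treated as
    False); ``iucn_category`` is drawn from the closed vocabulary, with
    missing values mapped to ``UNASSIGNED``.
    """

    pa_id: str
    geometry: BaseGeometry
    marine_flag: bool | None = None
    iucn_category: str = "UNASSIGNED"
    name: str = ""

    def __post_init__(self) -> None:
        self.iucn_category = normalize_iucn(self.iucn_category)
        if self.geometry is None or self.geometry.is_empty:
            raise DataError(f"record {self.pa_id}: empty geometry")
        if self.geometry.geom_type in ("Point", "MultiPoint"):
            raise DataError(
                f"record {self.pa_id}: point-only protected-area records are "
                "not supported (no buffering rule is defined); provide polygons"
            )


@dataclass
class ProtectionRaster:
    """Per-cell protected fraction for one subset on one grid."""

    subset: int
    fractions: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        if self.subset not in SUBSET_IDS:
            raise ConfigError(f"unknown subset id {self.subset}")
        if self.fractions.shape != (self.spec.n_rows, self.spec.n_cols):
            raise DataError("fraction field shape does not match grid")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1 + 1e-12):
            raise DataError("protected fractions must lie in [0, 1]")


def normalize_iucn(value: object) -> str:
    """Map a raw category value onto the closed vocabulary."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "UNASSIGNED"
    text = str(value).strip()
    if text == "" or text.lower() in ("nan", "none", "not assigned", "unassigned"):
        return "UNASSIGNED"
    if text not in IUCN_CATEGORIES:
        raise DataError(f"unknown IUCN category {text!r}; expected one of {IUCN_CATEGORIES}")
    return text


def split_antimeridian(geom: BaseGeometry) -> BaseGeometry:
    """Clip a geometry into [-180, 180] longitude, translating any parts
    drawn past the antimeridian back into range.

    Geometries built in a continuous longitude frame (e.g. a box around
    +179.8° extending to +181°) become two pieces on either side of ±180,
    avoiding wrap-around area blowups.
    """
    world = box(-180.0, -90.0, 180.0, 90.0)
    lon_min, _, lon_max, _ = geom.bounds
    if lon_min >= -180.0 and lon_max <= 180.0:
        return geom
    parts = [geom.intersection(world)]
    if lon_max > 180.0:
        parts.append(shapely.affinity.translate(geom, xoff=-360.0).intersection(world))
    if lon_min < -180.0:
        parts.append(shapely.affinity.translate(geom, xoff=360.0).intersection(world))
    return unary_union([p for p in parts if not p.is_empty])


def repair_geometry(geom: BaseGeometry) -> BaseGeometry | None:
    """Repair an invalid geometry, keeping every polygonal lobe.

    ``make_valid`` is preferred over zero-width buffering because buffering
    silently discards one lobe of a self-intersecting ring. Returns None
    when the geometry cannot be repaired to a non-empty polygonal shape.
    """
    if geom is None or geom.is_empty:
        return None
    g = split_antimeridian(geom)
    if not g.is_valid:
        g = shapely.make_valid(g)
    if g.geom_type == "GeometryCollection":
        polys = [p for p in g.geoms if p.geom_type in ("Polygon", "MultiPolygon")]
        g = unary_union(polys) if polys else Polygon()
    if g.is_empty or not g.is_valid:
        return None
    return g


def _authalic(geom: BaseGeometry) -> BaseGeometry:
    return shapely.transform(
        geom,
        lambda a: np.column_stack((np.radians(a[:, 0]), np.sin(np.radians(a[:, 1])))),
    )


def spherical_area_km2(geom: BaseGeometry, spec: GridSpec,
                       densify_deg: float | None = 0.05) -> float:
    """Spherical area (km²) of a lon/lat polygon on the grid's sphere.

    Edges are densified before the authalic transform so oblique segments
    follow the lon/lat straight lines they represent.
    """
    if geom.is_empty:
        return 0.0
    if densify_deg is not None:
        geom = shapely.segmentize(geom, densify_deg)
    return _authalic(geom).area * spec.earth_radius_km**2


def ocean_overlaps(geom: BaseGeometry, ocean_mask: np.ndarray, spec: GridSpec) -> bool:
    """True when the geometry intersects at least one ocean cell."""
    if ocean_mask.shape != (spec.n_rows, spec.n_cols):
        raise DataError("ocean mask shape does not match grid")
    for part in getattr(geom, "geoms", [geom]):
        r0, r1, c0, c1 = window_for_bounds(part.bounds, spec)
        window = ocean_mask[r0 : r1 + 1, c0 : c1 + 1]
        if not window.any():
            continue
        rr, cc = np.nonzero(window)
        res = spec.resolution_deg
        lon_min = -180.0 + (c0 + cc) * res
        lat_max = 90.0 - (r0 + rr) * res
        boxes = shapely.box(lon_min, lat_max - res, lon_min + res, lat_max)
        if shapely.intersects(boxes, part).any():
            return True
    return False


def select_subset(
    records: Iterable[ProtectedAreaRecord],
    subset: int,
    ocean_mask: np.ndarray,
    spec: GridSpec,
) -> list[ProtectedAreaRecord]:
    """Filter records into one of the four subset definitions.

    Subsets 1 and 4 test geometric overlap with ocean cells; subsets 2 and
    3 test the marine flag only; 3 and 4 additionally require an IUCN
    category in I–IV (UNASSIGNED never qualifies).
    """
    if subset not in SUBSET_IDS:
        raise ConfigError(f"unknown subset id {subset}; expected one of {SUBSET_IDS}")
    out = []
    for rec in records:
        marine = rec.marine_flag is True
        strict = rec.iucn_category in STRICT_CATEGORIES
        if subset == 2:
            keep = marine
        elif subset == 3:
            keep = marine and strict
        else:
            if subset == 4 and not strict:
                keep = False  # skip the geometric test when the category already fails
            else:
                keep = ocean_overlaps(rec.geometry, ocean_mask, spec)
        if keep:
            out.append(rec)
    return out


def dissolve(records: Sequence[ProtectedAreaRecord]) -> BaseGeometry:
    """Set union of all record geometries (repairing invalid ones first).

    Unrepairable geometries are dropped with a logged warning; the union
    prevents double counting where designations overlap.
    """
    repaired, dropped = [], 0
    for rec in records:
        g = repair_geometry(rec.geometry)
        if g is None:
            dropped += 1
            logger.warning("dropping unrepairable geometry for record %s", rec.pa_id)
            continue
        repaired.append(g)
    if dropped:
        logger.warning("dissolve: dropped %d unrepairable geometries", dropped)
    if not repaired:
        return Polygon()
    return unary_union(repaired)


def rasterize_protection(
    dissolved: BaseGeometry, spec: GridSpec, subset: int = 4
) -> ProtectionRaster:
    """Convert a dissolved multipolygon to per-cell protected fractions.

    ``fraction[r, c]`` is the spherical area of ``geometry ∩ cell`` over the
    full spherical cell area. An empty geometry yields an all-zero raster
    (a valid "no protected areas" state).
    """
    fractions = np.zeros((spec.n_rows, spec.n_cols))
    if dissolved is None or dissolved.is_empty:
        return ProtectionRaster(subset=subset, fractions=fractions, spec=spec)
    areas = cell_areas(spec)
    seg = max(spec.resolution_deg / 8.0, 0.01)
    # union parts are disjoint, so per-part accumulation cannot exceed 1
    for part in getattr(dissolved, "geoms", [dissolved]):
        if part.is_empty or part.geom_type not in ("Polygon", "MultiPolygon"):
            continue
        prepared = shapely.prepared.prep(part)
        r0, r1, c0, c1 = window_for_bounds(part.bounds, spec)
        res = spec.resolution_deg
        for r in range(r0, r1 + 1):
            lat_max = 90.0 - r * res
            for c in range(c0, c1 + 1):
                lon_min = -180.0 + c * res
                cell = box(lon_min, lat_max - res, lon_min + res, lat_max)
                if not prepared.intersects(cell):
                    continue
                if prepared.contains_properly(cell):
                    fractions[r, c] += 1.0
                    continue
                inter = part.intersection(cell)
                if inter.is_empty:
                    continue
                a = spherical_area_km2(inter, spec, densify_deg=seg)
                fractions[r, c] += a / areas[r, c]
    np.clip(fractions, 0.0, 1.0, out=fractions)
    return ProtectionRaster(subset=subset, fractions=fractions, spec=spec)


def total_protected_area(raster: ProtectionRaster, areas: np.ndarray) -> float:
    """Total protected area in km²: Σ fraction_i × area_i."""
    if raster.fractions.shape != areas.shape:
        raise DataError("raster and area field grids do not match")
    return float(np.sum(raster.fractions * areas))


def build_protection_raster(
    records: Iterable[ProtectedAreaRecord],
    subset: int,
    ocean_mask: np.ndarray,
    spec: GridSpec,
) -> ProtectionRaster:
    """Select → dissolve → rasterize, the standard path for one subset."""
    selected = select_subset(records, subset, ocean_mask, spec)
    return rasterize_protection(dissolve(selected), spec, subset=subset)
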