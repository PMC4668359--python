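"""Reading and writing the pipeline's on-disk dialects.

Everything is plain text: species tables as long CSV (or Parquet),
protected-area and EEZ polygons as GeoJSON (WGS84 lon/lat), masks and
rasters as ESRI ASCII grids plus long CSV. GeoJSON is handled with
``shapely.geometry.shape``/``mapping`` and the standard json module;
feature properties carry the register attributes, with the column names
mappable through the run configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import mapping, shape

from .errors import DataError
from .gap_analysis import EezRegion
from .grid import GridSpec, read_ascii_grid, write_ascii_grid
from .mpa_subsets import ProtectedAreaRecord
from .synthetic import SyntheticWorld
from .species_ranges import write_probability_maps

__all__ = [
    "DEFAULT_MPA_COLUMNS",
    "write_mpa_geojson",
    "read_mpa_geojson",
    "write_eez_geojson",
    "read_eez_geojson",
    "write_ocean_mask",
    "read_ocean_mask",
    "write_world",
    "file_sha256",
]

# GeoJSON property names for the register attributes; a run config may remap
# them (WDPA itself uses e.g. MARINE / IUCN_CAT).
DEFAULT_MPA_COLUMNS = {
    "pa_id": "pa_id",
    "marine_flag": "marine",
    "iucn_category": "iucn_category",
    "name": "name",
}


def _dump_json(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def write_mpa_geojson(records: Sequence[ProtectedAreaRecord], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(rec.geometry),
            "properties": {
                "pa_id": rec.pa_id,
                "marine": rec.marine_flag,
                "iucn_category": rec.iucn_category,
                "name": rec.name,
            },
        }
        for rec in records
    ]
    _dump_json({"type": "FeatureCollection", "features": features}, Path(path))


def read_mpa_geojson(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[ProtectedAreaRecord]:
    cols = dict(DEFAULT_MPA_COLUMNS)
    if columns:
        cols.update(columns)
    with open(path, encoding="utf-8") as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    records = []
    for i, feat in enumerate(collection.get("features", [])):
        props = feat.get("properties", {}) or {}
        geom = feat.get("geometry")
        if geom is None:
            raise DataError(f"{path}: feature {i} has no geometry")
        marine = props.get(cols["marine_flag"])
        if marine is not None:
            marine = bool(marine)
        records.append(
            ProtectedAreaRecord(
                pa_id=str(props.get(cols["pa_id"], f"FEATURE{i}")),
                geometry=shape(geom),
                marine_flag=marine,
                iucn_category=props.get(cols["iucn_category"]),
                name=str(props.get(cols["name"], "") or ""),
            )
        )
    return records


def write_eez_geojson(regions: Sequence[EezRegion], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(region.geometry),
            "properties": {"region_id": region.region_id},
        }
        for region in regions
    ]
    _dump_json({"type": "FeatureCollection", "features": features}, Path(path))


def read_eez_geojson(path: str | Path) -> list[EezRegion]:
    with open(path, encoding="utf-8") as fh:
        collection = json.load(fh)
    regions = []
    for i, feat in enumerate(collection.get("features", [])):
        rid = (feat.get("properties") or {}).get("region_id")
        if not rid:
            raise DataError(f"{path}: feature {i} missing region_id")
        regions.append(EezRegion(region_id=str(rid), geometry=shape(feat["geometry"])))
    return regions


def write_ocean_mask(mask: np.ndarray, spec: GridSpec, path: str | Path) -> None:
    write_ascii_grid(mask.astype(float), spec, path)


def read_ocean_mask(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    values, spec = read_ascii_grid(path)
    return values > 0.5, spec


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict:
    """Write a synthetic world in the dialects the pipeline reads.

    Returns a manifest mapping file names to sha256 checksums (plus the
    grid parameters and seed); no timestamps, so reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = world.config.grid
    write_probability_maps(world.species_maps, outdir / "species.csv", spec)
    write_mpa_geojson(world.mpa_records, outdir / "mpas.geojson")
    write_eez_geojson(world.eez_regions, outdir / "eez.geojson")
    write_ocean_mask(world.ocean_mask, spec, outdir / "ocean_mask.asc")
    files = ["species.csv", "mpas.geojson", "eez.geojson", "ocean_mask.asc"]
    if world.truth is not None:
        _dump_json(world.truth, outdir / "truth.json")
        files.append("truth.json")
    manifest = {
        "seed": world.config.seed,
        "grid": {
            "resolution_deg": spec.resolution_deg,
            "earth_radius_km": spec.earth_radius_km,
        },
        "files": {name: file_sha256(outdir / name) for name in files},
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
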