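"""Global geographic lattice and spherical cell-area arithmetic.

Every other module works on a regular latitude/longitude grid. The
conventions are fixed here, once:

* rows run north to south starting at +90° latitude, columns run west to
  east starting at −180° longitude (row-major, north-up);
* each cell is half-open, ``[lat_min, lat_max) x [lon_min, lon_max)``; the
  global upper edges (+90° latitude, +180° longitude) are closed by
  clamping into the last row / column;
* all areas are spherical (radius 6371 km by default), using the exact band
  formula ``a = R² · Δλ · (sin φ_max − sin φ_min)``.

A spherical Earth is deliberate: at half-degree resolution the
sphere-vs-ellipsoid area difference (<0.4%) is far below the grid
discretisation error, and the sphere has an exact closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError

LAT_ORIGIN = 90.0
LON_ORIGIN = -180.0

__all__ = [
    "GridSpec",
    "cell_bounds",
    "cell_center",
    "cell_area",
    "cell_areas",
    "point_to_cell",
    "window_for_bounds",
    "write_grid_csv",
    "write_ascii_grid",
    "read_ascii_grid",
    "area_field_to_csv",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular global lon/lat grid plus the Earth radius used for areas.

    Parameters
    ----------
    resolution_deg : float
        Cell size in degrees. Must divide 180 exactly. The analysis default
        is 0.5° (360 rows × 720 columns); tests may use coarser grids.
    earth_radius_km : float
        Radius of the spherical Earth used for all area arithmetic.
    """

    resolution_deg: float = 0.5
    earth_radius_km: float = 6371.0

    def __post_init__(self) -> None:
        if self.resolution_deg <= 0:
            raise ConfigError("resolution_deg must be positive")
        if self.earth_radius_km <= 0:
            raise ConfigError("earth_radius_km must be positive")
        rows = 180.0 / self.resolution_deg
        if abs(rows - round(rows)) > 1e-9:
            raise ConfigError(
                f"resolution_deg={self.resolution_deg} does not divide 180 evenly"
            )

    @property
    def n_rows(self) -> int:
        return round(180.0 / self.resolution_deg)

    @property
    def n_cols(self) -> int:
        return round(360.0 / self.resolution_deg)

    def validate_cell(self, row: int, col: int) -> None:
        if not 0 <= row < self.n_rows:
            raise DataError(f"row {row} out of range [0, {self.n_rows})")
        if not 0 <= col < self.n_cols:
            raise DataError(f"col {col} out of range [0, {self.n_cols})")


def cell_bounds(row: int, col: int, spec: GridSpec) -> tuple[float, float, float, float]:
    """Bounds ``(lat_min, lat_max, lon_min, lon_max)`` of one cell, degrees.

    Half-open in both axes: the cell owns its southern and western edges.
    """
    spec.validate_cell(row, col)
    res = spec.resolution_deg
    lat_max = LAT_ORIGIN - row * res
    lat_min = lat_max - res
    lon_min = LON_ORIGIN + col * res
    lon_max = lon_min + res
    return lat_min, lat_max, lon_min, lon_max


def cell_center(row: int, col: int, spec: GridSpec) -> tuple[float, float]:
    """Center ``(lat, lon)`` of one cell, degrees."""
    lat_min, lat_max, lon_min, lon_max = cell_bounds(row, col, spec)
    return (lat_min + lat_max) / 2.0, (lon_min + lon_max) / 2.0


def cell_area(row: int, col: int, spec: GridSpec) -> float:
    """Spherical area of one cell in km² (depends on the row only)."""
    lat_min, lat_max, _, _ = cell_bounds(row, col, spec)
    dlam = math.radians(spec.resolution_deg)
    r2 = spec.earth_radius_km**2
    return r2 * dlam * (math.sin(math.radians(lat_max)) - math.sin(math.radians(lat_min)))


def cell_areas(spec: GridSpec) -> np.ndarray:
    """Per-cell area field, km², shape ``(n_rows, n_cols)``.

    Areas are constant within a latitude band and sum to 4πR² over the
    globe (the sine terms telescope).
    """
    res = spec.resolution_deg
    edges = LAT_ORIGIN - res * np.arange(spec.n_rows + 1)
    sines = np.sin(np.radians(edges))
    band = spec.earth_radius_km**2 * math.radians(res) * (sines[:-1] - sines[1:])
    return np.repeat(band[:, None], spec.n_cols, axis=1)


def point_to_cell(lat: float, lon: float, spec: GridSpec) -> tuple[int, int]:
    """Cell containing a point, honouring the half-open edge convention.

    ``lat = +90`` and ``lon = +180`` clamp into the first row / last column
    so every point of the closed globe maps to exactly one cell.
    """
    if not -90.0 <= lat <= 90.0:
        raise DataError(f"latitude {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise DataError(f"longitude {lon} outside [-180, 180]")
    res = spec.resolution_deg
    row = spec.n_rows - 1 - math.floor((lat + 90.0) / res)
    row = min(max(row, 0), spec.n_rows - 1)
    col = math.floor((lon - LON_ORIGIN) / res)
    col = min(max(col, 0), spec.n_cols - 1)
    return row, col


def window_for_bounds(
    bounds: tuple[float, float, float, float], spec: GridSpec
) -> tuple[int, int, int, int]:
    """Cell window ``(row0, row1, col0, col1)`` (inclusive) covering a
    shapely-style ``(lon_min, lat_min, lon_max, lat_max)`` bounding box,
    clipped to the grid."""
    lon_min, lat_min, lon_max, lat_max = bounds
    r0, c0 = point_to_cell(min(lat_max, 90.0), max(lon_min, -180.0), spec)
    r1, c1 = point_to_cell(max(lat_min, -90.0), min(lon_max, 180.0), spec)
    return r0, r1, c0, c1


# ---------------------------------------------------------------------------
# text raster I/O (long CSV and ESRI ASCII grid)

def write_grid_csv(values: np.ndarray, spec: GridSpec, path: str | Path,
                   value_column: str = "value") -> None:
    """Write a per-cell field as long CSV: row,col,center_lat,center_lon,value."""
    if values.shape != (spec.n_rows, spec.n_cols):
        raise DataError("field shape does not match grid")
    res = spec.resolution_deg
    rows, cols = np.indices(values.shape)
    lat = LAT_ORIGIN - (rows + 0.5) * res
    lon = LON_ORIGIN + (cols + 0.5) * res
    import pandas as pd

    df = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "center_lat": lat.ravel(),
            "center_lon": lon.ravel(),
            value_column: values.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_ascii_grid(values: np.ndarray, spec: GridSpec, path: str | Path,
                     nodata: float = -9999.0) -> None:
    """Write a per-cell field as an ESRI ASCII grid (plain-text raster)."""
    if values.shape != (spec.n_rows, spec.n_cols):
        raise DataError("field shape does not match grid")
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {LON_ORIGIN}\n"
        f"yllcorner {-90.0}\n"
        f"cellsize {spec.resolution_deg}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for r in range(values.shape[0]):
            fh.write(" ".join(f"{v:.10g}" for v in values[r]) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path, encoding="utf-8") as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    spec = GridSpec(resolution_deg=head["cellsize"])
    values = np.atleast_2d(values)
    if values.shape != (spec.n_rows, spec.n_cols):
        raise DataError(
            f"ASCII grid shape {values.shape} does not match "
            f"{spec.n_rows}x{spec.n_cols} at {head['cellsize']}°"
        )
    return values, spec


def area_field_to_csv(spec: GridSpec, path: str | Path) -> None:
    """Export the cell-area field as long CSV (row, col, centers, area_km2)."""
    write_grid_csv(cell_areas(spec), spec, path, value_column="area_km2")
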