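"""Species occurrence-probability maps and their thresholded binary ranges.

Distribution models of the AquaMaps kind assign each half-degree cell a
relative probability of occurrence in [0, 1]: 1 inside the preferred range,
0 outside the range limits, decaying linearly between. This module consumes
such probabilities as given (no environmental envelopes are fit) and turns
them into binary ranges at a probability threshold.

Threshold semantics: a cell belongs to the range when its probability is
``>= t`` for ``t > 0``, and when it is ``> 0`` at ``t = 0`` — otherwise a
zero threshold would put every ocean cell in every range. Range areas use
full spherical cell areas so that coverage numerators and denominators stay
in identical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .grid import LAT_ORIGIN, LON_ORIGIN, GridSpec

CSV_COLUMNS = [
    "species_id",
    "kingdom",
    "phylum",
    "class",
    "center_lon",
    "center_lat",
    "probability",
]

__all__ = [
    "CSV_COLUMNS",
    "SpeciesProbabilityMap",
    "SpeciesRange",
    "read_probability_maps",
    "write_probability_maps",
    "maps_to_frame",
    "threshold_range",
    "median_range_size",
]


@dataclass
class SpeciesProbabilityMap:
    """Sparse per-cell occurrence probabilities for one species."""

    species_id: str
    kingdom: str
    phylum: str
    class_name: str
    cells: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        if not self.cells:
            raise DataError(f"species {self.species_id}: no cells with probability > 0")
        for cell, p in self.cells.items():
            if not 0.0 < p <= 1.0:
                raise DataError(
                    f"species {self.species_id}: probability {p} at cell {cell} "
                    "outside (0, 1]"
                )


@dataclass(frozen=True)
class SpeciesRange:
    """Binary range of one species at one probability threshold."""

    species_id: str
    threshold: float
    cells: frozenset[tuple[int, int]]
    range_area_km2: float


def _coord_to_index(center: np.ndarray, origin: float, sign: float, res: float,
                    n: int, axis: str) -> np.ndarray:
    """Map center coordinates to indices, rejecting off-center values."""
    idx_f = (center - origin) * sign / res - 0.5
    idx = np.rint(idx_f).astype(int)
    expected = origin + sign * (idx + 0.5) * res
    bad = (np.abs(center - expected) > 1e-6) | (idx < 0) | (idx >= n)
    if bad.any():
        rows = np.nonzero(bad)[0][:5].tolist()
        raise DataError(
            f"{axis} coordinates are not cell centers on this grid "
            f"(first offending input rows: {rows})"
        )
    return idx


def read_probability_maps(
    source: str | Path | pd.DataFrame, spec: GridSpec
) -> list[SpeciesProbabilityMap]:
    """Read a long table of per-cell species probabilities.

    Accepts a CSV or Parquet path, or a DataFrame, with columns
    ``species_id,kingdom,phylum,class,center_lon,center_lat,probability``.
    Coordinates must be cell centers (within 1e-6°); duplicate
    (species, cell) rows and probabilities outside [0, 1] are rejected;
    zero-probability rows are dropped from the sparse maps.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix == ".parquet":
            df = pd.read_parquet(path)
        else:
            df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"species table missing columns: {missing}")

    prob = pd.to_numeric(df["probability"], errors="coerce").to_numpy()
    if np.isnan(prob).any() or (prob < 0).any() or (prob > 1).any():
        bad = np.nonzero(np.isnan(prob) | (prob < 0) | (prob > 1))[0][:5].tolist()
        raise DataError(f"probabilities outside [0, 1] (first offending rows: {bad})")

    rows = _coord_to_index(df["center_lat"].to_numpy(float), LAT_ORIGIN, -1.0,
                           spec.resolution_deg, spec.n_rows, "latitude")
    cols = _coord_to_index(df["center_lon"].to_numpy(float), LON_ORIGIN, 1.0,
                           spec.resolution_deg, spec.n_cols, "longitude")
    df = df.assign(_row=rows, _col=cols, probability=prob)

    dup = df.duplicated(subset=["species_id", "_row", "_col"], keep=False)
    if dup.any():
        bad = df.index[dup][:5].tolist()
        raise DataError(f"duplicate (species, cell) rows (first offending rows: {bad})")

    df = df[df["probability"] > 0.0]
    maps: list[SpeciesProbabilityMap] = []
    for sid, grp in df.groupby("species_id", sort=True):
        first = grp.iloc[0]
        maps.append(
            SpeciesProbabilityMap(
                species_id=str(sid),
                kingdom=str(first["kingdom"]),
                phylum=str(first["phylum"]),
                class_name=str(first["class"]),
                cells={
                    (int(r), int(c)): float(p)
                    for r, c, p in zip(grp["_row"], grp["_col"], grp["probability"])
                },
            )
        )
    return maps


def maps_to_frame(maps: list[SpeciesProbabilityMap], spec: GridSpec) -> pd.DataFrame:
    """Long-table form of a list of probability maps (the CSV dialect)."""
    res = spec.resolution_deg
    records = []
    for m in maps:
        for (r, c), p in sorted(m.cells.items()):
            records.append(
                (
                    m.species_id,
                    m.kingdom,
                    m.phylum,
                    m.class_name,
                    LON_ORIGIN + (c + 0.5) * res,
                    LAT_ORIGIN - (r + 0.5) * res,
                    p,
                )
            )
    return pd.DataFrame(records, columns=CSV_COLUMNS)


def write_probability_maps(
    maps: list[SpeciesProbabilityMap], path: str | Path, spec: GridSpec
) -> None:
    """Write maps in the long CSV (or Parquet) dialect; round-trips exactly."""
    df = maps_to_frame(maps, spec)
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.12g")


def threshold_range(
    pmap: SpeciesProbabilityMap, t: float, areas: np.ndarray
) -> SpeciesRange:
    """Binary range at threshold ``t``: probability >= t (t > 0) or > 0 (t = 0)."""
    if not 0.0 <= t <= 1.0:
        raise ConfigError(f"threshold {t} outside [0, 1]")
    if t == 0.0:
        cells = frozenset(pmap.cells)
    else:
        cells = frozenset(cell for cell, p in pmap.cells.items() if p >= t)
    area = float(sum(areas[r, c] for r, c in cells))
    return SpeciesRange(
        species_id=pmap.species_id, threshold=t, cells=cells, range_area_km2=area
    )


def median_range_size(ranges: list[SpeciesRange]) -> float:
    """Median of range areas (km²); mean of the two central values when even."""
    if not ranges:
        raise DataError("median_range_size: empty range list")
    return float(np.median([r.range_area_km2 for r in ranges]))
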