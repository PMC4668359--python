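"""Orchestrated experiments: the threshold sweep and the four-subset table.

Sensitivity of the representation statistics to the occurrence-probability
threshold is tested by sweeping t over 0–1 against a fixed protection
raster (rasterization is threshold-independent, so one raster is reused).
By range nesting, the gap proportion is non-decreasing and the median range
size non-increasing in t — a theorem, asserted on every run.

The subset table recomputes the whole pipeline per protected-area subset at
one fixed threshold (0.5 by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .gap_analysis import BIN_ORDER, species_coverage, summarize_bins
from .grid import GridSpec
from .mpa_subsets import (
    ProtectedAreaRecord,
    ProtectionRaster,
    build_protection_raster,
    total_protected_area,
)
from .species_ranges import (
    SpeciesProbabilityMap,
    median_range_size,
    threshold_range,
)

logger = logging.getLogger(__name__)

__all__ = ["SweepConfig", "run_threshold_sweep", "run_subset_table"]

BIN_COLUMNS = {
    "GAP": "pct_gap",
    "C0_2": "pct_0_2",
    "C2_5": "pct_2_5",
    "C5_10": "pct_5_10",
    "C10_PLUS": "pct_10_plus",
}


@dataclass(frozen=True)
class SweepConfig:
    """Thresholds and subsets for the orchestrated experiments."""

    thresholds: tuple[float, ...] = (0.0, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0)
    subsets: tuple[int, ...] = (4,)

    def __post_init__(self) -> None:
        ts = self.thresholds
        if not ts:
            raise ConfigError("SweepConfig needs at least one threshold")
        if any(not 0.0 <= t <= 1.0 for t in ts):
            raise ConfigError("thresholds must lie in [0, 1]")
        if list(ts) != sorted(set(ts)):
            raise ConfigError("thresholds must be sorted ascending without duplicates")
        if any(s not in (1, 2, 3, 4) for s in self.subsets):
            raise ConfigError("subsets must be drawn from {1, 2, 3, 4}")


def _coverage_rows(
    maps: Sequence[SpeciesProbabilityMap],
    raster: ProtectionRaster,
    areas: np.ndarray,
    threshold: float,
) -> tuple[list, list]:
    """Coverage results and ranges at one threshold; empty ranges excluded."""
    results, ranges, excluded = [], [], 0
    for pmap in maps:
        rng = threshold_range(pmap, threshold, areas)
        if not rng.cells:
            excluded += 1
            continue
        ranges.append(rng)
        results.append(species_coverage(rng, raster, areas))
    if excluded:
        logger.info(
            "threshold %.2f: excluded %d species with empty ranges", threshold, excluded
        )
    return results, ranges


def run_threshold_sweep(
    maps: Sequence[SpeciesProbabilityMap],
    raster: ProtectionRaster,
    areas: np.ndarray,
    config: SweepConfig = SweepConfig(),
) -> pd.DataFrame:
    """One row per threshold: median range size and bin percentages.

    Species whose range is empty at a threshold are excluded from that row
    (their coverage is undefined) and counted in ``n_excluded``.
    """
    if not maps:
        raise DataError("run_threshold_sweep: no species maps")
    rows = []
    for t in config.thresholds:
        results, ranges = _coverage_rows(maps, raster, areas, t)
        if not results:
            raise DataError(f"threshold {t}: every species had an empty range")
        summary = summarize_bins(results, total_protected_area(raster, areas))
        row = {
            "threshold": t,
            "n_species": summary.n_species,
            "n_excluded": len(maps) - summary.n_species,
            "median_range_km2": median_range_size(ranges),
        }
        row.update(
            {BIN_COLUMNS[b.value]: summary.proportions[b] for b in BIN_ORDER}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_subset_table(
    maps: Sequence[SpeciesProbabilityMap],
    records: Sequence[ProtectedAreaRecord],
    ocean_mask: np.ndarray,
    areas: np.ndarray,
    spec: GridSpec,
    threshold: float = 0.5,
    subsets: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """One row per protected-area subset at a fixed threshold."""
    if not maps:
        raise DataError("run_subset_table: no species maps")
    rows = []
    for subset in subsets:
        raster = build_protection_raster(records, subset, ocean_mask, spec)
        results, _ = _coverage_rows(maps, raster, areas, threshold)
        if not results:
            raise DataError(f"subset {subset}: every species had an empty range")
        total = total_protected_area(raster, areas)
        summary = summarize_bins(results, total)
        row = {
            "subset": subset,
            "total_area_km2": total,
            "n_species": summary.n_species,
        }
        row.update(
            {BIN_COLUMNS[b.value]: summary.proportions[b] for b in BIN_ORDER}
        )
        rows.append(row)
    return pd.DataFrame(rows)
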