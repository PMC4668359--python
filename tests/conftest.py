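import numpy as np
import pytest

from mpagap.grid import GridSpec, cell_areas
from mpagap.synthetic import SyntheticWorldConfig, TaxonGroup

# Small taxa for coarse-grid test worlds: bounded range sizes keep BFS cheap.
SMALL_TAXA = (
    TaxonGroup("Animalia", "Chordata", "Actinopterygii", 0.5, (3, 60)),
    TaxonGroup("Animalia", "Chordata", "Mammalia", 0.1, (20, 200)),
    TaxonGroup("Animalia", "Mollusca", "Gastropoda", 0.4, (2, 30)),
)


@pytest.fixture(scope="session")
def coarse_spec() -> GridSpec:
    """A 5° grid (36 x 72): cheap enough for randomized worlds."""
    return GridSpec(resolution_deg=5.0)


@pytest.fixture(scope="session")
def coarse_areas(coarse_spec) -> np.ndarray:
    return cell_areas(coarse_spec)


def small_world_config(seed: int, **overrides) -> SyntheticWorldConfig:
    """A small randomized world on the coarse grid."""
    kwargs = dict(
        seed=seed,
        grid=GridSpec(resolution_deg=5.0),
        n_species=20,
        n_mpas=10,
        n_islands=4,
        n_regions=4,
        taxa=SMALL_TAXA,
        mpa_size_deg=(1.0, 12.0),
        eez_band_cells=2,
    )
    kwargs.update(overrides)
    return SyntheticWorldConfig(**kwargs)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; never call pipeline internals)

def oracle_cell_fraction(geom, row: int, col: int, spec: GridSpec, n: int = 50) -> float:
    """Protected fraction of a cell by dense point sampling.

    Points on a regular n x n lattice of sub-cell centers, weighted by
    cos(latitude) since spherical area density varies within the cell.
    """
    import shapely

    from mpagap.grid import cell_bounds

    lat_min, lat_max, lon_min, lon_max = cell_bounds(row, col, spec)
    step_lat = (lat_max - lat_min) / n
    step_lon = (lon_max - lon_min) / n
    lats = lat_min + (np.arange(n) + 0.5) * step_lat
    lons = lon_min + (np.arange(n) + 0.5) * step_lon
    lon_g, lat_g = np.meshgrid(lons, lats)
    weights = np.cos(np.radians(lat_g))
    inside = shapely.intersects_xy(geom, lon_g.ravel(), lat_g.ravel()).reshape(n, n)
    return float((weights * inside).sum() / weights.sum())


def oracle_species_coverage(cells, fractions, areas):
    """Brute-force coverage: plain Python accumulation over range cells."""
    covered = 0.0
    total = 0.0
    any_protected = False
    for r, c in cells:
        covered += fractions[r][c] * areas[r][c]
        total += areas[r][c]
        if fractions[r][c] != 0.0:
            any_protected = True
    return covered / total, total, not any_protected


def oracle_bin_label(coverage: float, is_gap: bool) -> str:
    if is_gap:
        return "GAP"
    if coverage < 0.02:
        return "C0_2"
    if coverage < 0.05:
        return "C2_5"
    if coverage < 0.10:
        return "C5_10"
    return "C10_PLUS"


def oracle_cell_area(lat_min_deg: float, lat_max_deg: float, dlon_deg: float,
                     radius_km: float, steps: int = 20000) -> float:
    """Cell area by fine Riemann quadrature of R² cosφ dφ dλ."""
    phis = np.linspace(np.radians(lat_min_deg), np.radians(lat_max_deg), steps + 1)
    mid = (phis[:-1] + phis[1:]) / 2.0
    dphi = phis[1] - phis[0]
    return float(radius_km**2 * np.radians(dlon_deg) * np.sum(np.cos(mid) * dphi))
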