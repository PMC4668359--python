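"""Subset predicates, dissolve semantics, and the partial-fraction rasterizer."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from mpagap.errors import ConfigError, DataError
from mpagap.grid import GridSpec, cell_areas, cell_bounds
from mpagap.mpa_subsets import (
    ProtectedAreaRecord,
    build_protection_raster,
    dissolve,
    normalize_iucn,
    rasterize_protection,
    select_subset,
    spherical_area_km2,
    split_antimeridian,
    total_protected_area,
)

from .conftest import oracle_cell_fraction

SPEC = GridSpec(resolution_deg=5.0)
AREAS = cell_areas(SPEC)


def record(geom, marine=None, iucn="UNASSIGNED", pa_id="PA1"):
    return ProtectedAreaRecord(pa_id=pa_id, geometry=geom, marine_flag=marine,
                               iucn_category=iucn)


@pytest.fixture
def all_ocean():
    return np.ones((SPEC.n_rows, SPEC.n_cols), dtype=bool)


class TestRecordValidation:
    def test_missing_category_becomes_unassigned(self):
        rec = record(box(0, 0, 5, 5), iucn=None)
        assert rec.iucn_category == "UNASSIGNED"

    def test_unknown_category_rejected(self):
        with pytest.raises(DataError):
            record(box(0, 0, 5, 5), iucn="VII")

    def test_point_records_rejected_with_message(self):
        from shapely.geometry import Point

        with pytest.raises(DataError, match="point-only"):
            record(Point(0, 0))

    @pytest.mark.parametrize("raw,expected", [("Ia", "Ia"), ("", "UNASSIGNED"),
                                              ("not assigned", "UNASSIGNED")])
    def test_category_normalization(self, raw, expected):
        assert normalize_iucn(raw) == expected


class TestSelectSubset:
    """The four subset definitions and their nesting."""

    def test_marine_flag_iucn_v_kept_by_1_and_2_only(self, all_ocean):
        recs = [record(box(0, 0, 10, 10), marine=True, iucn="V")]
        kept = {s: select_subset(recs, s, all_ocean, SPEC) for s in (1, 2, 3, 4)}
        assert [len(kept[s]) for s in (1, 2, 3, 4)] == [1, 1, 0, 0]

    def test_unflagged_iucn_ii_kept_by_1_and_4_only(self, all_ocean):
        recs = [record(box(0, 0, 10, 10), marine=False, iucn="II")]
        kept = {s: select_subset(recs, s, all_ocean, SPEC) for s in (1, 2, 3, 4)}
        assert [len(kept[s]) for s in (1, 2, 3, 4)] == [1, 0, 0, 1]

    def test_unassigned_never_passes_strict_subsets(self, all_ocean):
        recs = [record(box(0, 0, 10, 10), marine=True, iucn="UNASSIGNED")]
        for s in (3, 4):
            assert select_subset(recs, s, all_ocean, SPEC) == []
        for s in (1, 2):
            assert len(select_subset(recs, s, all_ocean, SPEC)) == 1

    def test_land_locked_polygon_fails_ocean_subsets(self):
        ocean = np.ones((SPEC.n_rows, SPEC.n_cols), dtype=bool)
        ocean[:, :36] = False  # western hemisphere is land
        recs = [record(box(-100, 0, -90, 10), marine=True, iucn="II")]
        assert select_subset(recs, 1, ocean, SPEC) == []
        assert select_subset(recs, 4, ocean, SPEC) == []
        assert len(select_subset(recs, 2, ocean, SPEC)) == 1

    def test_subset_nesting(self, all_ocean):
        rng = np.random.default_rng(5)
        cats = ["Ia", "II", "IV", "V", "VI", "UNASSIGNED"]
        recs = []
        for i in range(30):
            lon, lat = rng.uniform(-170, 160), rng.uniform(-80, 70)
            recs.append(
                record(box(lon, lat, lon + 8, lat + 8),
                       marine=bool(rng.random() < 0.7),
                       iucn=cats[int(rng.integers(len(cats)))], pa_id=f"P{i}")
            )
        kept = {s: {r.pa_id for r in select_subset(recs, s, all_ocean, SPEC)}
                for s in (1, 2, 3, 4)}
        assert kept[3] <= kept[2]
        assert kept[4] <= kept[1]

    def test_unknown_subset_rejected(self, all_ocean):
        with pytest.raises(ConfigError):
            select_subset([], 5, all_ocean, SPEC)


class TestDissolve:
    def test_identical_polygons_union_is_idempotent(self):
        g = box(0, 0, 10, 10)
        merged = dissolve([record(g, pa_id="A"), record(g, pa_id="B")])
        assert merged.area == pytest.approx(g.area)

    def test_disjoint_polygons_sum(self):
        merged = dissolve([record(box(0, 0, 5, 5), pa_id="A"),
                           record(box(20, 0, 25, 5), pa_id="B")])
        assert merged.area == pytest.approx(50.0)

    def test_half_overlapping_cells(self):
        """Two 50%-overlapping unit squares dissolve to 1.5 squares."""
        merged = dissolve([record(box(0, 0, 1, 1), pa_id="A"),
                           record(box(0.5, 0, 1.5, 1), pa_id="B")])
        assert merged.area == pytest.approx(1.5)

    def test_invalid_bowtie_repaired(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        assert not bowtie.is_valid
        merged = dissolve([record(bowtie)])
        assert merged.is_valid
        assert merged.area == pytest.approx(2.0)


class TestRasterize:
    def test_cell_coincident_polygon_fills_exactly_one_cell(self):
        lat_min, lat_max, lon_min, lon_max = cell_bounds(10, 20, SPEC)
        raster = rasterize_protection(box(lon_min, lat_min, lon_max, lat_max), SPEC)
        assert raster.fractions[10, 20] == pytest.approx(1.0, abs=1e-12)
        frac = raster.fractions.copy()
        frac[10, 20] = 0.0
        assert np.all(frac == 0.0)

    def test_empty_geometry_gives_zero_raster(self):
        raster = rasterize_protection(Polygon(), SPEC)
        assert np.all(raster.fractions == 0.0)
        assert total_protected_area(raster, AREAS) == 0.0

    def test_western_half_cell(self):
        """A rectangle over the western lon-half of an equatorial cell."""
        lat_min, lat_max, lon_min, lon_max = cell_bounds(17, 36, SPEC)
        half = box(lon_min, lat_min, (lon_min + lon_max) / 2, lat_max)
        raster = rasterize_protection(half, SPEC)
        assert raster.fractions[17, 36] == pytest.approx(0.5, abs=3 / 2500)

    def test_fractions_match_point_sampling_oracle(self):
        """Random sub-lattice-aligned boxes vs the 50x50 weighted oracle.

        Coordinates are snapped to 1/50-cell multiples so no polygon edge
        can fall on a sample point: the midpoint oracle is then exact up to
        its cosine weighting, and 3/2500 is pure rasterizer slack.
        """
        rng = np.random.default_rng(11)
        snap = SPEC.resolution_deg / 50.0
        for trial in range(10):
            lon = snap * round(rng.uniform(-160, 140) / snap)
            lat = snap * round(rng.uniform(-70, 55) / snap)
            w = snap * rng.integers(5, 140)
            h = snap * rng.integers(5, 120)
            geom = box(lon, lat, lon + w, lat + h)
            raster = rasterize_protection(geom, SPEC)
            rr, cc = np.nonzero(raster.fractions)
            assert len(rr) > 0
            for r, c in zip(rr, cc):
                oracle = oracle_cell_fraction(geom, r, c, SPEC, n=50)
                assert raster.fractions[r, c] == pytest.approx(
                    oracle, abs=3 / 2500
                ), f"trial {trial} cell {(r, c)}"

    def test_oblique_polygons_within_lattice_coherence(self):
        """Free convex polygons: the lattice oracle itself is only O(1/50)
        accurate when an edge runs near a sample row, so the bound is 1.5e-2."""
        rng = np.random.default_rng(12)
        for _ in range(6):
            lon = rng.uniform(-160, 140)
            lat = rng.uniform(-70, 55)
            pts = np.c_[lon + rng.uniform(0, 14, 7), lat + rng.uniform(0, 12, 7)]
            hull = Polygon(pts).convex_hull
            raster = rasterize_protection(hull, SPEC)
            rr, cc = np.nonzero(raster.fractions)
            for r, c in zip(rr, cc):
                oracle = oracle_cell_fraction(hull, r, c, SPEC, n=50)
                assert raster.fractions[r, c] == pytest.approx(oracle, abs=1.5e-2)

    def test_monotone_under_adding_polygons(self):
        a = dissolve([record(box(0, 0, 12, 9))])
        b = dissolve([record(box(0, 0, 12, 9)), record(box(30, -20, 44, -6))])
        fa = rasterize_protection(a, SPEC).fractions
        fb = rasterize_protection(b, SPEC).fractions
        assert np.all(fb >= fa - 1e-15)

    def test_overlap_needs_dissolve(self):
        """Naive per-polygon fraction sums exceed 1; dissolved ones do not."""
        g1, g2 = box(0, 0, 5, 5), box(0, 0, 5, 5)
        naive = (rasterize_protection(g1, SPEC).fractions
                 + rasterize_protection(g2, SPEC).fractions)
        assert naive.max() > 1.0
        merged = dissolve([record(g1, pa_id="A"), record(g2, pa_id="B")])
        assert rasterize_protection(merged, SPEC).fractions.max() <= 1.0 + 1e-12

    def test_antimeridian_box_splits_and_keeps_area(self):
        geom = split_antimeridian(box(177, 0, 183, 5))
        assert geom.bounds[0] >= -180 and geom.bounds[2] <= 180
        raster = rasterize_protection(geom, SPEC)
        west = raster.fractions[:, -1].sum()   # [175, 180) column
        east = raster.fractions[:, 0].sum()    # [-180, -175) column
        assert west > 0 and east > 0
        expected = spherical_area_km2(geom, SPEC)
        assert total_protected_area(raster, AREAS) == pytest.approx(expected, rel=1e-3)


class TestTotals:
    def test_full_equatorial_half_degree_cell(self):
        spec = GridSpec(resolution_deg=0.5)
        lat_min, lat_max, lon_min, lon_max = cell_bounds(179, 360, spec)
        raster = rasterize_protection(box(lon_min, lat_min, lon_max, lat_max), spec)
        total = total_protected_area(raster, cell_areas(spec))
        assert total == pytest.approx(3.09e3, rel=1e-2)

    def test_subset3_total_never_exceeds_subset2(self, all_ocean):
        rng = np.random.default_rng(3)
        cats = ["Ia", "II", "V", "UNASSIGNED"]
        recs = [
            record(box(lon := rng.uniform(-170, 160), lat := rng.uniform(-80, 70),
                       lon + 6, lat + 6),
                   marine=bool(rng.random() < 0.8),
                   iucn=cats[int(rng.integers(len(cats)))], pa_id=f"P{i}")
            for i in range(20)
        ]
        t2 = total_protected_area(
            build_protection_raster(recs, 2, all_ocean, SPEC), AREAS)
        t3 = total_protected_area(
            build_protection_raster(recs, 3, all_ocean, SPEC), AREAS)
        assert t3 <= t2 + 1e-9

    def test_grid_mismatch_rejected(self):
        raster = rasterize_protection(box(0, 0, 5, 5), SPEC)
        with pytest.raises(DataError):
            total_protected_area(raster, cell_areas(GridSpec(resolution_deg=2.0)))
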