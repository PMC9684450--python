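"""Container invariants and GeoTIFF/CSV round trips."""

import numpy as np
import pytest

import popdisagg.io as gio
from popdisagg import (
    BuildingCountMap,
    CensusTable,
    CoRegistrationError,
    GridSpec,
    HierarchyError,
    PopulationMap,
    RegionHierarchy,
    RegionMap,
    ValidationError,
)
from popdisagg.grids import CovariateStack, check_hierarchy_consistency


class TestGridSpec:
    @pytest.mark.parametrize("rows,cols,cell", [(0, 4, 100), (4, 0, 100), (4, 4, 0), (4, 4, -1)])
    def test_invalid_geometry_rejected(self, rows, cols, cell):
        with pytest.raises(ValidationError):
            GridSpec(rows, cols, cell_size=cell)

    def test_compatibility_requires_exact_match(self):
        a = GridSpec(4, 4)
        assert a.compatible(GridSpec(4, 4))
        assert not a.compatible(GridSpec(4, 5))
        assert not a.compatible(GridSpec(4, 4, origin=(10.0, 0.0)))


class TestContainers:
    def test_stack_channel_count_must_match_planes(self):
        with pytest.raises(ValidationError):
            CovariateStack(GridSpec(2, 2), ["a", "b"], np.zeros((2, 2, 1)))

    def test_stack_rejects_nonfinite_outside_mask(self):
        vals = np.zeros((2, 2, 1))
        vals[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            CovariateStack(GridSpec(2, 2), ["a"], vals)

    def test_building_counts_must_be_nonnegative_integers(self):
        with pytest.raises(ValidationError):
            BuildingCountMap(GridSpec(2, 2), -np.ones((2, 2), dtype=int))
        with pytest.raises(ValidationError):
            BuildingCountMap(GridSpec(2, 2), np.full((2, 2), 0.5))

    def test_region_ids_negative_rejected(self):
        with pytest.raises(ValidationError):
            RegionMap(GridSpec(2, 2), np.array([[-1, 0], [1, 2]]))

    def test_census_rejects_negative_and_duplicates(self):
        with pytest.raises(ValidationError):
            CensusTable("fine", {3: -5.0})
        t = CensusTable("fine", {1: 100, 2: 50})
        assert t.n_c == 2 and t.total == 150

    def test_empty_census_warns(self):
        with pytest.warns(UserWarning):
            t = CensusTable("fine", {})
        assert t.n_c == 0

    def test_population_map_rejects_negative(self):
        with pytest.raises(ValidationError):
            PopulationMap(GridSpec(2, 2), np.array([[1.0, -0.1], [0, 0]]))

    def test_hierarchy_consistency_checked_exactly(self):
        h = RegionHierarchy({1: 10, 2: 10})
        fine = CensusTable("fine", {1: 100, 2: 50})
        check_hierarchy_consistency(fine, CensusTable("coarse", {10: 150}), h)
        with pytest.raises(HierarchyError):
            check_hierarchy_consistency(fine, CensusTable("coarse", {10: 151}), h)


class TestRasterIO:
    def test_float_raster_round_trip(self, tmp_path):
        grid = GridSpec(4, 4, cell_size=100.0, origin=(500000.0, 9000000.0), crs_tag="EPSG:32736")
        arr = np.arange(16, dtype=np.float32).reshape(4, 4)
        gio.write_raster(tmp_path / "x.tif", arr, grid)
        back, bgrid, nodata, _ = gio.read_raster(tmp_path / "x.tif")
        np.testing.assert_allclose(back, arr, rtol=1e-6)
        assert bgrid.compatible(grid) and bgrid.crs_tag == "EPSG:32736"

    def test_population_raster_round_trip_and_adjusted_flag(self, tmp_path):
        grid = GridSpec(4, 4)
        pop = PopulationMap(grid, np.random.default_rng(0).gamma(1, 2, (4, 4)), adjusted=True)
        gio.write_population_raster(pop, tmp_path / "p.tif")
        back = gio.read_population_raster(tmp_path / "p.tif")
        np.testing.assert_allclose(back.values, pop.values, rtol=1e-6)
        assert back.adjusted is True

    def test_covariate_stack_assembly_and_manifest(self, tmp_path):
        grid = GridSpec(4, 4)
        rng = np.random.default_rng(0)
        paths = []
        for i in range(17):
            p = tmp_path / f"c{i:02d}.tif"
            gio.write_raster(p, rng.normal(size=(4, 4)).astype(np.float32), grid)
            paths.append(p)
        stack = gio.read_covariate_stack(paths[:1], ["nightlight"])
        assert stack.n_channels == 1 and stack.grid.shape == (4, 4)
        stack17 = gio.read_covariate_stack(paths, [f"cov{i}" for i in range(17)])
        assert stack17.n_channels == 17

    def test_coregistration_mismatch_rejected(self, tmp_path):
        gio.write_raster(tmp_path / "a.tif", np.zeros((4, 4), np.float32), GridSpec(4, 4))
        gio.write_raster(tmp_path / "b.tif", np.zeros((4, 5), np.float32), GridSpec(4, 5))
        with pytest.raises(CoRegistrationError):
            gio.read_covariate_stack([tmp_path / "a.tif", tmp_path / "b.tif"], ["a", "b"])

    def test_nodata_cells_imputed_and_flagged(self, tmp_path):
        grid = GridSpec(2, 2)
        arr = np.array([[1.0, 3.0], [-99999.0, 5.0]], dtype=np.float32)
        gio.write_raster(tmp_path / "x.tif", arr, grid, nodata=-99999.0)
        stack = gio.read_covariate_stack([tmp_path / "x.tif"], ["x"])
        assert stack.nodata_mask[1, 0]
        assert stack.values[1, 0, 0] == pytest.approx(3.0)  # mean of valid


class TestTableIO:
    def test_census_round_trip(self, tmp_path):
        (tmp_path / "c.csv").write_text("region_id,population\n1,100\n2,50\n")
        t = gio.read_census_table(tmp_path / "c.csv", "fine")
        assert t.n_c == 2 and t.total == 150
        gio.write_census_table(t, tmp_path / "c2.csv")
        t2 = gio.read_census_table(tmp_path / "c2.csv", "fine")
        assert t2.entries == t.entries

    def test_census_validation_errors(self, tmp_path):
        (tmp_path / "neg.csv").write_text("region_id,population\n3,-5\n")
        with pytest.raises(ValidationError):
            gio.read_census_table(tmp_path / "neg.csv", "fine")
        (tmp_path / "dup.csv").write_text("region_id,population\n1,5\n1,6\n")
        with pytest.raises(ValidationError):
            gio.read_census_table(tmp_path / "dup.csv", "fine")

    def test_region_map_with_hierarchy(self, tmp_path):
        grid = GridSpec(2, 2)
        gio.write_raster(tmp_path / "r.tif", np.array([[1, 1], [2, 0]], dtype=np.int32),
                         grid, nodata=-1)
        (tmp_path / "h.csv").write_text("fine_id,coarse_id\n1,10\n2,10\n")
        regions, hier = gio.load_region_map(tmp_path / "r.tif", tmp_path / "h.csv")
        assert set(regions.region_ids().tolist()) == {1, 2}
        assert (regions.ids == 0).sum() == 1
        assert hier.coarse_of(1) == 10 and hier.members(10) == [1, 2]

    def test_region_id_missing_from_hierarchy_rejected(self, tmp_path):
        grid = GridSpec(2, 2)
        gio.write_raster(tmp_path / "r.tif", np.array([[7, 1], [2, 0]], dtype=np.int32),
                         grid, nodata=-1)
        (tmp_path / "h.csv").write_text("fine_id,coarse_id\n1,10\n2,10\n")
        with pytest.raises(HierarchyError):
            gio.load_region_map(tmp_path / "r.tif", tmp_path / "h.csv")


def test_landscape_directory_round_trip(tmp_path, small_landscape):
    gio.write_landscape(small_landscape, tmp_path / "land")
    back = gio.read_landscape(tmp_path / "land")
    np.testing.assert_allclose(
        back.covariates.values, small_landscape.covariates.values, rtol=1e-5, atol=1e-5
    )
    np.testing.assert_array_equal(back.buildings.counts, small_landscape.buildings.counts)
    np.testing.assert_array_equal(back.regions.ids, small_landscape.regions.ids)
    assert back.census_fine.entries == small_landscape.census_fine.entries
    assert back.census_coarse.entries == small_landscape.census_coarse.entries
    assert back.hierarchy.fine_to_coarse == small_landscape.hierarchy.fine_to_coarse
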