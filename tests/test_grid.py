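import numpy as np
import pandas as pd
import pytest

import heatrun as hr
from heatrun.grid import GridFormatError, TimeAxis, _interval_overlap_matrix


class TestCellArea:
    def test_equatorial_quarter_degree_cell(self):
        # closed-form band area for a 0.25 deg cell centered on the equator
        expected = 6371.0**2 * np.radians(0.25) * 2 * np.sin(np.radians(0.125))
        assert hr.cell_area_km2(0.0, 0.25) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(772.6, abs=0.2)

    @pytest.mark.parametrize("lat", [0.0, 12.5, 45.0, 89.875])
    def test_hemispheric_symmetry(self, lat):
        assert hr.cell_area_km2(lat, 0.25) == pytest.approx(
            hr.cell_area_km2(-lat, 0.25)
        )

    def test_global_sum_matches_sphere(self):
        lats = -90 + 0.25 * (np.arange(720) + 0.5)
        band = np.array([hr.cell_area_km2(phi, 0.25) for phi in lats])
        total = band.sum() * 1440  # every longitude column is identical
        sphere = 4 * np.pi * 6371.0**2
        assert abs(total - sphere) / sphere < 1e-3

    def test_out_of_range_latitude_rejected(self):
        with pytest.raises(ValueError):
            hr.cell_area_km2(91.0, 0.25)


class TestGridDefinition:
    def test_irregular_spacing_rejected(self):
        with pytest.raises(ValueError, match="irregular|ascending"):
            hr.GridDefinition(
                np.array([0.0, 0.25, 0.6]), np.array([0.0, 0.25]), 0.25,
                np.ones((3, 2), dtype=bool),
            )

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="land_mask"):
            hr.GridDefinition(
                np.array([0.0, 0.25]), np.array([0.0, 0.25]), 0.25,
                np.ones((3, 2), dtype=bool),
            )


class TestAggregation:
    def test_nested_block_sum(self, small_grid):
        fine = hr.generate_population(
            hr.SyntheticPopulationConfig(fine_factor=2, total_population=100, seed=1),
            small_grid,
        )
        fine.counts[:] = np.array(
            [[10, 20, 1, 1], [30, 40, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]], float
        )
        coarse = hr.aggregate_population_to_grid(fine, small_grid)
        assert coarse.counts[0, 0] == pytest.approx(100.0)
        assert coarse.total() == pytest.approx(fine.total())

    def test_na_cells_skipped(self, small_grid):
        fine = hr.generate_population(
            hr.SyntheticPopulationConfig(fine_factor=2, total_population=100, seed=1),
            small_grid,
        )
        fine.counts[:] = 0.0
        fine.counts[0, 0] = 10
        fine.counts[0, 1] = np.nan
        fine.counts[1, 0] = 30
        fine.counts[1, 1] = 40
        coarse = hr.aggregate_population_to_grid(fine, small_grid)
        assert coarse.counts[0, 0] == pytest.approx(80.0)

    def test_non_nested_matches_rectangle_overlap_oracle(self):
        rng = np.random.default_rng(42)
        fine_g = hr.GridDefinition(
            0.07 + 0.1 * np.arange(8), 10.03 + 0.1 * np.arange(9), 0.1,
            np.ones((8, 9), dtype=bool),
        )
        counts = rng.uniform(0, 50, size=(8, 9))
        fine = hr.PopulationGrid(fine_g, 2000, counts)
        target = hr.GridDefinition(
            np.array([0.1, 0.35, 0.6]), np.array([10.1, 10.35, 10.6]), 0.25,
            np.ones((3, 3), dtype=bool),
        )
        got = hr.aggregate_population_to_grid(fine, target).counts

        def overlap(lo1, hi1, lo2, hi2):
            return max(0.0, min(hi1, hi2) - max(lo1, lo2))

        expected = np.zeros((3, 3))
        for a, la in enumerate(target.lat):
            for b, lo in enumerate(target.lon):
                for i, fla in enumerate(fine_g.lat):
                    for j, flo in enumerate(fine_g.lon):
                        w = (
                            overlap(la - 0.125, la + 0.125, fla - 0.05, fla + 0.05)
                            * overlap(lo - 0.125, lo + 0.125, flo - 0.05, flo + 0.05)
                            / 0.01
                        )
                        expected[a, b] += counts[i, j] * w
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_conservation_when_fine_nests(self, small_grid):
        fine = hr.generate_population(
            hr.SyntheticPopulationConfig(fine_factor=4, total_population=12345, seed=3),
            small_grid,
        )
        coarse = hr.aggregate_population_to_grid(fine, small_grid)
        assert coarse.total() == pytest.approx(12345.0)

    def test_disjoint_extents_rejected(self, small_grid):
        far = hr.GridDefinition(
            np.array([50.0, 50.25]), np.array([0.0, 0.25]), 0.25,
            np.ones((2, 2), dtype=bool),
        )
        fine = hr.PopulationGrid(far, 2000, np.ones((2, 2)))
        with pytest.raises(ValueError, match="disjoint"):
            hr.aggregate_population_to_grid(fine, small_grid)


class TestNetcdfRoundTrip:
    def test_synthetic_cube_round_trips_bit_exactly(self, quiet_config, tmp_path):
        temp = hr.generate_daily_temperature(quiet_config(n_years=2))
        path = tmp_path / "t.nc"
        temp.to_netcdf(path)
        back = hr.read_temperature_netcdf(path)
        np.testing.assert_array_equal(back.tmax, temp.tmax)
        np.testing.assert_array_equal(back.tmin, temp.tmin)
        np.testing.assert_array_equal(back.time.year, temp.time.year)
        np.testing.assert_array_equal(back.time.month, temp.time.month)
        assert back.time.calendar == "noleap"

    def test_kelvin_units_converted(self, tmp_path):
        import xarray as xr

        ds = xr.Dataset(
            {
                "tmax": (("time", "lat", "lon"), np.full((3, 1, 1), 300.0)),
                "tmin": (("time", "lat", "lon"), np.full((3, 1, 1), 295.0)),
            },
            coords={"time": [0.0, 1.0, 2.0], "lat": [5.0], "lon": [100.0]},
        )
        for v in ("tmax", "tmin"):
            ds[v].attrs["units"] = "K"
        ds["time"].attrs["units"] = "days since 2000-01-01"
        ds["time"].attrs["calendar"] = "standard"
        path = tmp_path / "k.nc"
        ds.to_netcdf(path, engine="scipy")
        cube = hr.read_temperature_netcdf(path)
        assert cube.tmax[0, 0, 0] == pytest.approx(26.85)
        assert cube.time.calendar == "standard"

    def test_descending_latitude_flipped_value_invariant(self, tmp_path):
        import xarray as xr

        rng = np.random.default_rng(0)
        tmax = rng.uniform(25, 35, size=(4, 3, 2))
        ds = xr.Dataset(
            {
                "tmax": (("time", "lat", "lon"), tmax),
                "tmin": (("time", "lat", "lon"), tmax - 5.0),
            },
            coords={"time": np.arange(4.0), "lat": [2.5, 2.25, 2.0], "lon": [100.0, 100.25]},
        )
        ds["time"].attrs["units"] = "days since 2000-01-01"
        path = tmp_path / "desc.nc"
        ds.to_netcdf(path, engine="scipy")
        cube = hr.read_temperature_netcdf(path)
        assert np.all(np.diff(cube.grid.lat) > 0)
        # value at coordinate (lat=2.5) must match the original first row
        k = int(np.flatnonzero(cube.grid.lat == 2.5)[0])
        np.testing.assert_allclose(cube.tmax[:, k, :], tmax[:, 0, :])

    def test_missing_variable_named_in_error(self, quiet_config, tmp_path):
        temp = hr.generate_daily_temperature(quiet_config(n_years=1))
        path = tmp_path / "t.nc"
        temp.to_netcdf(path)
        with pytest.raises(GridFormatError, match="nope"):
            hr.read_temperature_netcdf(path, var_names=("nope", "tmin"))


class TestAsciiRaster:
    def test_round_trip_and_nodata(self, small_grid, tmp_path):
        pop = hr.generate_population(
            hr.SyntheticPopulationConfig(
                fine_factor=2, total_population=500, na_fraction=0.2, seed=5
            ),
            small_grid,
        )
        path = tmp_path / "pop.asc"
        hr.write_ascii_grid(pop, path)
        back = hr.read_population_raster(path, 2000)
        np.testing.assert_array_equal(np.isnan(back.counts), np.isnan(pop.counts))
        np.testing.assert_allclose(back.counts[~np.isnan(back.counts)],
                                   pop.counts[~np.isnan(pop.counts)])
        assert back.grid.lat == pytest.approx(pop.grid.lat)

    def test_aggregate_after_read_conserves_total(self, small_grid, tmp_path):
        pop = hr.generate_population(
            hr.SyntheticPopulationConfig(fine_factor=3, total_population=777, seed=9),
            small_grid,
        )
        path = tmp_path / "pop.asc"
        hr.write_ascii_grid(pop, path)
        coarse = hr.aggregate_population_to_grid(
            hr.read_population_raster(path, 2000), small_grid
        )
        assert coarse.total() == pytest.approx(777.0)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\n1 2\n")
        with pytest.raises(GridFormatError, match="header"):
            hr.read_population_raster(path, 2000)


class TestExportCsv:
    def test_round_trip_lossless_doubles(self, tmp_path):
        df = pd.DataFrame({"year": [2000, 2001], "x": [1 / 3, np.pi * 1e6]})
        path = tmp_path / "t.csv"
        hr.export_csv(df, path)
        back = pd.read_csv(path)
        np.testing.assert_array_equal(back["x"].to_numpy(), df["x"].to_numpy())
        assert "." in path.read_text()  # locale-independent decimal point

    def test_empty_frame_writes_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["year", "AHW"])
        path = tmp_path / "e.csv"
        hr.export_csv(df, path)
        assert path.read_text().strip() == "year,AHW"


class TestTimeAxis:
    def test_noleap_year_has_365_days(self):
        ax = TimeAxis.noleap_range(1961, 2)
        assert len(ax) == 730
        assert ax.doy[364] == 365 and ax.doy[365] == 1

    def test_gap_in_standard_axis_rejected(self):
        dates = pd.to_datetime(["2000-01-01", "2000-01-03"])
        with pytest.raises(ValueError, match="gap-free"):
            TimeAxis.from_datetimes(dates)

    def test_interval_overlap_rows_sum_to_one_when_covered(self):
        w = _interval_overlap_matrix(
            0.05 + 0.1 * np.arange(10), 0.1, np.array([0.25, 0.75]), 0.5
        )
        np.testing.assert_allclose(w.sum(axis=0), 1.0)
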