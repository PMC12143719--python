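import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forestmap import (
    GridTransform,
    MapTileSpec,
    encode_uint16,
    output_filename,
    parse_output_filename,
    parse_tile_id,
    read_geotiff,
    read_plot_table,
    tile_id_for,
    write_geotiff,
    write_map_tile,
    write_plot_table,
    write_raster_stack,
    read_raster_stack,
)
from forestmap.core import (
    NODATA_CODE,
    NONFOREST_CODE,
    SchemaError,
    TableParseError,
    tile_corner_for,
    validate_plot_table,
)


def _plot_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["plot_id", "easting", "northing", "year", "country", "vol", "agb", "dcp"],
    )


class TestPlotTable:
    def test_well_formed_rows_pass(self, tmp_path):
        df = _plot_frame([
            ("a", 4e6, 2.5e6, 2020, "AT", 120.0, 80.0, 60.0),
            ("b", 4e6 + 100, 2.5e6, 2020, "AT", 0.0, 0.0, 0.0),
            ("c", 4e6 + 200, 2.5e6, 2021, "AT", 300.0, 180.0, 100.0),
        ])
        path = write_plot_table(df, tmp_path / "plots.csv")
        out, diags = read_plot_table(path)
        assert len(out) == 3 and diags == []

    def test_out_of_range_dcp_rejected_with_diagnostic(self):
        df = _plot_frame([
            ("a", 0.0, 0.0, 2020, "AT", 1.0, 1.0, 140.0),
            ("b", 0.0, 0.0, 2020, "AT", 1.0, 1.0, 40.0),
        ])
        out, diags = validate_plot_table(df)
        assert list(out["plot_id"]) == ["b"]
        assert len(diags) == 1 and "dcp" in diags[0] and "'a'" in diags[0]

    @pytest.mark.parametrize(
        "mutate, reason",
        [
            (lambda df: df.assign(vol=[-1.0, 2.0]), "vol"),
            (lambda df: df.assign(agb=[np.nan, 2.0]), "non-finite"),
            (lambda df: df.assign(plot_id=["a", "a"]), "duplicate"),
        ],
    )
    def test_invariant_violations_rejected(self, mutate, reason):
        df = mutate(_plot_frame([
            ("a", 0.0, 0.0, 2020, "AT", 1.0, 1.0, 10.0),
            ("b", 0.0, 0.0, 2020, "AT", 1.0, 1.0, 10.0),
        ]))
        out, diags = validate_plot_table(df)
        assert len(out) == 1
        assert reason in diags[0]

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="dcp"):
            validate_plot_table(pd.DataFrame({"plot_id": ["a"]}))

    def test_non_numeric_cell_is_parse_error(self):
        df = _plot_frame([("a", "oops", 0.0, 2020, "AT", 1.0, 1.0, 10.0)])
        with pytest.raises(TableParseError, match="easting"):
            validate_plot_table(df)

    def test_synthetic_table_round_trips(self, small_scene, tmp_path):
        _, _, _, plots = small_scene
        path = write_plot_table(plots, tmp_path / "rt.csv")
        out, diags = read_plot_table(path)
        assert diags == []
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), plots, check_exact=False, rtol=0, atol=1e-9
        )


class TestTileGrid:
    @pytest.mark.parametrize(
        "e, n",
        [
            (3_950_000, 2_450_000),  # worked example from the published naming
            (3_900_000, 2_400_000),  # corner belongs to its own (half-open) tile
            (4_399_999, 2_899_999),  # far corner of the same half-open square
        ],
    )
    def test_known_points_map_to_E39_N24(self, e, n):
        assert tile_id_for(e, n) == "E39_N24"

    @settings(derandomize=True, max_examples=200)
    @given(
        e=st.floats(1e6, 7e6, allow_nan=False),
        n=st.floats(1e6, 6e6, allow_nan=False),
        de=st.floats(-6e5, 6e5),
        dn=st.floats(-6e5, 6e5),
    )
    def test_tiles_partition_the_plane(self, e, n, de, dn):
        """Two points share a label iff they lie in the same half-open square."""
        c1 = tile_corner_for(e, n)
        c2 = tile_corner_for(e + de, n + dn)
        same_square = c1 == c2
        assert (tile_id_for(e, n) == tile_id_for(e + de, n + dn)) == same_square
        # every corner is a multiple of 100 km and contains its point
        for c, v in zip(c1, (e, n)):
            assert c % 100_000 == 0
            assert c <= v < c + 500_000

    def test_tile_label_round_trip(self):
        assert parse_tile_id("E39_N24") == (3_900_000, 2_400_000)


class TestOutputNaming:
    def test_published_worked_example(self):
        spec = MapTileSpec(year=2020, variable="stdev_vol", tile_e=39, tile_n=24)
        assert output_filename(spec) == "2020_stdev_vol_E39_N24.tif"

    @pytest.mark.parametrize("variable", ["AGB", "P_agb_conifers", "stdev_agb"])
    def test_filename_round_trip(self, variable):
        spec = MapTileSpec(year=2020, variable=variable, tile_e=39, tile_n=24)
        assert parse_output_filename(output_filename(spec)) == spec

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown output variable"):
            MapTileSpec(year=2020, variable="volume", tile_e=39, tile_n=24)


class TestEncoding:
    def test_rounding_sentinels_and_clamp(self):
        values = np.array([[123.5, 7.0], [70_000.0, 1.2]])
        forest = np.array([[True, False], [True, True]])
        valid = np.array([[True, True], [True, False]])
        enc = encode_uint16(values, forest, valid)
        assert enc[0, 0] == 124  # half away from zero
        assert enc[0, 1] == NONFOREST_CODE
        assert enc[1, 0] == 65533  # clamped
        assert enc[1, 1] == NODATA_CODE

    def test_negative_value_is_an_error(self):
        with pytest.raises(ValueError, match="negative"):
            encode_uint16(np.array([-1.0]), np.array([True]), np.array([True]))

    def test_idempotent_and_half_unit_preserving(self, rng):
        values = rng.uniform(0, 600, size=(20, 20))
        forest = rng.random((20, 20)) > 0.3
        valid = rng.random((20, 20)) > 0.1
        enc = encode_uint16(values, forest, valid)
        again = encode_uint16(enc.astype(float), forest, valid)
        assert np.array_equal(enc, again)
        use = valid & forest
        assert np.abs(enc[use].astype(float) - values[use]).max() <= 0.5


class TestGeoTiff:
    def test_value_and_georeferencing_round_trip(self, tmp_path):
        transform = GridTransform(origin_e=3_900_000, origin_n=2_900_000, pixel=10.0)
        arr = np.arange(12, dtype=np.float32).reshape(3, 4)
        path = write_geotiff(tmp_path / "x.tif", arr, transform, epsg=3035, nodata=-9999)
        back, tback, epsg, nodata = read_geotiff(path)
        assert np.array_equal(back, arr)
        assert tback == transform
        assert epsg == 3035 and nodata == -9999

    def test_map_tile_write(self, tmp_path):
        spec = MapTileSpec(year=2020, variable="AGB", tile_e=39, tile_n=24)
        enc = np.full((5, 5), 42, dtype=np.uint16)
        path = write_map_tile(spec, enc, tmp_path)
        assert path.name == "2020_AGB_E39_N24.tif"
        back, transform, epsg, nodata = read_geotiff(path)
        assert np.array_equal(back, enc)
        assert nodata == NODATA_CODE and epsg == 3035
        # georeferencing reproduces the tile's lower-left corner
        xmin, ymin, _, _ = transform.extent(back.shape)
        assert (xmin, ymin) == (3_900_000, 2_400_000)

    def test_missing_crs_is_config_error(self, tmp_path):
        from forestmap.core import ConfigError

        spec = MapTileSpec(year=2020, variable="AGB", tile_e=39, tile_n=24)
        with pytest.raises(ConfigError, match="CRS"):
            write_map_tile(spec, np.zeros((2, 2), np.uint16), tmp_path, epsg=None)

    def test_raster_stack_round_trip(self, small_scene, tmp_path):
        _, _, stack, _ = small_scene
        read_back = read_raster_stack(write_raster_stack(stack, tmp_path / "stack"))
        for name, arr in stack.bands.items():
            assert np.array_equal(read_back.bands[name], arr), name
        assert np.array_equal(read_back.gfc, stack.gfc)
        assert read_back.transform == stack.transform
        assert read_back.gfc_transform == stack.gfc_transform
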