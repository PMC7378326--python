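"""Affine transforms, circular masking, tile cropping and geo I/O."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, Point, Polygon

from orchardyield.geodata import (GeoRaster, circular_mask, crop_tree_tile,
                                  make_transform, pixel_to_world, read_raster,
                                  read_vector, world_to_pixel, write_raster,
                                  write_vector)
from orchardyield.synthetic import TreeRecord


def tree_at(x, y, tid="t0"):
    return TreeRecord(tree_id=tid, row_index=0, position_in_row=0, world_xy=(x, y))


class TestAffine:
    def test_origin_maps_to_pixel_corner(self):
        t = make_transform(0.0, 0.0, 1.0)
        assert tuple(world_to_pixel(t, (0.0, 0.0))) == (0.0, 0.0)

    def test_one_meter_east_at_orthomosaic_gsd(self):
        t = make_transform(0.0, 0.0, 0.00418)
        col, row = world_to_pixel(t, (1.0, 0.0))
        assert col == pytest.approx(1 / 0.00418)  # 239.234...
        assert row == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(x=st.floats(-1e4, 1e4), y=st.floats(-1e4, 1e4),
           ox=st.floats(-100, 100), oy=st.floats(-100, 100),
           gsd=st.floats(1e-3, 10.0))
    def test_round_trip_exact_to_nanometer(self, x, y, ox, oy, gsd):
        t = make_transform(ox, oy, gsd)
        back = pixel_to_world(t, world_to_pixel(t, (x, y)))
        assert abs(back[0] - x) < 1e-9 and abs(back[1] - y) < 1e-9


def brute_force_mask(raster, center, diameter):
    """Pixel-by-pixel oracle for circle membership via pixel centers."""
    out = np.zeros((raster.height, raster.width), dtype=bool)
    for r in range(raster.height):
        for c in range(raster.width):
            x, y = pixel_to_world(raster.transform, (c + 0.5, r + 0.5))
            out[r, c] = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= (diameter / 2) ** 2
    return out


class TestCircularMask:
    def setup_method(self):
        self.raster = GeoRaster(np.zeros((5, 5, 3), np.uint8),
                                make_transform(0.0, 5.0, 1.0))

    def test_plus_shape_for_two_meter_circle(self):
        # center at the center pixel's center, diameter exactly 2 m:
        # the 4-neighbours are at distance 1 = radius, diagonals sqrt(2) > 1
        mask = circular_mask(self.raster, (2.5, 2.5), 2.0)
        assert mask.sum() == 5
        assert mask[2, 2] and mask[1, 2] and mask[3, 2] and mask[2, 1] and mask[2, 3]
        np.testing.assert_array_equal(mask, brute_force_mask(self.raster, (2.5, 2.5), 2.0))

    def test_subpixel_circle_catches_exactly_one_center(self):
        mask = circular_mask(self.raster, (1.5, 3.5), 0.5)
        assert mask.sum() == 1 and mask[1, 1]

    def test_circle_spanning_raster_is_all_true(self):
        assert circular_mask(self.raster, (2.5, 2.5), 20.0).all()

    def test_missing_circle_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            mask = circular_mask(self.raster, (100.0, 100.0), 1.0)
        assert not mask.any()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle_on_random_circles(self, seed):
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        gsd = float(rng.uniform(0.1, 2.0))
        raster = GeoRaster(np.zeros((h, w, 3), np.uint8),
                           make_transform(rng.uniform(-5, 5), rng.uniform(-5, 5), gsd))
        center = (float(rng.uniform(-2, w * gsd + 2)), float(rng.uniform(-2, h * gsd + 2)))
        diameter = float(rng.uniform(0.2, 8.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = circular_mask(raster, center, diameter)
        np.testing.assert_array_equal(mask, brute_force_mask(raster, center, diameter))


class TestCropTreeTile:
    def test_masked_pixel_sum_equals_value_times_cardinality(self):
        pixels = np.full((20, 20, 3), 7, np.uint8)
        raster = GeoRaster(pixels, make_transform(0.0, 20.0, 1.0))
        tile = crop_tree_tile(raster, tree_at(10.0, 10.0), 8.0)
        assert tile.raster.pixels.sum() == 7 * tile.mask.sum() * 3

    def test_interior_tile_width_matches_diameter(self):
        raster = GeoRaster(np.zeros((200, 200, 3), np.uint8),
                           make_transform(0.0, 2.0, 0.01))
        tile = crop_tree_tile(raster, tree_at(1.0, 1.0), 1.0)
        expect = int(np.ceil(1.0 / 0.01))
        assert abs(tile.raster.width - expect) <= 1
        assert abs(tile.raster.height - expect) <= 1

    def test_window_offset_preserves_world_position(self):
        raster = GeoRaster(np.zeros((50, 50, 3), np.uint8),
                           make_transform(0.0, 50.0, 1.0))
        tile = crop_tree_tile(raster, tree_at(25.0, 25.0), 10.0)
        # the tile's origin pixel is window_offset in the parent
        parent_xy = pixel_to_world(raster.transform,
                                   (tile.window_offset[0], tile.window_offset[1]))
        tile_xy = pixel_to_world(tile.raster.transform, (0.0, 0.0))
        np.testing.assert_allclose(parent_xy, tile_xy, atol=1e-12)

    def test_cropping_is_idempotent_for_same_circle(self):
        rng = np.random.default_rng(3)
        raster = GeoRaster(rng.integers(0, 255, (40, 40, 3)).astype(np.uint8),
                           make_transform(0.0, 40.0, 1.0))
        tree = tree_at(20.0, 20.0)
        once = crop_tree_tile(raster, tree, 12.0)
        twice = crop_tree_tile(once.raster, tree, 12.0)
        np.testing.assert_array_equal(once.raster.pixels, twice.raster.pixels)
        assert twice.window_offset == (0, 0)

    def test_missing_tree_error_names_the_tree(self):
        raster = GeoRaster(np.zeros((5, 5, 3), np.uint8), make_transform(0, 5, 1.0))
        with pytest.raises(ValueError, match="t99"):
            crop_tree_tile(raster, tree_at(500.0, 500.0, "t99"), 1.0)


class TestRasterIO:
    def test_geotiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        raster = GeoRaster(rng.integers(0, 255, (12, 9, 3)).astype(np.uint8),
                           make_transform(123.4, 567.8, 0.00418), crs="EPSG:4326")
        write_raster(raster, tmp_path / "x.tif")
        back = read_raster(tmp_path / "x.tif")
        np.testing.assert_array_equal(back.pixels, raster.pixels)
        np.testing.assert_allclose(back.transform, raster.transform)
        assert back.crs == "EPSG:4326"

    def test_unknown_extension_rejected(self, tmp_path):
        raster = GeoRaster(np.zeros((2, 2, 3), np.uint8), make_transform(0, 2, 1))
        with pytest.raises(ValueError, match="extension"):
            write_raster(raster, tmp_path / "x.png")
        with pytest.raises(ValueError):
            read_raster(tmp_path / "x.jpg")

    def test_malformed_tiff_rejected(self, tmp_path):
        (tmp_path / "bad.tif").write_bytes(b"not a tiff at all")
        with pytest.raises(ValueError):
            read_raster(tmp_path / "bad.tif")


FEATURES = [
    {"geometry": Point(1.5, 2.5),
     "properties": {"tree_id": "r00t00", "row_index": 0, "fruit_count": 41}},
    {"geometry": Point(4.5, 2.5),
     "properties": {"tree_id": "r01t00", "row_index": 1, "fruit_count": 7}},
]


class TestVectorIO:
    @pytest.mark.parametrize("ext", ["geojson", "shp"])
    def test_point_attribute_round_trip(self, tmp_path, ext):
        write_vector(FEATURES, tmp_path / f"trees.{ext}")
        back = read_vector(tmp_path / f"trees.{ext}")
        assert len(back) == 2
        for orig, rt in zip(FEATURES, back):
            assert rt["geometry"].equals_exact(orig["geometry"], 1e-9)
            for key, val in orig["properties"].items():
                assert rt["properties"][key[:10] if ext == "shp" else key] == val

    def test_polyline_and_polygon_round_trip_shapefile(self, tmp_path):
        feats = [{"geometry": LineString([(0, 0), (3, 1), (5, 0)]),
                  "properties": {"row_index": 0}}]
        write_vector(feats, tmp_path / "lines.shp")
        back = read_vector(tmp_path / "lines.shp")
        assert back[0]["geometry"].equals_exact(feats[0]["geometry"], 1e-9)

        poly = [{"geometry": Polygon([(0, 0), (2, 0), (2, 2), (0, 2)]),
                 "properties": {"fruit_count": 12}}]
        mapping = write_vector(poly, tmp_path / "poly.shp")
        rt = read_vector(tmp_path / "poly.shp")[0]
        assert rt["geometry"].equals(poly[0]["geometry"])
        assert rt["properties"][mapping["fruit_count"]] == 12

    def test_shapefile_field_name_truncation_map(self, tmp_path):
        feats = [{"geometry": Point(0, 0),
                  "properties": {"position_in_row": 3, "position_in_block": 5}}]
        mapping = write_vector(feats, tmp_path / "t.shp")
        # both names collide at 10 chars; the map documents unique renames
        assert mapping["position_in_row"] != mapping["position_in_block"]
        assert all(len(v) <= 10 for v in mapping.values())
        props = read_vector(tmp_path / "t.shp")[0]["properties"]
        assert props[mapping["position_in_row"]] == 3
        assert props[mapping["position_in_block"]] == 5

    def test_unknown_extension_and_malformed_file(self, tmp_path):
        with pytest.raises(ValueError, match="extension"):
            write_vector(FEATURES, tmp_path / "x.gpkg")
        (tmp_path / "bad.geojson").write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_vector(tmp_path / "bad.geojson")
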