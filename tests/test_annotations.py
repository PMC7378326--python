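"""VOC I/O conventions, tiling bookkeeping, rotation and intensity maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardyield.annotations import (AnnotationSet, AugmentParams, BBox,
                                      augment_dataset, brightness_contrast,
                                      read_voc, rotate, tile_image, write_voc)

VOC_SAMPLE = """<annotation>
  <folder>images</folder><filename>tile_001</filename>
  <size><width>416</width><height>416</height><depth>3</depth></size>
  <object><name>apple</name>
    <bndbox><xmin>1</xmin><ymin>1</ymin><xmax>10</xmax><ymax>10</ymax></bndbox>
  </object>
</annotation>
"""


class TestVocIO:
    def test_one_based_inclusive_becomes_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.xml"
        p.write_text(VOC_SAMPLE)
        ann = read_voc(p)
        assert (ann.width, ann.height) == (416, 416)
        b = ann.boxes[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (0, 0, 10, 10)

    def test_empty_object_list(self, tmp_path):
        p = tmp_path / "e.xml"
        p.write_text("<annotation><size><width>10</width>"
                     "<height>10</height></size></annotation>")
        assert read_voc(p).boxes == []

    def test_write_read_identity_and_bit_stability(self, tmp_path):
        ann = AnnotationSet("img", 100, 80,
                            [BBox(0, 0, 10, 10), BBox(30, 40, 55, 61, score=0.75)])
        write_voc(ann, tmp_path / "w.xml")
        back = read_voc(tmp_path / "w.xml")
        assert back.boxes == ann.boxes
        assert (back.width, back.height) == (100, 80)
        write_voc(back, tmp_path / "w2.xml")
        assert (tmp_path / "w.xml").read_bytes() == (tmp_path / "w2.xml").read_bytes()

    def test_missing_elements_named_in_error(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<annotation><object><bndbox><xmin>1</xmin></bndbox>"
                     "</object></annotation>")
        with pytest.raises(ValueError, match="size"):
            read_voc(p)


class TestTiling:
    def test_single_tile_image_passes_through(self):
        img = np.zeros((416, 416, 3), np.uint8)
        ann = AnnotationSet("i", 416, 416, [BBox(5, 5, 30, 30)])
        tiles = tile_image(img, ann)
        assert len(tiles) == 1
        assert tiles[0][1].boxes == ann.boxes

    def test_straddling_box_appears_clipped_in_both_tiles(self):
        img = np.zeros((416, 832, 3), np.uint8)
        ann = AnnotationSet("i", 832, 416, [BBox(400, 100, 432, 132)])
        tiles = tile_image(img, ann, min_visibility=0.25)
        assert len(tiles) == 2
        left, right = tiles[0][1], tiles[1][1]
        assert left.boxes[0] == BBox(400, 100, 416, 132)
        assert right.boxes[0] == BBox(0, 100, 16, 132)

    def test_full_visibility_drops_straddling_boxes(self):
        img = np.zeros((416, 832, 3), np.uint8)
        ann = AnnotationSet("i", 832, 416, [BBox(400, 100, 432, 132)])
        tiles = tile_image(img, ann, min_visibility=1.0)
        assert all(not t[1].boxes for t in tiles)

    def test_remainder_tiles_keep_native_size(self):
        img = np.zeros((500, 900, 3), np.uint8)
        tiles = tile_image(img, AnnotationSet("i", 900, 500, []))
        sizes = {t[0].shape[:2] for t in tiles}
        assert sizes == {(416, 416), (416, 68), (84, 416), (84, 68)}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_clipped_area_fully_accounted_before_filter(self, seed):
        """Tiling partitions each box's area across tiles (min_visibility=0)."""
        rng = np.random.default_rng(seed)
        w, h = int(rng.integers(50, 900)), int(rng.integers(50, 900))
        img = np.zeros((h, w, 3), np.uint8)
        boxes = []
        for _ in range(5):
            x0, y0 = rng.uniform(0, w - 2), rng.uniform(0, h - 2)
            boxes.append(BBox(x0, y0, min(w, x0 + rng.uniform(1, 60)),
                              min(h, y0 + rng.uniform(1, 60))))
        ann = AnnotationSet("i", w, h, boxes)
        tiles = tile_image(img, ann, tile_size=137, min_visibility=0.0)
        clipped_area = sum(b.area for _, t in tiles for b in t.boxes)
        assert clipped_area == pytest.approx(sum(b.area for b in boxes))


def rotated_box_by_mask_oracle(box: BBox, w: int, h: int, angle: int) -> BBox:
    """Rasterize the box, rotate the mask with np.rot90, take extents."""
    mask = np.zeros((h, w), bool)
    mask[int(box.ymin):int(box.ymax), int(box.xmin):int(box.xmax)] = True
    for _ in range(angle // 90):
        mask = np.rot90(mask, k=-1)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BBox(cols[0], rows[0], cols[-1] + 1, rows[-1] + 1, label=box.label)


class TestRotation:
    def test_quarter_turn_clockwise_example(self):
        img = np.zeros((200, 100, 3), np.uint8)
        ann = AnnotationSet("i", 100, 200, [BBox(10, 20, 30, 40)])
        _, out = rotate(img, ann, 90)
        b = out.boxes[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (160, 10, 180, 30)

    def test_half_turn_twice_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (60, 40, 3)).astype(np.uint8)
        ann = AnnotationSet("i", 40, 60, [BBox(3, 5, 17, 30)])
        img2, ann2 = rotate(*rotate(img, ann, 180), 180)
        np.testing.assert_array_equal(img2, img)
        assert ann2.boxes == ann.boxes

    def test_other_angles_rejected(self):
        img = np.zeros((4, 4, 3), np.uint8)
        with pytest.raises(ValueError):
            rotate(img, AnnotationSet("i", 4, 4, []), 45)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(seed=st.integers(0, 100_000),
           angle=st.sampled_from([90, 180, 270]))
    def test_remap_matches_mask_rotation_oracle(self, seed, angle):
        rng = np.random.default_rng(seed)
        w, h = int(rng.integers(5, 80)), int(rng.integers(5, 80))
        x0, y0 = int(rng.integers(0, w - 1)), int(rng.integers(0, h - 1))
        box = BBox(x0, y0, int(rng.integers(x0 + 1, w + 1)),
                   int(rng.integers(y0 + 1, h + 1)))
        img = np.zeros((h, w, 3), np.uint8)
        _, out = rotate(img, AnnotationSet("i", w, h, [box]), angle)
        assert out.boxes[0] == rotated_box_by_mask_oracle(box, w, h, angle)
        assert out.boxes[0].area == box.area  # rigid motion


class TestBrightnessContrast:
    @pytest.mark.parametrize("value,alpha,beta,expected", [
        (100, 1.0, 0.0, 100),   # identity
        (100, 1.2, 10.0, 130),  # direct arithmetic
        (250, 1.1, 0.0, 255),   # clipped at the top
        (10, 1.0, -50.0, 0),    # clipped at the bottom
    ])
    def test_linear_map_with_clipping(self, value, alpha, beta, expected):
        img = np.full((2, 2, 3), value, np.uint8)
        assert brightness_contrast(img, alpha, beta)[0, 0, 0] == expected

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            brightness_contrast(np.zeros((2, 2, 3), np.uint8), 0.0, 1.0)


class TestAugmentation:
    def _dataset(self, n):
        rng = np.random.default_rng(0)
        out = []
        for i in range(n):
            img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
            out.append((img, AnnotationSet(f"img{i}", 16, 16,
                                           [BBox(2, 2, 9, 9)])))
        return out

    def test_factor_three_config_triples_the_dataset(self):
        params = AugmentParams(rotations=(90, 180))
        assert params.expansion_factor == 3
        out = augment_dataset(self._dataset(1000), params)
        assert len(out) == 3000

    def test_empty_input_gives_empty_output(self):
        assert augment_dataset([], AugmentParams(rotations=(90,))) == []

    def test_every_output_annotation_is_valid(self):
        out = augment_dataset(self._dataset(10),
                              AugmentParams(rotations=(90, 270), alpha=1.2, beta=8))
        assert len(out) == 40
        for img, ann in out:
            ann.validate()
            assert img.shape[:2] == (ann.height, ann.width)
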