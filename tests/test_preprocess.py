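"""Photometric/geometric preprocessing and the seeded split."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from paniclecount.annotations_io import AnnotatedImage, BoundingBox, DatasetManifest
from paniclecount.preprocess import (
    PAPER_SPLIT_FRACTIONS,
    EnhancementParams,
    SplitSpec,
    augment,
    enhance,
    resize_with_boxes,
    split_dataset,
    source_id,
)


def _image(h=256, w=256, value=100, boxes=()):
    return AnnotatedImage(
        "img", np.full((h, w, 3), value, dtype=np.uint8), list(boxes)
    )


class TestEnhance:
    def test_identity_factors_leave_pixels_unchanged(self):
        params = EnhancementParams(*(1.0,) * 8)
        img = _image(64, 64, 77)
        for v in enhance(img, params):
            assert np.array_equal(v.pixels, img.pixels)

    def test_brightness_factor_is_linear_scale(self):
        """Brightness 1.2 on uniform gray 100 gives uniform 120."""
        img = _image(32, 32, 100)
        out = {v.image_id: v for v in enhance(img)}
        bright = out["img__brightness_enh"]
        assert np.all(bright.pixels == 120)
        dim = out["img__brightness_att"]
        assert np.all(dim.pixels == 60)

    def test_default_params_give_eight_variants(self):
        box = BoundingBox(5, 5, 20, 20)
        variants = enhance(_image(boxes=[box]))
        assert len(variants) == 8
        # photometric ops never move boxes
        assert all(v.boxes == [box] for v in variants)
        assert all(v.pixels.dtype == np.uint8 for v in variants)

    def test_factors_must_be_positive(self):
        with pytest.raises(ValueError):
            EnhancementParams(brightness_enh=0.0)

    def test_defaults_match_study_percentages(self):
        p = EnhancementParams()
        assert (p.brightness_enh, p.brightness_att) == (1.20, 0.60)
        assert (p.chroma_enh, p.chroma_att) == (1.20, 0.60)
        assert (p.contrast_enh, p.contrast_att) == (1.20, 0.60)
        assert (p.sharpness_enh, p.sharpness_att) == (2.00, 0.10)


class TestAugment:
    def test_mirror_box_mapping(self):
        box = BoundingBox(10, 20, 30, 60)
        img = _image(256, 256, boxes=[box])
        mirror = next(v for v in augment(img) if v.image_id.endswith("mirror"))
        assert mirror.boxes == [BoundingBox(226, 20, 246, 60)]

    def test_rot180_is_involution(self):
        rng = np.random.default_rng(0)
        img = AnnotatedImage(
            "img", rng.integers(0, 255, (64, 48, 3), dtype=np.uint8),
            [BoundingBox(3, 7, 20, 30)],
        )
        r180 = next(v for v in augment(img) if v.image_id.endswith("rot180"))
        back = next(v for v in augment(r180) if v.image_id.endswith("rot180"))
        assert np.array_equal(back.pixels, img.pixels)
        assert back.boxes == img.boxes

    def test_rot90_pixel_oracle(self):
        """The rotated box covers exactly the rotated marked pixels."""
        h, w = 40, 64
        pixels = np.zeros((h, w, 3), dtype=np.uint8)
        box = BoundingBox(10, 5, 25, 18)
        pixels[5:18, 10:25] = 255
        img = AnnotatedImage("img", pixels, [box])
        r90 = next(v for v in augment(img) if v.image_id.endswith("rot90"))
        assert r90.pixels.shape == (w, h, 3)
        ys, xs = np.nonzero(r90.pixels[:, :, 0])
        (b,) = r90.boxes
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (
            xs.min(), ys.min(), xs.max() + 1, ys.max() + 1
        )

    def test_three_variants_with_valid_boxes(self):
        img = _image(64, 32, boxes=[BoundingBox(0, 0, 10, 5)])
        variants = augment(img)
        assert len(variants) == 3
        for v in variants:
            vh, vw = v.size
            for b in v.boxes:
                assert 0 <= b.x_min < b.x_max <= vw
                assert 0 <= b.y_min < b.y_max <= vh

    def test_area_preserved(self):
        img = _image(64, 48, boxes=[BoundingBox(3, 7, 21, 30)])
        for v in augment(img):
            assert v.boxes[0].area == img.boxes[0].area


class TestResize:
    def test_identity_when_already_target(self):
        img = _image(256, 256, boxes=[BoundingBox(0, 0, 10, 10)])
        assert resize_with_boxes(img, (256, 256)) is img

    def test_downscale_by_half_scales_boxes(self):
        img = _image(512, 512, boxes=[BoundingBox(0, 0, 100, 100)])
        out = resize_with_boxes(img, (256, 256))
        assert out.size == (256, 256)
        assert out.boxes == [BoundingBox(0, 0, 50, 50)]

    def test_camera_native_frame_to_model_input(self):
        img = _image(3048, 5472, value=50)
        out = resize_with_boxes(img, (256, 256))
        assert out.size == (256, 256)

    def test_collapsing_box_dropped_with_warning(self, caplog):
        img = _image(512, 512, boxes=[BoundingBox(10, 10, 11, 11)])
        with caplog.at_level("WARNING"):
            out = resize_with_boxes(img, (64, 64))
        assert out.boxes == []
        assert "collapsed" in caplog.text

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            resize_with_boxes(_image(), (0, 256))


def _manifest(n, stem="img"):
    return DatasetManifest(
        [(Path(f"{stem}_{i:03d}.png"), Path(f"{stem}_{i:03d}.xml")) for i in range(n)]
    )


class TestSplit:
    def test_235_images_at_80_20(self):
        train, test = split_dataset(_manifest(235), SplitSpec(0.8, seed=3))
        assert (len(train), len(test)) == (188, 47)

    def test_even_half_split(self):
        train, test = split_dataset(_manifest(100), SplitSpec(0.5, seed=0))
        assert len(train) == len(test) == 50

    @pytest.mark.parametrize("fraction", PAPER_SPLIT_FRACTIONS)
    def test_study_fractions_partition_without_overlap(self, fraction):
        m = _manifest(235)
        train, test = split_dataset(m, SplitSpec(fraction, seed=1))
        train_set = {str(e[0]) for e in train}
        test_set = {str(e[0]) for e in test}
        assert not train_set & test_set
        assert train_set | test_set == {str(e[0]) for e in m}

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SplitSpec(1.0)
        with pytest.raises(ValueError):
            SplitSpec(0.0)

    def test_variants_stay_on_one_side(self):
        entries = []
        for i in range(20):
            for tag in ("", "__mirror", "__rot90", "__brightness_enh"):
                entries.append(
                    (Path(f"img_{i:03d}{tag}.png"), Path(f"img_{i:03d}{tag}.xml"))
                )
        train, test = split_dataset(DatasetManifest(entries), SplitSpec(0.6, seed=9))
        train_src = {source_id(e[0].stem) for e in train}
        test_src = {source_id(e[0].stem) for e in test}
        assert not train_src & test_src

    def test_deterministic_given_seed(self):
        m = _manifest(50)
        a = split_dataset(m, SplitSpec(0.8, seed=5))
        b = split_dataset(m, SplitSpec(0.8, seed=5))
        c = split_dataset(m, SplitSpec(0.8, seed=6))
        assert a[0].entries == b[0].entries
        assert a[0].entries != c[0].entries

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(DatasetManifest([]), SplitSpec(0.8))
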