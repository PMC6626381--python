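"""Patch-set construction: positives, negatives, resizing, validation crops."""

import datetime as dt

import numpy as np
import pytest

import headingdate as hd
from headingdate.core import ValidationError
from headingdate.patches import (LABEL_FLOWER, LABEL_NON_FLOWER,
                                 build_validation_crops, load_patches,
                                 save_patches)


class TestPositives:
    def test_exact_count_and_label(self, small_series):
        patches = hd.extract_positive_patches(small_series, 4, size=32, seed=0)
        assert len(patches) == 4
        assert all(p.label == LABEL_FLOWER for p in patches)
        assert all(p.pixels.shape == (32, 32, 3) for p in patches)

    def test_requesting_more_than_available_warns(self, small_series):
        with pytest.warns(UserWarning, match="only 5"):
            patches = hd.extract_positive_patches(small_series, 99, size=32,
                                                  seed=0)
        assert len(patches) == 5

    def test_no_boxes_gives_empty_with_warning(self):
        params = hd.PhenologyParams(emergence_schedule={80: 0},
                                    images_per_day=1, rng_seed=0)
        series = hd.generate_field_series(params)
        with pytest.warns(UserWarning):
            assert hd.extract_positive_patches(series, 3, size=32, seed=0) == []

    def test_sampling_is_seeded(self, small_series):
        a = hd.extract_positive_patches(small_series, 1, size=32, seed=9)
        b = hd.extract_positive_patches(small_series, 1, size=32, seed=9)
        assert a[0].source_box == b[0].source_box
        assert np.array_equal(a[0].pixels, b[0].pixels)


class TestNegatives:
    def test_negatives_never_touch_ground_truth(self, small_series, window32):
        negs = hd.sample_negative_patches(small_series, 40, window32, seed=3)
        assert len(negs) == 40
        assert all(n.label == LABEL_NON_FLOWER for n in negs)
        gt = {img.image_id: img.gt_boxes for img in small_series}
        for n in negs:
            assert all(n.source_box.intersection_area(b) == 0
                       for b in gt[n.source_image_id])

    def test_fully_annotated_image_is_sampling_error(self, window32):
        px = np.zeros((80, 80, 3), dtype=np.uint8)
        img = hd.AnnotatedImage("full", px, dt.datetime(2013, 8, 1, 9, 0),
                                [hd.Box(0, 0, 80, 80)], 0)
        series = hd.ImageSeries("full", [img], dt.date(2013, 8, 1))
        with pytest.raises(ValidationError, match="0 of 5"):
            hd.sample_negative_patches(series, 5, window32, seed=0,
                                       max_attempts=50)


class TestResize:
    def test_resizes_to_target(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 255, (140, 140, 3), dtype=np.uint8)
        assert hd.resize_patch(patch, 224).shape == (224, 224, 3)

    def test_identity_at_target_size(self):
        rng = np.random.default_rng(1)
        patch = rng.integers(0, 255, (224, 224, 3), dtype=np.uint8)
        assert np.array_equal(hd.resize_patch(patch, 224), patch)

    def test_constant_patch_stays_constant(self):
        patch = np.full((37, 53, 3), 117, dtype=np.uint8)
        out = hd.resize_patch(patch, 64)
        assert np.all(out == 117)

    def test_zero_area_is_error(self):
        with pytest.raises(ValidationError):
            hd.resize_patch(np.zeros((0, 10, 3), dtype=np.uint8), 32)


@pytest.fixture(scope="module")
def series5():
    # 5 days x 3 slots = 15 images per series, at the default slot times
    return [hd.generate_field_series(hd.PhenologyParams(
                emergence_schedule={80 + d: 4 for d in range(5)},
                rng_seed=100 + i), name=f"s{i}")
            for i in range(2)]


class TestValidationCrops:

    def test_per_series_times_series_crops(self, series5):
        crops = build_validation_crops(series5, per_series=15, crop=320,
                                       seed=0)
        assert len(crops) == 2 * 15
        assert all(c.pixels.shape == (320, 320, 3) for c in crops)

    def test_equal_distribution_over_slots(self, series5):
        crops = build_validation_crops(series5[:1], per_series=15, crop=320,
                                       seed=0)
        hours = [c.timestamp.hour for c in crops]
        assert sorted(set(hours)) == [8, 11, 15]
        assert all(hours.count(h) == 5 for h in (8, 11, 15))

    def test_boxes_reexpressed_in_crop_coordinates(self, series5):
        crops = build_validation_crops(series5, per_series=15, crop=320,
                                       seed=1)
        assert any(c.gt_boxes for c in crops)
        for c in crops:
            for b in c.gt_boxes:
                assert b.fits_within(320, 320)

    def test_slot_with_too_few_images_names_slot(self):
        params = hd.PhenologyParams(emergence_schedule={80: 2, 81: 2},
                                    rng_seed=0)  # only 2 days -> 2 per slot
        series = hd.generate_field_series(params)
        with pytest.raises(ValidationError, match="slot"):
            build_validation_crops([series], per_series=15, crop=320, seed=0)

    def test_unequal_division_rejected(self, series5):
        with pytest.raises(ValidationError, match="divide"):
            build_validation_crops(series5, per_series=14, crop=320, seed=0)

    def test_gt_fully_outside_crop_is_dropped(self):
        px = np.zeros((200, 400, 3), dtype=np.uint8)
        img = hd.AnnotatedImage(
            "wide", px, dt.datetime(2013, 8, 1, 8, 30),
            [hd.Box(0, 0, 20, 20), hd.Box(380, 180, 400, 200)], 0)
        # crop pinned to the full height so only x varies: width 200 on a
        # 400-wide image can never contain both corner boxes
        series = hd.ImageSeries("wide", [img], dt.date(2013, 8, 1))
        crops = build_validation_crops(
            [series], per_series=1,
            slots=[(dt.time(8, 0), dt.time(9, 0))], crop=200, seed=0)
        assert len(crops) == 1
        assert len(crops[0].gt_boxes) <= 1


def test_patch_manifest_round_trip(tmp_path, small_series):
    patches = hd.extract_positive_patches(small_series, 3, size=32, seed=0)
    manifest = save_patches(patches, tmp_path)
    back = load_patches(manifest)
    assert len(back) == 3
    for a, b in zip(patches, back):
        assert np.array_equal(a.pixels, b.pixels)
        assert a.label == b.label
        assert a.source_image_id == b.source_image_id
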