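"""Domain types and annotation/detection CSV round-trips."""

import datetime as dt

import numpy as np
import pytest
from PIL import Image

import headingdate as hd
from headingdate.core import AnnotationError, ValidationError
from headingdate.detector import DetectionSet


def _blank_png(path, w=64, h=48):
    Image.fromarray(np.zeros((h, w, 3), dtype=np.uint8)).save(path)


class TestBox:
    @pytest.mark.parametrize("coords", [
        (0, 0, 0, 10),    # zero width
        (0, 0, 10, 0),    # zero height
        (5, 5, 5, 5),     # degenerate point
        (10, 0, 5, 10),   # inverted x
        (-1, 0, 5, 5),    # negative coordinate
    ])
    def test_invalid_boxes_rejected(self, coords):
        with pytest.raises(ValidationError):
            hd.Box(*coords)

    def test_half_open_area(self):
        assert hd.Box(2, 3, 7, 9).area == 5 * 6

    def test_intersection_area(self):
        a = hd.Box(0, 0, 10, 10)
        assert a.intersection_area(hd.Box(5, 0, 15, 10)) == 50
        assert a.intersection_area(hd.Box(20, 20, 30, 30)) == 0

    def test_clip_outside_returns_none(self):
        assert hd.Box(0, 0, 5, 5).clip(10, 10, 20, 20) is None


class TestSeriesInvariants:
    def test_duplicate_timestamps_rejected(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        ts = dt.datetime(2013, 8, 1, 9, 0)
        imgs = [hd.AnnotatedImage("a", px, ts, [], 62),
                hd.AnnotatedImage("b", px, ts, [], 62)]
        with pytest.raises(ValidationError, match="strictly increasing"):
            hd.ImageSeries("s", imgs, dt.date(2013, 5, 31))

    def test_day_index_must_match_elapsed_days(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        img = hd.AnnotatedImage("a", px, dt.datetime(2013, 8, 1, 9, 0), [], 5)
        with pytest.raises(ValidationError, match="day_index"):
            hd.ImageSeries("s", [img], dt.date(2013, 5, 31))

    def test_box_outside_image_rejected(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValidationError, match="img1"):
            hd.AnnotatedImage("img1", px, dt.datetime(2013, 8, 1, 9, 0),
                              [hd.Box(5, 5, 15, 15)], 0)


class TestReadAnnotations:
    def test_two_rows_one_image(self, tmp_path):
        _blank_png(tmp_path / "img1.png")
        (tmp_path / "ann.csv").write_text(
            "image_id,image_path,timestamp,x_min,y_min,x_max,y_max\n"
            "img1,img1.png,2013-08-01 09:00,0,0,10,10\n"
            "img1,img1.png,2013-08-01 09:00,20,20,30,30\n")
        series = hd.read_annotations(tmp_path / "ann.csv")
        assert len(series) == 1
        assert series.images[0].gt_boxes == [hd.Box(0, 0, 10, 10),
                                             hd.Box(20, 20, 30, 30)]

    def test_image_with_empty_coordinate_fields(self, tmp_path):
        _blank_png(tmp_path / "img1.png")
        (tmp_path / "ann.csv").write_text(
            "image_id,image_path,timestamp,x_min,y_min,x_max,y_max\n"
            "img1,img1.png,2013-08-01 09:00,,,,\n")
        series = hd.read_annotations(tmp_path / "ann.csv")
        assert len(series) == 1
        assert series.images[0].gt_boxes == []

    def test_inverted_box_is_parse_error_naming_line(self, tmp_path):
        _blank_png(tmp_path / "img1.png")
        (tmp_path / "ann.csv").write_text(
            "image_id,image_path,timestamp,x_min,y_min,x_max,y_max\n"
            "img1,img1.png,2013-08-01 09:00,10,0,5,10\n")
        with pytest.raises(AnnotationError, match="line 2"):
            hd.read_annotations(tmp_path / "ann.csv")

    def test_box_outside_image_names_image(self, tmp_path):
        _blank_png(tmp_path / "img1.png", w=32, h=32)
        (tmp_path / "ann.csv").write_text(
            "image_id,image_path,timestamp,x_min,y_min,x_max,y_max\n"
            "img1,img1.png,2013-08-01 09:00,0,0,100,100\n")
        with pytest.raises(ValidationError, match="img1"):
            hd.read_annotations(tmp_path / "ann.csv")

    def test_annotation_round_trip_lossless(self, tmp_path, small_series):
        path = tmp_path / "out.csv"
        images = {}
        for img in small_series:
            Image.fromarray(img.pixels).save(tmp_path / f"{img.image_id}.png")
            images[img.image_id] = f"{img.image_id}.png"
        hd.write_annotations(small_series, path, image_paths=images)
        back = hd.read_annotations(path)
        assert back.name == small_series.name
        assert back.transplanting_date == small_series.transplanting_date
        for a, b in zip(small_series, back):
            assert a.image_id == b.image_id
            assert a.timestamp == b.timestamp
            assert a.gt_boxes == b.gt_boxes
            assert a.day_index == b.day_index


class TestDetectionIO:
    @staticmethod
    def _random_detections(n_boxes, seed=0):
        rng = np.random.default_rng(seed)
        boxes, probs = [], []
        for _ in range(n_boxes):
            x, y = int(rng.integers(0, 5000)), int(rng.integers(0, 3300))
            boxes.append(hd.Box(x, y, x + 140, y + 140))
            probs.append(round(float(rng.uniform(0.5, 1.0)), 8))
        return DetectionSet("img1", dt.datetime(2013, 8, 1, 9, 0), None,
                            boxes, probs)

    def test_888_boxes_give_888_rows(self, tmp_path):
        det = self._random_detections(888)
        hd.write_detections(det, tmp_path / "det.csv")
        lines = [l for l in (tmp_path / "det.csv").read_text().splitlines()
                 if l and not l.startswith("#")]
        assert len(lines) == 1 + 888  # header + data

    def test_empty_set_writes_header_only(self, tmp_path):
        det = DetectionSet("img1", dt.datetime(2013, 8, 1, 9, 0), None)
        hd.write_detections(det, tmp_path / "det.csv")
        lines = [l for l in (tmp_path / "det.csv").read_text().splitlines()
                 if l and not l.startswith("#")]
        assert lines == ["image_id,timestamp,x_min,y_min,x_max,y_max,probability"]

    def test_round_trip_identity(self, tmp_path):
        det = self._random_detections(37, seed=5)
        hd.write_detections(det, tmp_path / "det.csv",
                            extra_header={"seed": "5"})
        (back,) = hd.read_detections(tmp_path / "det.csv")
        assert back.image_id == det.image_id
        assert back.timestamp == det.timestamp
        assert back.boxes == det.boxes
        assert back.probabilities == pytest.approx(det.probabilities, abs=1e-8)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            DetectionSet("x", dt.datetime(2013, 8, 1, 9, 0), None,
                         [hd.Box(0, 0, 1, 1)], [])
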