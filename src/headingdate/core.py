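"""Shared domain types, coordinate conventions, and annotation/detection I/O.

Coordinate convention
---------------------
All boxes are 0-based, half-open pixel rectangles: ``[x_min, x_max) x
[y_min, y_max)``, so ``area = (x_max - x_min) * (y_max - y_min)`` with no
off-by-one ambiguity.  Any 1-based or inclusive-end annotation dialect must
be converted at the I/O boundary; internal code only ever sees this
convention.

Day counting
------------
``day_index`` is the number of whole calendar days elapsed since the
transplanting date (transplanting day = day 0).  Output files record this
convention in their headers.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from PIL import Image

if TYPE_CHECKING:  # pragma: no cover
    from .detector import DetectionSet

TIMESTAMP_FMT = "%Y-%m-%d %H:%M"

ANNOTATION_FIELDS = ("image_id", "image_path", "timestamp",
                     "x_min", "y_min", "x_max", "y_max")
DETECTION_FIELDS = ("image_id", "timestamp",
                    "x_min", "y_min", "x_max", "y_max", "probability")


class AnnotationError(ValueError):
    """Malformed annotation/detection file (names the offending line)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True, order=True)
class Box:
    """Axis-aligned pixel rectangle, 0-based, half-open on both axes."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min < 0 or self.y_min < 0:
            raise ValidationError(f"negative box coordinates: {self}")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValidationError(f"box has non-positive area: {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "Box") -> int:
        """Pixel area of the overlap with ``other`` (0 if disjoint)."""
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        return w * h if (w > 0 and h > 0) else 0

    def shift(self, dx: int, dy: int) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy,
                   self.x_max + dx, self.y_max + dy)

    def clip(self, x_min: int, y_min: int, x_max: int, y_max: int) -> "Box | None":
        """Intersect with a clip window; None if nothing survives."""
        x0 = max(self.x_min, x_min)
        y0 = max(self.y_min, y_min)
        x1 = min(self.x_max, x_max)
        y1 = min(self.y_max, y_max)
        if x1 <= x0 or y1 <= y0:
            return None
        return Box(x0, y0, x1, y1)

    def fits_within(self, width: int, height: int) -> bool:
        return self.x_max <= width and self.y_max <= height


@dataclass
class AnnotatedImage:
    """A timestamped field image with its ground-truth panicle boxes."""

    image_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    timestamp: dt.datetime
    gt_boxes: list[Box] = field(default_factory=list)
    day_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"image {self.image_id!r}: pixels must be HxWx3, got {px.shape}")
        self.pixels = px
        h, w = px.shape[:2]
        for box in self.gt_boxes:
            if not box.fits_within(w, h):
                raise ValidationError(
                    f"image {self.image_id!r}: box {box} exceeds {w}x{h} bounds")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def crop(self, box: Box) -> np.ndarray:
        return self.pixels[box.y_min:box.y_max, box.x_min:box.x_max]


@dataclass
class ImageSeries:
    """Chronologically ordered annotated images of one field/camera."""

    name: str
    images: list[AnnotatedImage]
    transplanting_date: dt.date

    def __post_init__(self) -> None:
        for prev, cur in zip(self.images, self.images[1:]):
            if cur.timestamp <= prev.timestamp:
                raise ValidationError(
                    f"series {self.name!r}: timestamps not strictly increasing "
                    f"({prev.image_id!r} at {prev.timestamp} vs "
                    f"{cur.image_id!r} at {cur.timestamp})")
        for img in self.images:
            expected = (img.timestamp.date() - self.transplanting_date).days
            if img.day_index != expected:
                raise ValidationError(
                    f"series {self.name!r}, image {img.image_id!r}: day_index "
                    f"{img.day_index} != {expected} days since transplanting")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    @property
    def total_gt_boxes(self) -> int:
        return sum(len(img.gt_boxes) for img in self.images)


@dataclass
class WindowConfig:
    """Sliding-window geometry plus classifier input/threshold settings.

    Defaults for ``classifier_input_size`` (224) and
    ``probability_threshold`` (0.5) follow the detection pipeline's standard
    operating point; per-dataset window dimensions live in
    :data:`headingdate.detector.DEFAULT_WINDOW_CONFIGS`.
    """

    window_w: int
    window_h: int
    stride: int
    classifier_input_size: int = 224
    probability_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("window_w", "window_h", "stride", "classifier_input_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValidationError(
                f"probability_threshold must be in [0, 1], got "
                f"{self.probability_threshold!r}")


# ---------------------------------------------------------------------------
# I/O helpers


def _parse_timestamp(text: str, lineno: int) -> dt.datetime:
    try:
        return dt.datetime.strptime(text.strip(), TIMESTAMP_FMT)
    except ValueError as exc:
        raise AnnotationError(
            f"line {lineno}: bad timestamp {text!r} (expected "
            f"'{TIMESTAMP_FMT}')") from exc


def _read_csv_rows(path: Path) -> tuple[dict[str, str], list[tuple[int, list[str]]]]:
    """Read a CSV with optional leading ``# key: value`` comment lines.

    Returns the parsed comment metadata and (lineno, row) pairs including the
    header row.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not line.strip():
                continue
            rows.append((lineno, next(csv.reader([line]))))
    return meta, rows


def read_annotations(
    path: str | Path,
    *,
    images_root: str | Path | None = None,
    transplanting_date: dt.date | None = None,
    name: str | None = None,
) -> ImageSeries:
    """Read a ground-truth annotation CSV into an :class:`ImageSeries`.

    Dialect (UTF-8, header row)::

        image_id,image_path,timestamp,x_min,y_min,x_max,y_max

    One row per box; an image without boxes is listed once with empty
    coordinate fields.  Leading ``# key: value`` comment lines may carry
    ``name`` and ``transplanting_date`` (ISO format); explicit keyword
    arguments override them.  If no transplanting date is available the date
    of the first image is used (that image becomes day 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    root = Path(images_root) if images_root is not None else path.parent

    meta, rows = _read_csv_rows(path)
    if not rows:
        raise AnnotationError("line 1: missing header row")
    header_line, header = rows[0]
    if [h.strip() for h in header] != list(ANNOTATION_FIELDS):
        raise AnnotationError(
            f"line {header_line}: bad header {header!r}; expected "
            f"{','.join(ANNOTATION_FIELDS)}")

    order: list[str] = []
    info: dict[str, dict] = {}
    for lineno, row in rows[1:]:
        if len(row) != len(ANNOTATION_FIELDS):
            raise AnnotationError(
                f"line {lineno}: expected {len(ANNOTATION_FIELDS)} fields, "
                f"got {len(row)}")
        image_id, image_path, ts_text = row[0], row[1], row[2]
        coords = [c.strip() for c in row[3:7]]
        ts = _parse_timestamp(ts_text, lineno)
        if image_id not in info:
            order.append(image_id)
            info[image_id] = {"path": image_path, "timestamp": ts, "boxes": []}
        elif info[image_id]["timestamp"] != ts:
            raise AnnotationError(
                f"line {lineno}: image {image_id!r} listed with conflicting "
                f"timestamps")
        if all(c == "" for c in coords):
            continue
        try:
            x0, y0, x1, y1 = (int(c) for c in coords)
        except ValueError as exc:
            raise AnnotationError(
                f"line {lineno}: non-integer box coordinates {coords!r}") from exc
        try:
            box = Box(x0, y0, x1, y1)
        except ValidationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from exc
        info[image_id]["boxes"].append(box)

    if transplanting_date is None and "transplanting_date" in meta:
        transplanting_date = dt.date.fromisoformat(meta["transplanting_date"])

    images: list[AnnotatedImage] = []
    for image_id in order:
        rec = info[image_id]
        img_path = root / rec["path"]
        if not img_path.exists():
            raise FileNotFoundError(
                f"image file for {image_id!r} not found: {img_path}")
        pixels = np.asarray(Image.open(img_path).convert("RGB"))
        images.append(AnnotatedImage(image_id=image_id, pixels=pixels,
                                     timestamp=rec["timestamp"],
                                     gt_boxes=rec["boxes"]))
    images.sort(key=lambda im: im.timestamp)
    if transplanting_date is None:
        transplanting_date = (images[0].timestamp.date() if images
                              else dt.date.today())
    for img in images:
        img.day_index = (img.timestamp.date() - transplanting_date).days
    try:
        return ImageSeries(name=name or meta.get("name", path.stem),
                           images=images,
                           transplanting_date=transplanting_date)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_annotations(series: ImageSeries, path: str | Path,
                      *, image_paths: dict[str, str] | None = None,
                      extra_header: dict[str, str] | None = None) -> None:
    """Write a series' ground truth in the annotation CSV dialect.

    ``image_paths`` maps image_id to the relative path recorded in the file
    (defaults to ``<image_id>.png``).  Round-trips losslessly through
    :func:`read_annotations` for coordinates and timestamps.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# name: {series.name}\n")
        fh.write(f"# transplanting_date: {series.transplanting_date.isoformat()}\n")
        fh.write("# day_index convention: whole days elapsed since "
                 "transplanting (transplanting = day 0)\n")
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_FIELDS)
        for img in series.images:
            img_path = (image_paths or {}).get(img.image_id, f"{img.image_id}.png")
            ts = img.timestamp.strftime(TIMESTAMP_FMT)
            if not img.gt_boxes:
                writer.writerow([img.image_id, img_path, ts, "", "", "", ""])
            for box in img.gt_boxes:
                writer.writerow([img.image_id, img_path, ts,
                                 box.x_min, box.y_min, box.x_max, box.y_max])


def write_detections(detections: "Iterable[DetectionSet] | DetectionSet",
                     path: str | Path,
                     *, extra_header: dict[str, str] | None = None) -> None:
    """Write detection sets in the detection CSV dialect.

    Dialect::

        image_id,timestamp,x_min,y_min,x_max,y_max,probability

    An empty detection set contributes no data rows; a file written from
    only-empty sets is header-only.
    """
    from .detector import DetectionSet  # local import avoids a cycle

    if isinstance(detections, DetectionSet):
        detections = [detections]
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(DETECTION_FIELDS)
        for det in detections:
            ts = det.timestamp.strftime(TIMESTAMP_FMT)
            for box, prob in zip(det.boxes, det.probabilities):
                writer.writerow([det.image_id, ts, box.x_min, box.y_min,
                                 box.x_max, box.y_max, f"{prob:.8f}"])


def read_detections(path: str | Path,
                    window: WindowConfig | None = None) -> "list[DetectionSet]":
    """Read a detection CSV back into per-image :class:`DetectionSet` objects.

    Inverse of :func:`write_detections` (up to probability formatting at
    8 decimal places).
    """
    from .detector import DetectionSet

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _, rows = _read_csv_rows(path)
    if not rows:
        raise AnnotationError("line 1: missing header row")
    header_line, header = rows[0]
    if [h.strip() for h in header] != list(DETECTION_FIELDS):
        raise AnnotationError(
            f"line {header_line}: bad header {header!r}; expected "
            f"{','.join(DETECTION_FIELDS)}")
    order: list[str] = []
    grouped: dict[str, dict] = {}
    for lineno, row in rows[1:]:
        if len(row) != len(DETECTION_FIELDS):
            raise AnnotationError(
                f"line {lineno}: expected {len(DETECTION_FIELDS)} fields, "
                f"got {len(row)}")
        image_id = row[0]
        ts = _parse_timestamp(row[1], lineno)
        try:
            x0, y0, x1, y1 = (int(c) for c in row[2:6])
            prob = float(row[6])
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: bad detection row") from exc
        try:
            box = Box(x0, y0, x1, y1)
        except ValidationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from exc
        if image_id not in grouped:
            order.append(image_id)
            grouped[image_id] = {"timestamp": ts, "boxes": [], "probs": []}
        grouped[image_id]["boxes"].append(box)
        grouped[image_id]["probs"].append(prob)
    return [DetectionSet(image_id=i, timestamp=grouped[i]["timestamp"],
                         window=window, boxes=grouped[i]["boxes"],
                         probabilities=grouped[i]["probs"])
            for i in order]
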