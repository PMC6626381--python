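"""Binary patch training-set construction and validation-crop building.

Positives are the annotated tight flowering-region boxes themselves,
resized to the classifier input size; negatives are window-sized crops
sampled uniformly from the non-annotated parts of the same images (zero
pixel overlap with any ground-truth box by default).  Validation images are
fixed-size random crops drawn from images spread equally over a set of
time-of-day slots, so detection metrics probe several lighting conditions.
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .core import AnnotatedImage, Box, ImageSeries, ValidationError, WindowConfig

LABEL_FLOWER = "flower"
LABEL_NON_FLOWER = "non_flower"

#: Time-of-day slots used for validation-set construction: morning, midday
#: and afternoon acquisition windows.
DEFAULT_TIME_SLOTS: tuple[tuple[dt.time, dt.time], ...] = (
    (dt.time(8, 0), dt.time(9, 0)),
    (dt.time(11, 0), dt.time(12, 0)),
    (dt.time(15, 0), dt.time(16, 0)),
)

#: Fraction of a ground-truth box's area that must survive crop clipping for
#: the box to be kept (symmetric with the IR >= 0.5 positivity rule).
MIN_RETAINED_AREA_FRACTION = 0.5


@dataclass
class PatchSample:
    """A fixed-size patch with its binary flower/non-flower label."""

    pixels: np.ndarray  # S x S x 3 uint8
    label: str
    source_image_id: str
    source_box: Box

    def __post_init__(self) -> None:
        if self.label not in (LABEL_FLOWER, LABEL_NON_FLOWER):
            raise ValidationError(f"unknown label {self.label!r}")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValidationError(
                f"patch must be square, got {self.pixels.shape}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def is_positive(self) -> bool:
        return self.label == LABEL_FLOWER


def resize_patch(pixels: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize of an RGB patch to ``target x target``.

    Deterministic; a source already at the target size is returned
    unchanged (copied), and constant-valued input stays constant.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 patch, got shape {pixels.shape}")
    if pixels.shape[0] == 0 or pixels.shape[1] == 0:
        raise ValidationError("cannot resize a zero-area patch")
    if pixels.shape[0] == target and pixels.shape[1] == target:
        return pixels.copy()
    img = Image.fromarray(np.ascontiguousarray(pixels.astype(np.uint8)))
    return np.asarray(img.resize((target, target), Image.BILINEAR))


def extract_positive_patches(series: ImageSeries, n: int,
                             *, size: int = 224,
                             seed: int = 0) -> list[PatchSample]:
    """Sample ``n`` annotated flowering-region boxes (without replacement)
    and return their image content resized to ``size``.

    If fewer than ``n`` boxes exist, all of them are returned with a
    warning.
    """
    pool: list[tuple[AnnotatedImage, Box]] = [
        (img, box) for img in series.images for box in img.gt_boxes]
    if len(pool) < n:
        warnings.warn(
            f"requested {n} positive patches but series {series.name!r} has "
            f"only {len(pool)} annotated boxes; returning all of them",
            stacklevel=2)
    rng = np.random.default_rng(seed)
    k = min(n, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False) if pool else []
    samples = []
    for i in np.sort(np.asarray(idx, dtype=int)):
        img, box = pool[int(i)]
        samples.append(PatchSample(
            pixels=resize_patch(img.crop(box), size),
            label=LABEL_FLOWER, source_image_id=img.image_id,
            source_box=box))
    return samples


def sample_negative_patches(series: ImageSeries, n: int,
                            window: WindowConfig,
                            *, seed: int = 0,
                            max_overlap: int = 0,
                            max_attempts: int | None = None
                            ) -> list[PatchSample]:
    """Sample ``n`` window-sized background patches uniformly at random.

    A candidate window is rejected if it overlaps any ground-truth box by
    more than ``max_overlap`` pixels (default 0: strictly non-annotated
    content only).  Raises if ``n`` windows cannot be placed within
    ``max_attempts`` draws (default ``100 * n``), reporting the achieved
    count.
    """
    usable = [img for img in series.images
              if img.width >= window.window_w and img.height >= window.window_h]
    if not usable:
        raise ValidationError(
            f"no image in series {series.name!r} can contain a "
            f"{window.window_w}x{window.window_h} window")
    if max_attempts is None:
        max_attempts = max(100 * n, 1000)
    rng = np.random.default_rng(seed)
    samples: list[PatchSample] = []
    attempts = 0
    while len(samples) < n and attempts < max_attempts:
        attempts += 1
        img = usable[int(rng.integers(0, len(usable)))]
        x0 = int(rng.integers(0, img.width - window.window_w + 1))
        y0 = int(rng.integers(0, img.height - window.window_h + 1))
        cand = Box(x0, y0, x0 + window.window_w, y0 + window.window_h)
        if any(cand.intersection_area(gt) > max_overlap for gt in img.gt_boxes):
            continue
        samples.append(PatchSample(
            pixels=resize_patch(img.crop(cand), window.classifier_input_size),
            label=LABEL_NON_FLOWER, source_image_id=img.image_id,
            source_box=cand))
    if len(samples) < n:
        raise ValidationError(
            f"could only place {len(samples)} of {n} background windows in "
            f"{max_attempts} draws (ground truth covers too much of the "
            f"imagery)")
    return samples


def _slot_of(ts: dt.datetime,
             slots: Sequence[tuple[dt.time, dt.time]]) -> int | None:
    for i, (start, end) in enumerate(slots):
        if start <= ts.time() <= end:
            return i
    return None


def build_validation_crops(series_list: Sequence[ImageSeries],
                           *, per_series: int = 15,
                           slots: Sequence[tuple[dt.time, dt.time]] = DEFAULT_TIME_SLOTS,
                           crop: int = 1000,
                           seed: int = 0) -> list[AnnotatedImage]:
    """Build the detection validation set: per series, ``per_series`` images
    distributed equally over the time-of-day ``slots``, each reduced to one
    random ``crop x crop`` window with its boxes clipped to crop coordinates.

    Clipped boxes keeping less than half their original area are dropped.
    """
    if per_series % len(slots) != 0:
        raise ValidationError(
            f"per_series={per_series} does not divide equally over "
            f"{len(slots)} time slots")
    per_slot = per_series // len(slots)
    rng = np.random.default_rng(seed)
    out: list[AnnotatedImage] = []
    for series in series_list:
        by_slot: list[list[AnnotatedImage]] = [[] for _ in slots]
        for img in series.images:
            s = _slot_of(img.timestamp, slots)
            if s is not None:
                by_slot[s].append(img)
        for s, imgs in enumerate(by_slot):
            if len(imgs) < per_slot:
                start, end = slots[s]
                raise ValidationError(
                    f"series {series.name!r}: slot {start}-{end} has only "
                    f"{len(imgs)} images, need {per_slot}")
            chosen = rng.choice(len(imgs), size=per_slot, replace=False)
            for i in np.sort(chosen):
                img = imgs[int(i)]
                if img.width < crop or img.height < crop:
                    raise ValidationError(
                        f"image {img.image_id!r} ({img.width}x{img.height}) "
                        f"is smaller than the {crop}x{crop} crop")
                cx = int(rng.integers(0, img.width - crop + 1))
                cy = int(rng.integers(0, img.height - crop + 1))
                boxes = []
                for gt in img.gt_boxes:
                    clipped = gt.clip(cx, cy, cx + crop, cy + crop)
                    if clipped is None:
                        continue
                    if clipped.area < MIN_RETAINED_AREA_FRACTION * gt.area:
                        continue
                    boxes.append(clipped.shift(-cx, -cy))
                out.append(AnnotatedImage(
                    image_id=f"{img.image_id}_crop{cx}x{cy}",
                    pixels=img.pixels[cy:cy + crop, cx:cx + crop].copy(),
                    timestamp=img.timestamp,
                    gt_boxes=boxes,
                    day_index=img.day_index))
    return out


def save_patches(patches: Sequence[PatchSample], outdir: str | Path) -> Path:
    """Persist patches as PNGs plus a ``manifest.csv``
    (``patch_path,label,source_image_id``); returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patch_path", "label", "source_image_id"])
        for i, p in enumerate(patches):
            rel = f"patch_{i:05d}_{p.label}.png"
            Image.fromarray(p.pixels).save(outdir / rel)
            writer.writerow([rel, p.label, p.source_image_id])
    return manifest


def load_patches(manifest: str | Path) -> list[PatchSample]:
    """Load a patch set written by :func:`save_patches`."""
    manifest = Path(manifest)
    root = manifest.parent
    patches = []
    with open(manifest, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pixels = np.asarray(Image.open(root / row["patch_path"]).convert("RGB"))
            s = pixels.shape[0]
            patches.append(PatchSample(
                pixels=pixels, label=row["label"],
                source_image_id=row["source_image_id"],
                source_box=Box(0, 0, s, s)))
    return patches
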