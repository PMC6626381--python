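"""Sliding-window flowering-region detection and per-image region counting.

The detector scans each image with a fixed-size window at a fixed stride,
scores the patch under every window position with a binary classifier, and
keeps the positions whose flower probability reaches the decision
threshold.  No merging or non-maximum suppression is applied: the region
*count* is the window count, which for a fixed window size is proportional
to the number of flowering panicles present and is the quantity the
phenology stage consumes.

Border remainder strips (right/bottom pixels left over when the image
dimensions are not an exact multiple of the stride) are dropped, not
padded.  Note that a stride smaller than the window (the Kamenoo setting)
produces overlapping windows and therefore potential double counting of a
single panicle; counts remain proportional, which is all the 50% rule
needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier import PatchClassifier
from .core import AnnotatedImage, Box, ValidationError, WindowConfig
from .patches import resize_patch

#: Per-dataset sliding-window settings used on the real five-sequence
#: acquisition (window dimensions and stride in pixels).
DEFAULT_WINDOW_CONFIGS: dict[str, WindowConfig] = {
    "Kinmaze": WindowConfig(140, 140, 140),
    "Kamenoo": WindowConfig(160, 160, 140),
    "Koshihikari-1": WindowConfig(160, 160, 150),
    "Koshihikari-2": WindowConfig(160, 160, 150),
    "Koshihikari-3": WindowConfig(160, 160, 150),
}


@dataclass
class DetectionSet:
    """All window positions classified positive for one image."""

    image_id: str
    timestamp: object  # datetime
    window: WindowConfig | None
    boxes: list[Box] = field(default_factory=list)
    probabilities: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.probabilities):
            raise ValidationError(
                f"{self.image_id!r}: {len(self.boxes)} boxes vs "
                f"{len(self.probabilities)} probabilities")

    def __len__(self) -> int:
        return len(self.boxes)


def slide_windows(image_w: int, image_h: int,
                  window: WindowConfig) -> list[Box]:
    """All window positions for an ``image_w x image_h`` image, row-major.

    Positions are ``(i*stride, j*stride)`` for
    ``i in [0, floor((image_w - window_w) / stride)]`` and likewise
    vertically; empty if the window exceeds the image.
    """
    if image_w < window.window_w or image_h < window.window_h:
        return []
    nx = (image_w - window.window_w) // window.stride + 1
    ny = (image_h - window.window_h) // window.stride + 1
    return [Box(i * window.stride, j * window.stride,
                i * window.stride + window.window_w,
                j * window.stride + window.window_h)
            for j in range(ny) for i in range(nx)]


def detect_flowering_regions(image: AnnotatedImage,
                             model: PatchClassifier,
                             window: WindowConfig) -> DetectionSet:
    """Score every sliding-window patch of ``image`` and keep the positions
    with flower probability >= ``window.probability_threshold``.

    Deterministic for a fixed model; batching is an internal optimisation
    with output identical to one-window-at-a-time scoring.
    """
    positions = slide_windows(image.width, image.height, window)
    if not positions:
        warnings.warn(
            f"image {image.image_id!r} ({image.width}x{image.height}) is "
            f"smaller than the {window.window_w}x{window.window_h} window; "
            f"empty detection set", stacklevel=2)
        return DetectionSet(image.image_id, image.timestamp, window)
    target = getattr(model, "input_size", None)
    patches = []
    for pos in positions:
        patch = image.crop(pos)
        if target is not None and patch.shape[0:2] != (target, target):
            patch = resize_patch(patch, target)
        patches.append(patch)
    if hasattr(model, "predict_batch"):
        probs = np.asarray(model.predict_batch(patches), dtype=float)
    else:
        probs = np.array([model.predict_prob(p) for p in patches])
    keep = probs >= window.probability_threshold
    return DetectionSet(
        image_id=image.image_id, timestamp=image.timestamp, window=window,
        boxes=[pos for pos, k in zip(positions, keep) if k],
        probabilities=[float(p) for p, k in zip(probs, keep) if k])


def count_regions(detections: DetectionSet) -> int:
    """Number of windows classified as flowering regions (the panicle-count
    proxy)."""
    return len(detections.boxes)


def detect_series(series, model: PatchClassifier,
                  window: WindowConfig) -> list[DetectionSet]:
    """Run detection over every image of a series, in timestamp order."""
    return [detect_flowering_regions(img, model, window) for img in series]
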