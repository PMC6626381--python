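"""Grad-CAM visual explanations of the flower decision on a patch.

The gradient of the flower-class logit is taken with respect to each
feature map of a chosen convolutional layer (by default the last spatial
layer of the network); global average pooling of that gradient gives one
importance weight per feature map; the weighted combination of the feature
maps is passed through ReLU, upsampled bilinearly to the patch size and
divided by its maximum, giving a heatmap in [0, 1].  A raw map that is
identically zero (zero gradients) stays all-zero rather than dividing by
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .core import ValidationError


@dataclass
class GradCAMMap:
    heatmap: np.ndarray  # patch-sized, fractions in [0, 1]
    target_layer_id: str
    patch_ref: str = ""


def _upsample_bilinear(arr: np.ndarray, width: int, height: int) -> np.ndarray:
    img = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(img.resize((width, height), Image.BILINEAR))


def gradcam(model, patch: np.ndarray, target_layer: str | None = None,
            patch_ref: str = "") -> GradCAMMap:
    """Grad-CAM heatmap for ``model``'s flower logit on ``patch``.

    ``model`` must expose named layers with cached forward/backward (the
    :class:`~headingdate.classifier.SmallCNN` contract).  ``target_layer``
    defaults to the last layer producing a spatial (C, H, W) output.
    """
    names = [name for name, _ in model.layers]
    spatial_flags = [layer.spatial for _, layer in model.layers]
    if target_layer is None:
        spatial_idx = [i for i, s in enumerate(spatial_flags) if s]
        if not spatial_idx:
            raise ValidationError("model has no spatial layers")
        idx = spatial_idx[-1]
    else:
        if target_layer not in names:
            raise ValidationError(
                f"layer {target_layer!r} not found; available layers: "
                f"{', '.join(names)}")
        idx = names.index(target_layer)
        if not spatial_flags[idx]:
            raise ValidationError(
                f"layer {target_layer!r} does not produce a spatial feature "
                f"map; pick one of: "
                f"{', '.join(n for n, s in zip(names, spatial_flags) if s)}")

    x = model._prepare(patch)
    activations = model.forward_cached(x)
    fmap = activations[idx]  # (C, h, w)
    grad = model.backward_to(idx)  # d(logit)/d(fmap), same shape
    weights = grad.mean(axis=(1, 2))  # GAP of the gradient per feature map
    raw = np.maximum((weights[:, None, None] * fmap).sum(axis=0), 0.0)

    h, w = np.asarray(patch).shape[:2]
    up = _upsample_bilinear(raw, w, h)
    up = np.maximum(up, 0.0)  # bilinear cannot undershoot, but be explicit
    peak = up.max()
    heatmap = up / peak if peak > 0 else np.zeros_like(up)
    return GradCAMMap(heatmap=heatmap, target_layer_id=names[idx],
                      patch_ref=patch_ref)


def overlay_heatmap(patch: np.ndarray, cam: GradCAMMap,
                    alpha: float = 0.5, colormap: str = "jet") -> np.ndarray:
    """Alpha-blend a colour-mapped heatmap over the patch (uint8 RGB).

    ``alpha=0`` returns the patch unchanged; ``alpha=1`` returns the pure
    colour-mapped heatmap.
    """
    import matplotlib
    matplotlib.use("Agg")

    patch = np.asarray(patch)
    if patch.shape[:2] != cam.heatmap.shape:
        raise ValidationError(
            f"patch {patch.shape[:2]} and heatmap {cam.heatmap.shape} "
            f"dimensions differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    if alpha == 0.0:
        return patch.astype(np.uint8).copy()
    colored = matplotlib.colormaps[colormap](cam.heatmap)[..., :3] * 255.0
    blended = (1.0 - alpha) * patch.astype(np.float64) + alpha * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def heatmap_peak(cam: GradCAMMap) -> tuple[int, int]:
    """(x, y) pixel location of the heatmap maximum (first on ties)."""
    flat = int(np.argmax(cam.heatmap))
    y, x = np.unravel_index(flat, cam.heatmap.shape)
    return int(x), int(y)
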