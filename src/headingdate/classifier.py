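"""Binary flower / non-flower patch classifier.

The default backbone is a small 4-convolution-block CNN built on
:mod:`headingdate.nn` and trained from scratch with the standard protocol
(stochastic gradient descent, learning rate 0.001, momentum 0.9, 3 epochs,
binary cross-entropy on a single sigmoid output).  An ImageNet-pretrained
ResNet-50 can be plugged in behind the same interface when torch is
installed (:func:`load_pretrained_resnet50`); nothing in the package
requires it.

Two non-learned classifiers share the interface: :class:`LuminanceOracle`
(thresholds the bright anthesis luminance band of synthetic sprites, useful
to validate the detection/phenology pipeline independently of training) and
:class:`ConstantClassifier` (degenerate test double).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from . import nn
from .core import ValidationError
from .patches import LABEL_FLOWER, PatchSample, resize_patch


@dataclass
class TrainConfig:
    """Training protocol of the patch classifier.

    Learning rate, momentum and epoch count are the pipeline's standard
    values; batch size and shuffling are implementation choices (the
    protocol leaves them open) and default to 32 with a seeded per-epoch
    shuffle.
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 3
    batch_size: int = 32
    rng_seed: int = 0
    backbone: str = "small_cnn"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@runtime_checkable
class PatchClassifier(Protocol):
    """Anything that maps an RGB patch to a flower probability in [0, 1].

    ``input_size`` is the square side the classifier expects, or None when
    any size is accepted (the detector then skips resizing).
    """

    input_size: int | None

    def predict_prob(self, patch: np.ndarray) -> float: ...


class SmallCNN:
    """4-conv-block scratch CNN with a global-average-pool sigmoid head.

    Architecture (input ``S x S x 3``): [conv3x3 -> ReLU -> maxpool2] x 3,
    then conv3x3 -> ReLU (the final spatial layer, ``relu4``, is the
    Grad-CAM default target), global average pooling and a single-logit
    dense layer.  ``predict_prob`` applies the sigmoid.
    """

    CHANNELS = (8, 16, 32, 32)

    def __init__(self, input_size: int, rng_seed: int = 0):
        if input_size < 8:
            raise ValidationError("input_size must be >= 8")
        self.input_size = int(input_size)
        self.rng_seed = int(rng_seed)
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0]))
        c1, c2, c3, c4 = self.CHANNELS
        self.layers: list[tuple[str, nn.Layer]] = [
            ("conv1", nn.Conv2D(3, c1, rng=rng)),
            ("relu1", nn.ReLU()),
            ("pool1", nn.MaxPool2()),
            ("conv2", nn.Conv2D(c1, c2, rng=rng)),
            ("relu2", nn.ReLU()),
            ("pool2", nn.MaxPool2()),
            ("conv3", nn.Conv2D(c2, c3, rng=rng)),
            ("relu3", nn.ReLU()),
            ("pool3", nn.MaxPool2()),
            ("conv4", nn.Conv2D(c3, c4, rng=rng)),
            ("relu4", nn.ReLU()),
            ("gap", nn.GlobalAvgPool()),
            ("fc", nn.Dense(c4, 1, rng=rng)),
        ]
        # Zero-init the freshly attached sigmoid head: the untrained model
        # then predicts exactly 0.5, so the short training protocol never
        # has to burn steps cancelling a random initial logit offset, and
        # the 0.5 decision threshold stays centred between the classes.
        fc = dict(self.layers)["fc"]
        fc.w.fill(0.0)
        fc.b.fill(0.0)

    # -- plumbing ----------------------------------------------------------

    def _prepare(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch)
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise ValidationError(f"expected HxWx3 patch, got {patch.shape}")
        if patch.size == 0:
            raise ValidationError("empty patch")
        if patch.shape[0] != self.input_size or patch.shape[1] != self.input_size:
            patch = resize_patch(patch.astype(np.uint8), self.input_size)
        # standardize to zero mean and ~unit variance (8-bit RGB has a
        # dynamic range of ~0.25 in [0,1] units); well-scaled inputs keep
        # the short training protocol's gradient magnitudes useful
        x = (patch.astype(np.float32) - 127.5) / 63.75
        return np.ascontiguousarray(x.transpose(2, 0, 1))

    def forward_logit(self, x: np.ndarray) -> float:
        for _, layer in self.layers:
            x = layer.forward(x)
        return float(x[0])

    def forward_cached(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward pass returning every layer's output (Grad-CAM support)."""
        acts = []
        for _, layer in self.layers:
            x = layer.forward(x)
            acts.append(x)
        return acts

    def backward_to(self, layer_index: int) -> np.ndarray:
        """Backprop d(logit)/d(output of ``layers[layer_index]``) after a
        cached forward pass."""
        grad = np.ones(1, dtype=np.float32)
        for _, layer in reversed(self.layers[layer_index + 1:]):
            grad = layer.backward(grad)
        return grad

    # -- public interface --------------------------------------------------

    def predict_prob(self, patch: np.ndarray) -> float:
        return float(nn.sigmoid(self.forward_logit(self._prepare(patch))))

    def predict_batch(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        """Per-sample inference; bit-identical to calling
        :meth:`predict_prob` one patch at a time, in any order."""
        return np.array([self.predict_prob(p) for p in patches])

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {"input_size": np.array(self.input_size),
                  "rng_seed": np.array(self.rng_seed)}
        for name, layer in self.layers:
            for p in layer.params:
                arrays[f"{name}.{p}"] = getattr(layer, p)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SmallCNN":
        data = np.load(path)
        model = cls(int(data["input_size"]), int(data["rng_seed"]))
        for name, layer in model.layers:
            for p in layer.params:
                getattr(layer, p)[...] = data[f"{name}.{p}"]
        return model


class LuminanceOracle:
    """Oracle classifier: answers from the synthetic sprites' construction.

    Synthetic panicle sprites occupy a luminance band disjoint from the
    canopy background, so a patch contains flowering content iff at least
    ``min_fraction`` of its pixels exceed ``threshold`` luminance.  Output
    is a hard 0.0 / 1.0.  Defaults match
    :class:`headingdate.synthetic.PhenologyParams` defaults.
    """

    input_size = None  # accepts any patch size

    def __init__(self, threshold: float = 185.0, min_fraction: float = 0.02):
        self.threshold = float(threshold)
        self.min_fraction = float(min_fraction)

    def predict_prob(self, patch: np.ndarray) -> float:
        patch = np.asarray(patch, dtype=np.float32)
        if patch.size == 0:
            raise ValidationError("empty patch")
        lum = (0.299 * patch[..., 0] + 0.587 * patch[..., 1]
               + 0.114 * patch[..., 2])
        return 1.0 if (lum > self.threshold).mean() >= self.min_fraction else 0.0

    def predict_batch(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        return np.array([self.predict_prob(p) for p in patches])


class ConstantClassifier:
    """Degenerate classifier returning a fixed probability (test double)."""

    input_size = None

    def __init__(self, probability: float):
        if not 0.0 <= probability <= 1.0:
            raise ValidationError("probability must be in [0, 1]")
        self.probability = float(probability)

    def predict_prob(self, patch: np.ndarray) -> float:
        return self.probability

    def predict_batch(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        return np.full(len(patches), self.probability)


def train_classifier(patches: Sequence[PatchSample],
                     config: TrainConfig | None = None) -> SmallCNN:
    """Train the patch classifier end to end with binary cross-entropy.

    Deterministic: a fixed ``config.rng_seed`` fixes weight initialisation
    and the per-epoch shuffle, so repeated training on the same data yields
    identical predictions.
    """
    config = config or TrainConfig()
    if config.backbone != "small_cnn":
        raise ValidationError(
            f"unknown backbone {config.backbone!r}; use 'small_cnn' here or "
            f"load_pretrained_resnet50() for the transfer-learning path")
    if not patches:
        raise ValidationError("no training patches")
    labels = np.array([1.0 if p.is_positive else 0.0 for p in patches],
                      dtype=np.float32)
    if labels.min() == labels.max():
        raise ValidationError(
            "training data contains a single class; need both flower and "
            "non_flower patches")
    sizes = {p.size for p in patches}
    if len(sizes) != 1:
        raise ValidationError(f"mixed patch sizes in training data: {sizes}")
    size = sizes.pop()

    model = SmallCNN(input_size=size, rng_seed=config.rng_seed)
    inputs = [model._prepare(p.pixels) for p in patches]
    opt = nn.SGDMomentum([layer for _, layer in model.layers],
                         config.learning_rate, config.momentum)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 1]))
    n = len(inputs)
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            for i in batch:
                logit = model.forward_logit(inputs[i])
                p = nn.sigmoid(logit)
                # d(BCE)/d(logit) = p - y, averaged over the batch
                grad = np.array([(p - labels[i]) / len(batch)],
                                dtype=np.float32)
                for _, layer in reversed(model.layers):
                    grad = layer.backward(grad)
            opt.step()
    return model


def evaluate_accuracy(model: PatchClassifier,
                      patches: Sequence[PatchSample],
                      threshold: float = 0.5) -> float:
    """Fraction of patches whose thresholded probability matches the label."""
    if not patches:
        raise ValidationError("no evaluation patches")
    correct = sum(
        1 for p in patches
        if (model.predict_prob(p.pixels) >= threshold) == p.is_positive)
    return correct / len(patches)


def load_pretrained_resnet50(checkpoint: str | Path | None = None):
    """Optional transfer-learning backbone: ImageNet-pretrained ResNet-50
    with its 1000-way softmax replaced by a single-node sigmoid layer.

    Requires torch/torchvision; raises ImportError with guidance otherwise.
    Returned object satisfies :class:`PatchClassifier`.
    """
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - torch optional
        raise ImportError(
            "the pretrained ResNet-50 backbone needs the optional torch "
            "extra (pip install headingdate[torch]); the default small_cnn "
            "backbone has no such dependency") from exc

    class _ResNetAdapter:  # pragma: no cover - torch optional
        input_size = 224

        def __init__(self):
            net = torchvision.models.resnet50(weights="IMAGENET1K_V1")
            net.fc = torch.nn.Linear(net.fc.in_features, 1)
            if checkpoint is not None:
                net.load_state_dict(torch.load(checkpoint, map_location="cpu"))
            net.eval()
            self.net = net

        def predict_prob(self, patch: np.ndarray) -> float:
            patch = resize_patch(patch, self.input_size)
            x = torch.from_numpy(
                patch.astype(np.float32).transpose(2, 0, 1) / 255.0)[None]
            with torch.no_grad():
                return float(torch.sigmoid(self.net(x))[0, 0])

        def predict_batch(self, patches):
            return np.array([self.predict_prob(p) for p in patches])

    return _ResNetAdapter()
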