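"""Minimal NumPy neural-network layers with exact manual backprop.

Supports the small patch-classification CNN and the Grad-CAM backward pass:
every layer implements ``forward``/``backward`` on a single CHW sample, so
inference results are bit-identical regardless of batch composition or
storage order (each sample's GEMMs see the same shapes every time), and the
gradient of the class logit with respect to any intermediate feature map is
available by chaining ``backward`` calls partway down the stack.

float32 throughout; optimisation is plain SGD with classical momentum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "GlobalAvgPool", "Dense",
           "SGDMomentum", "sigmoid"]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Layer:
    """Base class: stateless apart from the cache of the last forward."""

    params: list[str] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def spatial(self) -> bool:
        """Whether this layer's output is a spatial (C, H, W) feature map."""
        return True


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, via im2col GEMM."""

    params = ["w", "b"]

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialisation
        rng = rng or np.random.default_rng()
        self.w = (rng.standard_normal((out_channels, fan_in)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        k, p = self.kernel, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (c, h, w, k, k) -> (h*w, c*k*k)
        return view.transpose(1, 2, 0, 3, 4).reshape(h * w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        cols = np.ascontiguousarray(self._im2col(x), dtype=np.float32)
        self._cols = cols
        self._shape = (h, w)
        out = cols @ self.w.T + self.b
        return out.T.reshape(self.out_channels, h, w)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        h, w = self._shape
        k, p = self.kernel, self.pad
        g = grad_out.reshape(self.out_channels, h * w)
        self.gw += g @ self._cols
        self.gb += g.sum(axis=1)
        gcols = (self.w.T @ g).reshape(
            self.in_channels, k, k, h, w)
        gx = np.zeros((self.in_channels, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gx[:, i:i + h, j:j + w] += gcols[:, i, j]
        return gx[:, p:p + h, p:p + w]

    def zero_grad(self) -> None:
        self.gw.fill(0.0)
        self.gb.fill(0.0)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :h2 * 2, :w2 * 2].reshape(c, h2, 2, w2, 2)
        patches = xt.transpose(0, 1, 3, 2, 4).reshape(c, h2, w2, 4)
        self._arg = patches.argmax(axis=3)
        self._in_shape = (c, h, w)
        return patches.max(axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        gx = np.zeros((c, h2, w2, 4), dtype=np.float32)
        idx = np.indices((c, h2, w2))
        gx[idx[0], idx[1], idx[2], self._arg] = grad_out
        gx = gx.reshape(c, h2, w2, 2, 2).transpose(0, 1, 3, 2, 4)
        full = np.zeros((c, h, w), dtype=np.float32)
        full[:, :h2 * 2, :w2 * 2] = gx.reshape(c, h2 * 2, w2 * 2)
        return full


class GlobalAvgPool(Layer):
    """(C, H, W) -> (C,) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        return np.broadcast_to(
            grad_out[:, None, None] / (h * w), (c, h, w)).astype(np.float32)

    @property
    def spatial(self) -> bool:
        return False


class Dense(Layer):
    params = ["w", "b"]

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / in_features)
        self.w = (rng.standard_normal((out_features, in_features)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self.w @ x + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.gw += np.outer(grad_out, self._x)
        self.gb += grad_out
        return self.w.T @ grad_out

    def zero_grad(self) -> None:
        self.gw.fill(0.0)
        self.gb.fill(0.0)

    @property
    def spatial(self) -> bool:
        return False


class SGDMomentum:
    """Classical momentum: v <- mu*v + g;  w <- w - lr*v."""

    def __init__(self, layers, learning_rate: float, momentum: float):
        self.lr = float(learning_rate)
        self.mu = float(momentum)
        self._targets = []
        for layer in layers:
            for name in layer.params:
                self._targets.append((layer, name))
        self._velocity = [np.zeros_like(getattr(layer, name))
                          for layer, name in self._targets]

    def step(self) -> None:
        for (layer, name), v in zip(self._targets, self._velocity):
            g = getattr(layer, "g" + name)
            v *= self.mu
            v += g
            getattr(layer, name)[...] -= self.lr * v

    def zero_grad(self) -> None:
        for layer, _ in self._targets:
            if hasattr(layer, "zero_grad"):
                layer.zero_grad()
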