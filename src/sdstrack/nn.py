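"""Minimal NumPy neural-network layers with explicit backpropagation.

Just the pieces the pose-estimation network needs: stride-1 'same'
convolution, ReLU, 2x2 max pooling, dense layers, L1 loss, and Adam.
Everything runs in float32 through BLAS matmuls (im2col); the backward
passes avoid scatter-adds entirely (the input gradient of a stride-1
convolution is itself a convolution with the spatially flipped kernels),
which keeps single-core CPU training practical.

Gradient correctness is pinned by finite-difference checks in the test
suite.  Tensors are NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense", "Sequential",
           "Adam", "l1_loss"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patch matrix for stride-1 'same' conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    b, c, h, w = x.shape
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' 2D convolution (odd kernel), He-initialised."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(fan_in, out_channels)).astype(np.float32)
        b = np.zeros(out_channels, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        b_, _, h, w = x.shape
        out = self._cols @ self.params[0] + self.params[1]
        return out.reshape(b_, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b_, _, h, w = self._shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.grads[0][...] = self._cols.T @ dy_mat
        self.grads[1][...] = dy_mat.sum(axis=0)
        # dx = conv(dy, W flipped spatially, channels transposed)
        wmat = self.params[0].reshape(self.cin, self.k, self.k, self.cout)
        wflip = wmat[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.cout * self.k * self.k, self.cin)
        dy_cols = _im2col(dy, self.k)
        dx = (dy_cols @ wflip).reshape(b_, h, w, self.cin).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, :, :h2 * 2, :w2 * 2].reshape(b, c, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        flat = np.zeros((b, c, h2, w2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros((b, c, h, w), dtype=dy.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = (
            flat.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
                .reshape(b, c, h2 * 2, w2 * 2))
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features)).astype(np.float32)
        b = np.zeros(out_features, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(pred.dtype)
    return loss, grad


class Adam:
    """Adam optimiser (Kingma & Ba) over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.99,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
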