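"""Layers for 3D volumetric networks (NCHWD layout, float32)."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def pooled_size(n: int, kernel: int = 3, stride: int = 2, padding: int = 1) -> int:
    """Output length of one pooling stage along one axis.

    With the default kernel 3 / stride 2 / padding 1 this is ceil(n/2),
    so 91 -> 46 -> 23 along the first axis of a standard 2 mm MNI grid.
    """
    return (n + 2 * padding - kernel) // stride + 1


class Layer:
    """Base class: parameters and gradients are dicts of ndarrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' padding for odd kernels.

    Lowered to a (N*voxels, C_in*k^3) x (C_in*k^3, C_out) matrix product.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 needs_input_grad: bool = True) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.padding = kernel // 2 if padding is None else padding
        self.needs_input_grad = needs_input_grad
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel ** 3
        # He initialisation, appropriate for the ReLU nonlinearities downstream
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel, kernel, kernel))
        self.params = {"W": w.astype(DTYPE), "b": np.zeros(out_channels, dtype=DTYPE)}
        self._cache: tuple | None = None

    def _im2col(self, x: np.ndarray, padding: int | None = None) -> tuple[np.ndarray, tuple]:
        """Lower to (N, C*k^3, voxels) with the voxel axis contiguous."""
        n, c, h, w, d = x.shape
        k = self.kernel
        p = self.padding if padding is None else padding
        if p:
            xp = np.zeros((n, c, h + 2 * p, w + 2 * p, d + 2 * p), dtype=x.dtype)
            xp[:, :, p:p + h, p:p + w, p:p + d] = x
            x = xp
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        ho, wo, do = win.shape[2:5]
        cols = np.ascontiguousarray(win.transpose(0, 1, 5, 6, 7, 2, 3, 4))
        return cols.reshape(n, c * k ** 3, ho * wo * do), (ho, wo, do)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, (ho, wo, do) = self._im2col(x)
        wmat = self.params["W"].reshape(self.out_channels, -1)
        out = np.matmul(wmat, cols)  # (N, C_out, voxels)
        out += self.params["b"].reshape(1, -1, 1)
        self._cache = (cols, x.shape) if train else None
        return out.reshape(x.shape[0], self.out_channels, ho, wo, do)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, h, w, d = x_shape
        k, p = self.kernel, self.padding
        dmat = dout.reshape(n, self.out_channels, -1)
        dw = np.matmul(dmat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["W"] = dw.reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=(0, 2))
        if not self.needs_input_grad:  # input layer: skip the data gradient
            self._cache = None
            return None
        # data gradient as a convolution of dout with the flipped kernels
        # (stride 1 throughout, so the transposed conv is a plain conv with
        # padding k - 1 - p and in/out channels swapped)
        wflip = self.params["W"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        wflip_mat = np.ascontiguousarray(wflip).reshape(c, -1)
        dcols, _ = self._im2col(np.ascontiguousarray(dout), padding=k - 1 - p)
        dx = np.matmul(wflip_mat, dcols).reshape(n, c, h, w, d)
        self._cache = None
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels, dtype=DTYPE), "beta": np.zeros(channels, dtype=DTYPE)}
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) * self._bc(inv_std)
        out = self._bc(self.params["gamma"]) * xhat + self._bc(self.params["beta"])
        if train:
            self._cache = (xhat, np.asarray(inv_std))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self._bc(self.params["gamma"])
        dx = (dxhat - self._bc(dxhat.mean(axis=axes))
              - xhat * self._bc((dxhat * xhat).mean(axis=axes))) * self._bc(inv_std)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = (x > 0) if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        out = out.astype(DTYPE)
        self._out = out if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._out * (1.0 - self._out)
        self._out = None
        return dx


class AvgPool3d(Layer):
    """Average pooling, kernel 3 / stride 2 / padding 1 by default.

    Padded positions do not count toward the divisor, so edge windows
    average over their in-bounds voxels only.
    """

    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1) -> None:
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._counts: dict[tuple, np.ndarray] = {}
        self._cache: tuple | None = None

    def _count(self, spatial: tuple[int, int, int]) -> np.ndarray:
        if spatial not in self._counts:
            ones = np.ones((1, 1) + spatial, dtype=DTYPE)
            self._counts[spatial] = self._window_sum(ones)
        return self._counts[spatial]

    def _window_sum(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        return win.sum(axis=(-3, -2, -1))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        spatial = x.shape[2:]
        counts = self._count(spatial)
        out = self._window_sum(x) / counts
        self._cache = (spatial, counts) if train else None
        return out.astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        spatial, counts = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        h, w, d = spatial
        ho, wo, do = dout.shape[2:]
        g = (dout / counts).astype(DTYPE)
        n, c = dout.shape[:2]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p, d + 2 * p), dtype=DTYPE)
        for i, j, l in product(range(k), range(k), range(k)):
            dxp[:, :, i:i + s * ho:s, j:j + s * wo:s, l:l + s * do:s] += g
        self._cache = None
        if p:
            return np.ascontiguousarray(dxp[:, :, p:p + h, p:p + w, p:p + d])
        return dxp


class GlobalAvgPool3d(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape if train else None
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w, d = self._shape
        dx = np.broadcast_to(dout[:, :, None, None, None], self._shape) / (h * w * d)
        self._shape = None
        return dx.astype(DTYPE, copy=False)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, math.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.params = {"W": w.astype(DTYPE), "b": np.zeros(out_features, dtype=DTYPE)}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"]
        self._x = None
        return dx
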