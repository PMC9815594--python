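"""Layers with explicit forward/backward passes on NumPy arrays.

Shapes follow the (N, C, H, W) convention.  Each layer caches what its
backward pass needs during ``forward`` and accumulates parameter gradients
into ``grads`` during ``backward``; ``backward`` returns the gradient with
respect to the layer input.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError

#: Computation dtype; float32 is plenty for image filtering and twice as
#: fast, float64 is used by the numerical gradient checks.
DTYPE = np.float32


class Layer:
    """Base class; layers without parameters leave ``params`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' output size (k in {1, 3}).

    The 3x3 case is computed tap by tap: the zero-padded input is copied
    into nine contiguous (C, N*H*W) blocks (one per kernel offset) and each
    tap is a single matrix product.  This keeps all heavy work in BLAS and
    all copies on long contiguous runs.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k not in (1, 3):
            raise ConfigurationError("Conv2d supports kernel sizes 1 and 3")
        self.cin, self.cout, self.k = cin, cout, k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.params = {
            "W": rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(DTYPE),
            "b": np.zeros(cout, dtype=DTYPE),
        }

    def forward(self, x, train=True):
        w, b = self.params["W"], self.params["b"]
        n, c, h, wd = x.shape
        if self.k == 1:
            xr = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, -1)
            self._cache = (xr, x.shape)
            y = (w[:, :, 0, 0] @ xr).reshape(self.cout, n, h, wd).transpose(1, 0, 2, 3)
            return y + b[None, :, None, None]
        xp = np.zeros((c, n, h + 2, wd + 2), dtype=x.dtype)
        xp[:, :, 1:-1, 1:-1] = x.transpose(1, 0, 2, 3)
        taps = [
            np.ascontiguousarray(xp[:, :, i : i + h, j : j + wd]).reshape(c, -1)
            for i in range(3)
            for j in range(3)
        ]
        self._cache = (taps, x.shape)
        wm = w.reshape(self.cout, c, 9)
        acc = wm[:, :, 0] @ taps[0]
        for t in range(1, 9):
            acc += wm[:, :, t] @ taps[t]
        y = acc.reshape(self.cout, n, h, wd).transpose(1, 0, 2, 3)
        return y + b[None, :, None, None]

    def backward(self, gy):
        w = self.params["W"]
        n, o, h, wd = gy.shape
        self.grads["b"] = gy.sum(axis=(0, 2, 3))
        gyr = np.ascontiguousarray(gy.transpose(1, 0, 2, 3)).reshape(o, -1)
        if self.k == 1:
            xr, xshape = self._cache
            self.grads["W"] = (gyr @ xr.T)[:, :, None, None]
            gx = (w[:, :, 0, 0].T @ gyr).reshape(self.cin, n, h, wd)
            return gx.transpose(1, 0, 2, 3)
        taps, xshape = self._cache
        c = self.cin
        wm = w.reshape(o, c, 9)
        gw = np.empty((o, c, 9), dtype=gy.dtype)
        # gx accumulated on a padded grid: tap (i, j) of the forward pass
        # reads xp[i : i + h, j : j + wd], so its gradient lands there.
        gxp = np.zeros((c, n, h + 2, wd + 2), dtype=gy.dtype)
        for t in range(9):
            i, j = divmod(t, 3)
            gw[:, :, t] = gyr @ taps[t].T
            gz = (wm[:, :, t].T @ gyr).reshape(c, n, h, wd)
            gxp[:, :, i : i + h, j : j + wd] += gz
        self.grads["W"] = gw.reshape(o, c, 3, 3)
        return gxp[:, :, 1:-1, 1:-1].transpose(1, 0, 2, 3)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (upsample) or stride 1.

    Stride 2 doubles H and W (the canonical 'up-convolution').  Stride 1
    keeps the spatial size: the full transposed output (H+1, W+1) is cropped
    to (H, W), which makes the layer a learned 2x2 mixing at constant
    resolution.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 2):
        super().__init__()
        if stride not in (1, 2):
            raise ConfigurationError("ConvTranspose2d supports stride 1 or 2 only")
        self.cin, self.cout, self.stride = cin, cout, stride
        scale = np.sqrt(2.0 / (cin * 4))
        self.params = {
            "W": rng.normal(0.0, scale, size=(cin, cout, 2, 2)).astype(DTYPE),
            "b": np.zeros(cout, dtype=DTYPE),
        }

    def forward(self, x, train=True):
        w, b = self.params["W"], self.params["b"]
        n, c, h, wd = x.shape
        self._cache = x
        if self.stride == 2:
            # (N*H*W, C) @ (C, O*4) -> interleave the 2x2 taps spatially
            xr = x.transpose(0, 2, 3, 1).reshape(-1, c)
            y = (xr @ w.reshape(c, -1)).reshape(n, h, wd, self.cout, 2, 2)
            y = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.cout, 2 * h, 2 * wd)
        else:
            y = np.zeros((n, self.cout, h + 1, wd + 1), dtype=x.dtype)
            for i in range(2):
                for j in range(2):
                    y[:, :, i : i + h, j : j + wd] += np.einsum("nchw,co->nohw", x, w[:, :, i, j])
            y = y[:, :, :h, :wd]
        return y + b[None, :, None, None]

    def backward(self, gy):
        w = self.params["W"]
        x = self._cache
        n, c, h, wd = x.shape
        self.grads["b"] = gy.sum(axis=(0, 2, 3))
        if self.stride == 2:
            gyr = gy.reshape(n, self.cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
            gyr = np.ascontiguousarray(gyr).reshape(-1, self.cout * 4)  # (NHW, O*2*2)
            xr = x.transpose(0, 2, 3, 1).reshape(-1, c)
            self.grads["W"] = (xr.T @ gyr).reshape(c, self.cout, 2, 2)
            gx = (gyr @ w.reshape(c, -1).T).reshape(n, h, wd, c)
            return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
        gw = np.zeros_like(w)
        gx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                # region of x whose (i, j) tap landed inside the cropped output
                hi, wi = h - i, wd - j
                xs = x[:, :, :hi, :wi]
                gys = gy[:, :, i : i + hi, j : j + wi]
                gw[:, :, i, j] = np.einsum("nchw,nohw->co", xs, gys)
                gx[:, :, :hi, :wi] += np.einsum("nohw,co->nchw", gys, w[:, :, i, j])
        self.grads["W"] = gw
        return gx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, dtype=DTYPE), "beta": np.zeros(c, dtype=DTYPE)}
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, gy):
        xhat, std = self._cache
        gamma = self.params["gamma"]
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = gy.sum(axis=(0, 2, 3))
        gxhat = gy * gamma[None, :, None, None]
        m1 = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gxhat - m1 - xhat * m2) / std[None, :, None, None]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; ties route the gradient to one cell."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._xshape
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gflat, self._argmax[..., None], gy[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gx.reshape(n, c, h, w)
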