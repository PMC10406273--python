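"""Minimal 3D convolutional neural-network layers on numpy.

Implements exactly the layer vocabulary the residual parcellation model
needs — 3D convolution, transposed 3D convolution, batch/instance
normalization, max pooling (kernel 3, stride 1), channel dropout and
sigmoid — each with a hand-derived backward pass, plus the Adam optimizer
and a step learning-rate schedule.  Everything runs in float32; volumes are
laid out as (N, C, D, H, W).

Convolutions are expressed through one primitive, the valid cross-
correlation of a padded input with a (C_out, C_in, k, k, k) kernel, whose
adjoint is again a cross-correlation with the transposed, spatially
flipped kernel.  That duality gives both the transposed-convolution
forward pass and every input gradient for free.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class SpatialUnderflowError(ValueError):
    """A layer would reduce some spatial dimension below one voxel."""


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _im2col(x: np.ndarray, k: int, pad: int):
    """Gather sliding k^3 windows into a GEMM-ready matrix.

    Returns (col, spatial_shape) with col of shape
    (N * D' * H' * W', C * k^3).
    """
    xp = _pad_spatial(x, pad)
    if min(xp.shape[2:]) < k:
        raise SpatialUnderflowError(
            f"spatial dims {xp.shape[2:]} smaller than kernel {k}"
        )
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    v = np.moveaxis(v, 1, 4)  # (N, D', H', W', C, k, k, k)
    sp = v.shape[:4]
    col = np.ascontiguousarray(v).reshape(
        int(np.prod(sp)), int(np.prod(v.shape[4:])))
    return col, sp


def _col_forward(col: np.ndarray, sp, w: np.ndarray) -> np.ndarray:
    y = col @ w.reshape(w.shape[0], -1).T
    y = y.reshape(sp + (w.shape[0],))
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


def _col_wgrad(col: np.ndarray, dy: np.ndarray, k: int) -> np.ndarray:
    o = dy.shape[1]
    dyf = np.ascontiguousarray(np.moveaxis(dy, 1, -1)).reshape(-1, o)
    dw = dyf.T @ col                      # (O, C*k^3)
    return dw.reshape(o, -1, k, k, k)


def _xcorr(x: np.ndarray, w: np.ndarray, pad: int = 0) -> np.ndarray:
    """Valid cross-correlation of (N,C,D,H,W) with (O,C,k,k,k) -> (N,O,D',H',W')."""
    col, sp = _im2col(x, w.shape[-1], pad)
    return _col_forward(col, sp, w)


class Layer:
    """Base class: parameters/gradients as name->array dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # spatial bookkeeping: change applied to each spatial dim
    def out_dims(self, dims: tuple[int, ...]) -> tuple[int, ...]:
        return dims


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3d(Layer):
    """k^3 convolution (cross-correlation), stride 1, padding 0 or (k-1)//2."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, padding: int = 0,
                 rng: np.random.Generator | None = None, name: str = "Conv3d"):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.padding = c_in, c_out, k, padding
        self.name = name
        fan = k ** 3
        self.params["weight"] = _glorot(rng, (c_out, c_in, k, k, k),
                                        c_in * fan, c_out * fan)
        self.params["bias"] = np.zeros(c_out, dtype=np.float32)

    def out_dims(self, dims):
        out = tuple(d + 2 * self.padding - (self.k - 1) for d in dims)
        if min(out) < 1:
            raise SpatialUnderflowError(
                f"{self.name}: input {dims} underflows to {out}")
        return out

    def forward(self, x, training):
        col, sp = _im2col(x, self.k, self.padding)
        self._col = col if training else None
        self._x = None if training else x
        y = _col_forward(col, sp, self.params["weight"])
        y += self.params["bias"][None, :, None, None, None]
        return y

    def backward(self, dy):
        w = self.params["weight"]
        col = self._col
        if col is None:
            col, _ = _im2col(self._x, self.k, self.padding)
        self.grads["weight"] = _col_wgrad(col, dy, self.k)
        self.grads["bias"] = dy.sum(axis=(0, 2, 3, 4))
        # input grad: full correlation with channel-transposed, flipped kernel
        wt = np.ascontiguousarray(
            w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
        return _xcorr(dy, wt, pad=self.k - 1 - self.padding)


class ConvTranspose3d(Layer):
    """Stride-1 transposed k^3 convolution.

    padding=0 grows each spatial dim by k-1; padding=1 with k=3 keeps the
    shape ('same', output cropped by one voxel per side).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, padding: int = 0,
                 rng: np.random.Generator | None = None,
                 name: str = "ConvTranspose3d"):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.padding = c_in, c_out, k, padding
        self.name = name
        fan = k ** 3
        self.params["weight"] = _glorot(rng, (c_in, c_out, k, k, k),
                                        c_in * fan, c_out * fan)
        self.params["bias"] = np.zeros(c_out, dtype=np.float32)

    def out_dims(self, dims):
        return tuple(d + (self.k - 1) - 2 * self.padding for d in dims)

    def forward(self, x, training):
        w = self.params["weight"]
        wt = np.ascontiguousarray(
            w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
        col, sp = _im2col(x, self.k, self.k - 1)
        self._col = col if training else None
        self._x = None if training else x
        y = _col_forward(col, sp, wt)
        if self.padding:
            p = self.padding
            y = np.ascontiguousarray(y[:, :, p:-p, p:-p, p:-p])
        y += self.params["bias"][None, :, None, None, None]
        return y

    def backward(self, dy):
        w = self.params["weight"]
        dy_full = _pad_spatial(dy, self.padding)
        self.grads["bias"] = dy.sum(axis=(0, 2, 3, 4))
        col = self._col
        if col is None:
            col, _ = _im2col(self._x, self.k, self.k - 1)
        dwt = _col_wgrad(col, dy_full, self.k)
        self.grads["weight"] = np.ascontiguousarray(
            dwt.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
        # adjoint of full correlation is the valid correlation with w as-is,
        # contracting the output channel axis
        return _xcorr(dy_full, w, pad=0)


class _NormBase(Layer):
    def __init__(self, c: int, eps: float = 1e-5, name: str = "Norm"):
        super().__init__()
        self.c, self.eps, self.name = c, eps, name
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)

    def _normalize(self, x, axes):
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        return xhat, inv

    def _affine(self, xhat):
        g = self.params["gamma"][None, :, None, None, None]
        b = self.params["beta"][None, :, None, None, None]
        return g * xhat + b

    def _backward(self, dy, axes):
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3, 4))
        g = self.params["gamma"][None, :, None, None, None]
        dxhat = dy * g
        dx = inv * (dxhat - dxhat.mean(axis=axes, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return dx.astype(np.float32, copy=False)


class BatchNorm3d(_NormBase):
    """Per-channel normalization over (batch, spatial), affine, running stats."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "BatchNorm3d"):
        super().__init__(c, eps, name)
        self.momentum = momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        # calibration mode: cumulative re-estimation of the running
        # statistics with frozen weights (dropout off), so evaluation
        # matches the data flow the final weights were trained for
        self.calibrating = False
        self._calib_count = 0

    AXES = (0, 2, 3, 4)

    def forward(self, x, training):
        if not training and self.calibrating:
            xhat, inv = self._normalize(x, self.AXES)
            mean = x.mean(axis=self.AXES)
            var = x.var(axis=self.AXES)
            n = self._calib_count
            self.running_mean = ((n * self.running_mean + mean)
                                 / (n + 1)).astype(np.float32)
            self.running_var = ((n * self.running_var + var)
                                / (n + 1)).astype(np.float32)
            self._calib_count += 1
            return self._affine(xhat)
        if training:
            xhat, inv = self._normalize(x, self.AXES)
            self._xhat, self._inv = xhat, inv
            mean = x.mean(axis=self.AXES)
            var = x.var(axis=self.AXES)
            mom = self.momentum
            self.running_mean = ((1 - mom) * self.running_mean
                                 + mom * mean).astype(np.float32)
            self.running_var = ((1 - mom) * self.running_var
                                + mom * var).astype(np.float32)
            return self._affine(xhat)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None, None]) \
            * inv[None, :, None, None, None]
        return self._affine(xhat)

    def backward(self, dy):
        return self._backward(dy, self.AXES)


class InstanceNorm3d(_NormBase):
    """Per-sample, per-channel normalization over spatial dims; affine."""

    AXES = (2, 3, 4)

    def __init__(self, c: int, eps: float = 1e-5, name: str = "InstanceNorm3d"):
        super().__init__(c, eps, name)

    def forward(self, x, training):
        xhat, inv = self._normalize(x, self.AXES)
        self._xhat, self._inv = xhat, inv
        return self._affine(xhat)

    def backward(self, dy):
        return self._backward(dy, self.AXES)


class MaxPool3d(Layer):
    """Max pooling, kernel 3, stride 1 (shrinks each spatial dim by 2)."""

    def __init__(self, k: int = 3, name: str = "MaxPool3d"):
        super().__init__()
        self.k, self.name = k, name

    def out_dims(self, dims):
        out = tuple(d - (self.k - 1) for d in dims)
        if min(out) < 1:
            raise SpatialUnderflowError(
                f"{self.name}: input {dims} underflows to {out}")
        return out

    def forward(self, x, training):
        k = self.k
        v = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        vf = v.reshape(v.shape[:5] + (k ** 3,))
        self._arg = vf.argmax(axis=-1)
        self._in_shape = x.shape
        return vf.max(axis=-1)

    def backward(self, dy):
        k = self.k
        N, C, D, H, W = self._in_shape
        Do, Ho, Wo = dy.shape[2:]
        i, j, l = np.unravel_index(self._arg, (k, k, k))
        d = np.arange(Do)[None, None, :, None, None] + i
        h = np.arange(Ho)[None, None, None, :, None] + j
        w = np.arange(Wo)[None, None, None, None, :] + l
        n = np.arange(N)[:, None, None, None, None]
        c = np.arange(C)[None, :, None, None, None]
        flat = (((n * C + c) * D + d) * H + h) * W + w
        dx = np.zeros(N * C * D * H * W, dtype=np.float32)
        np.add.at(dx, flat.ravel(), dy.ravel())
        return dx.reshape(self._in_shape)


class Dropout3d(Layer):
    """Channel dropout (whole feature maps), inverted scaling."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None,
                 name: str = "Dropout3d"):
        super().__init__()
        self.rate, self.name = rate, name
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape[:2]) < keep).astype(np.float32) / keep
        self._mask = mask[:, :, None, None, None]
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sigmoid(Layer):
    def __init__(self, name: str = "Sigmoid"):
        super().__init__()
        self.name = name

    def forward(self, x, training):
        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Adam:
    """Adam over a flat list of (layer, param-name) handles."""

    def __init__(self, handles, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.handles = list(handles)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in self.handles]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in self.handles]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for idx, (layer, name) in enumerate(self.handles):
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m[idx]
            v = self.v[idx]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (self.lr * (m / bc1)
                      / (np.sqrt(v / bc2) + self.eps))
            layer.params[name] -= update.astype(layer.params[name].dtype)

    def zero_grad(self):
        for layer, _ in self.handles:
            layer.grads.clear()


def step_lr(base_lr: float, epoch: int, step_size: int, gamma: float) -> float:
    """Learning rate decayed by ``gamma`` every ``step_size`` epochs."""
    return base_lr * gamma ** (epoch // step_size)
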