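"""Minimal trainable neural-network layers on numpy.

Supports N-dimensional convolution / transposed convolution (N = 1, 2, 3),
batch normalization, ReLU, 2-D max pooling and sequential containers —
exactly the operations the reconstruction and enhancement networks need.
Forward passes cache what the hand-derived backward passes require; all
parameters are float32.

Convolution is implemented with stride-tricks windowing plus a single
GEMM; the transposed convolution is the exact adjoint (input-gradient) of
the strided convolution, so gradients of one are computed by the other.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


def _tup(v, nd: int) -> tuple[int, ...]:
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * nd


def _pad_spatial(x: np.ndarray, pad: tuple[int, ...]) -> np.ndarray:
    if all(p == 0 for p in pad):
        return x
    width = [(0, 0), (0, 0)] + [(p, p) for p in pad]
    return np.pad(x, width)


def conv_forward(x: np.ndarray, w: np.ndarray, stride, pad):
    """Strided cross-correlation.  x: (B, C, *S); w: (O, C, *k).

    Returns (y, cache) with y: (B, O, *So), So_d = (S_d + 2 p_d - k_d)//s_d + 1.
    """
    nd = x.ndim - 2
    k = w.shape[2:]
    stride = _tup(stride, nd)
    pad = _tup(pad, nd)
    xp = _pad_spatial(x, pad)
    win = sliding_window_view(xp, k, axis=tuple(range(2, 2 + nd)))
    # win: (B, C, *Sfull, *k) -> strided view
    slc = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    win = win[slc]
    B = x.shape[0]
    So = win.shape[2 : 2 + nd]
    C_K = w.shape[1] * int(np.prod(k))
    x2 = np.moveaxis(win, 1, 1 + nd)  # (B, *So, C, *k)
    x2 = np.ascontiguousarray(x2).reshape(-1, C_K)
    w2 = w.reshape(w.shape[0], C_K)
    y = (x2 @ w2.T).reshape(B, *So, w.shape[0])
    y = np.moveaxis(y, -1, 1)
    cache = (x2, x.shape, w.shape, stride, pad)
    return np.ascontiguousarray(y), cache


def conv_weight_grad(gy: np.ndarray, cache) -> np.ndarray:
    """Weight gradient of conv_forward given the cached input windows."""
    x2, x_shape, w_shape, stride, pad = cache
    g2 = np.moveaxis(gy, 1, -1).reshape(-1, w_shape[0])
    return (g2.T @ x2).reshape(w_shape)


def conv_backward(gy: np.ndarray, w: np.ndarray, cache):
    """Gradients of conv_forward w.r.t. input and weight."""
    x2, x_shape, w_shape, stride, pad = cache
    gw = conv_weight_grad(gy, cache)
    gx = conv_input_grad(gy, w, stride, pad, x_shape[2:])
    return gx, gw


def _dilate(x: np.ndarray, stride: tuple[int, ...]) -> np.ndarray:
    """Insert stride-1 zeros between spatial samples."""
    if all(s == 1 for s in stride):
        return x
    nd = x.ndim - 2
    S = x.shape[2:]
    out_shape = x.shape[:2] + tuple((S[d] - 1) * stride[d] + 1 for d in range(nd))
    out = np.zeros(out_shape, dtype=x.dtype)
    slc = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    out[slc] = x
    return out


def conv_input_grad(gy: np.ndarray, w: np.ndarray, stride, pad, x_spatial):
    """Adjoint of conv_forward in its input: scatters gy back to x-space.

    Also serves as the forward pass of transposed convolution (with the
    weight stored as (C_in, C_out, *k) and gy playing the input role).
    """
    nd = gy.ndim - 2
    k = w.shape[2:]
    stride = _tup(stride, nd)
    pad = _tup(pad, nd)
    gyd = _dilate(gy, stride)
    # pad dilated gradient to k-1 on the left; on the right additionally
    # cover any input columns the strided conv never reached
    dil = gyd.shape[2:]
    width = [(0, 0), (0, 0)]
    for d in range(nd):
        covered = dil[d] + k[d] - 1  # size of full correlation result
        target = x_spatial[d] + 2 * pad[d]
        width.append((k[d] - 1, k[d] - 1 + max(0, target - covered)))
    gyp = np.pad(gyd, width)
    wf = w[(slice(None), slice(None)) + (slice(None, None, -1),) * nd]  # flip spatial
    wt = np.ascontiguousarray(np.swapaxes(wf, 0, 1))  # (C, O, *k)
    gx_full, _ = conv_forward(gyp, wt, stride=1, pad=0)
    slc = (slice(None), slice(None)) + tuple(
        slice(pad[d], pad[d] + x_spatial[d]) for d in range(nd)
    )
    return np.ascontiguousarray(gx_full[slc])


def convT_forward(x, w, stride, pad, output_padding):
    """Transposed convolution via one GEMM plus kernel-offset scatter-adds
    (avoids materializing zero-dilated im2col buffers).

    x: (B, Cin, *Lin); w: (Cin, Cout, *k).  Output spatial size per axis is
    ``(Lin-1)*stride - 2*pad + k + output_padding``.
    """
    from itertools import product

    nd = x.ndim - 2
    B, Cin = x.shape[:2]
    Lin = x.shape[2:]
    k = w.shape[2:]
    Cout = w.shape[1]
    x2 = np.moveaxis(x, 1, -1).reshape(-1, Cin)
    t = (x2 @ w.reshape(Cin, -1)).reshape(B, *Lin, Cout, *k)
    t = np.moveaxis(t, 1 + nd, 1)  # (B, Cout, *Lin, *k)
    buf_sp = tuple((Lin[d] - 1) * stride[d] + k[d] for d in range(nd))
    y = np.zeros((B, Cout, *buf_sp), dtype=x.dtype)
    for off in product(*map(range, k)):
        slc = tuple(
            slice(off[d], off[d] + stride[d] * (Lin[d] - 1) + 1, stride[d])
            for d in range(nd)
        )
        y[(slice(None), slice(None), *slc)] += t[
            (slice(None), slice(None)) + (slice(None),) * nd + off
        ]
    out_sp = tuple(
        buf_sp[d] - 2 * pad[d] + output_padding[d] for d in range(nd)
    )
    # crop the conv padding; extend by output_padding with zeros
    slc = tuple(slice(pad[d], buf_sp[d] - pad[d]) for d in range(nd))
    y = y[(slice(None), slice(None), *slc)]
    if any(op > 0 for op in output_padding):
        width = [(0, 0), (0, 0)] + [(0, output_padding[d]) for d in range(nd)]
        y = np.pad(y, width)
    assert y.shape[2:] == out_sp
    return y


def convT_weight_grad(x, gy, w_shape, stride, pad):
    """Weight gradient of convT_forward: gather strided slices of the
    (padded) output gradient per kernel offset."""
    from itertools import product

    nd = x.ndim - 2
    B, Cin = x.shape[:2]
    Lin = x.shape[2:]
    k = w_shape[2:]
    Cout = w_shape[1]
    width = [(0, 0), (0, 0)] + [(pad[d], pad[d]) for d in range(nd)]
    gyp = np.pad(gy, width)
    # right-pad if the buffer used during forward was larger (output_padding
    # never contributes gradient to the weights, so zero-extension suffices)
    buf_sp = tuple((Lin[d] - 1) * stride[d] + k[d] for d in range(nd))
    extra = [(0, 0), (0, 0)] + [
        (0, max(0, buf_sp[d] - gyp.shape[2 + d])) for d in range(nd)
    ]
    gyp = np.pad(gyp, extra)
    x2 = x.reshape(B, Cin, -1)
    gw = np.empty(w_shape, dtype=x.dtype)
    for off in product(*map(range, k)):
        slc = tuple(
            slice(off[d], off[d] + stride[d] * (Lin[d] - 1) + 1, stride[d])
            for d in range(nd)
        )
        g = gyp[(slice(None), slice(None), *slc)].reshape(B, Cout, -1)
        gw[(slice(None), slice(None), *off)] = np.einsum("bim,bom->io", x2, g)
    return gw


class Layer:
    """Base layer: forward caches, backward consumes the cache."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConvNd(Layer):
    """N-dimensional convolution (cross-correlation) with bias."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, ndim=1, rng=None):
        self.ndim = ndim
        k = _tup(kernel, ndim)
        self.stride = _tup(stride, ndim)
        self.pad = _tup(pad, ndim)
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * int(np.prod(k))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, *k))
        self.w = Param(w, "conv_w")
        self.b = Param(np.zeros(out_ch), "conv_b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        y, cache = conv_forward(x, self.w.data, self.stride, self.pad)
        self._cache = cache
        return y + self.b.data.reshape((1, -1) + (1,) * self.ndim)

    def backward(self, gy):
        gx, gw = conv_backward(gy, self.w.data, self._cache)
        self.w.grad += gw
        self.b.grad += gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        return gx


class ConvTransposeNd(Layer):
    """Transposed N-d convolution; output size is solved to match
    ``(L-1)*stride - 2*pad + kernel + output_padding`` per axis."""

    def __init__(
        self, in_ch, out_ch, kernel, stride=1, pad=0, output_padding=0, ndim=3, rng=None
    ):
        self.ndim = ndim
        self.kernel = _tup(kernel, ndim)
        self.stride = _tup(stride, ndim)
        self.pad = _tup(pad, ndim)
        self.output_padding = _tup(output_padding, ndim)
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * int(np.prod(self.kernel))
        # stored in conv layout (O=in_ch, C=out_ch, *k): the forward pass is
        # the adjoint of a conv whose input has out_ch channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch, *self.kernel))
        self.w = Param(w, "deconv_w")
        self.b = Param(np.zeros(out_ch), "deconv_b")
        self._x = None

    def params(self):
        return [self.w, self.b]

    def out_spatial(self, in_spatial):
        return tuple(
            (in_spatial[d] - 1) * self.stride[d]
            - 2 * self.pad[d]
            + self.kernel[d]
            + self.output_padding[d]
            for d in range(self.ndim)
        )

    def forward(self, x, train):
        self._x = x
        y = convT_forward(x, self.w.data, self.stride, self.pad, self.output_padding)
        return y + self.b.data.reshape((1, -1) + (1,) * self.ndim)

    def backward(self, gy):
        # the adjoint of the scatter is a plain strided conv with the same
        # weight (layout (Cin, Cout, *k) read as (O, C, *k))
        gx, _ = conv_forward(gy, self.w.data, self.stride, self.pad)
        self.w.grad += convT_weight_grad(self._x, gy, self.w.data.shape, self.stride, self.pad)
        self.b.grad += gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        return gx


class BatchNorm(Layer):
    """Batch normalization over (batch, *spatial) per channel.

    ``y = gamma * (x - mu) / sqrt(var + chi) + beta`` with ``chi`` a small
    stabilizing constant (default 1e-3).  Training mode uses batch
    statistics and updates exponential running statistics; eval mode uses
    the running statistics.  A batch of one sample in training mode is an
    error (the variance is undefined for learning purposes).
    """

    def __init__(self, channels: int, chi: float = 1e-3, momentum: float = 0.1):
        self.chi = float(chi)
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), "bn_gamma")
        self.beta = Param(np.zeros(channels), "bn_beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if train:
            if x.shape[0] < 2:
                raise ValueError("BatchNorm requires batch size >= 2 in training mode")
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu = self.running_mean
            var = self.running_var
        inv = 1.0 / np.sqrt(var + self.chi)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv, axes, shape)
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, gy):
        xhat, inv, axes, shape = self._cache
        m = gy.size / gy.shape[1]
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.data.reshape(shape) * inv.reshape(shape)
        mean_gy = gy.mean(axis=axes).reshape(shape)
        mean_gyx = (gy * xhat).mean(axis=axes).reshape(shape)
        return g * (gy - mean_gy - xhat * mean_gyx)


def batch_norm(y: np.ndarray, gamma, beta, chi: float = 1e-3) -> np.ndarray:
    """Functional batch normalization over the batch axis (axis 0).

    Returns ``gamma * (y - mean) / sqrt(var + chi) + beta`` using the
    statistics of the given batch.  Mirrors the training-mode behavior of
    :class:`BatchNorm` for a (batch, channel, ...) tensor or a 1-D batch.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("batch_norm requires a batch of at least 2")
    if y.ndim == 1:
        mu, var = y.mean(), y.var()
        return gamma * (y - mu) / np.sqrt(var + chi) + beta
    axes = (0,) + tuple(range(2, y.ndim))
    shape = (1, -1) + (1,) * (y.ndim - 2)
    mu = y.mean(axis=axes).reshape(shape)
    var = y.var(axis=axes).reshape(shape)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (y.shape[1],)).reshape(shape)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (y.shape[1],)).reshape(shape)
    return gamma * (y - mu) / np.sqrt(var + chi) + beta


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (spatial sides must be even)."""

    def forward(self, x, train):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        xc = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        idx = xc.argmax(axis=-1)
        self._idx = idx
        self._in_shape = x.shape
        return np.take_along_axis(xc, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        B, C, H, W = self._in_shape
        gc = np.zeros((B, C, H // 2, W // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gc, self._idx[..., None], gy[..., None], axis=-1)
        gx = gc.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gx.reshape(B, C, H, W)


class Reshape(Layer):
    """Reshape the per-sample feature block (channels included)."""

    def __init__(self, out_shape: tuple[int, ...]):
        self.out_shape = out_shape

    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], *self.out_shape)

    def backward(self, gy):
        return gy.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff.astype(np.float32)


def param_count(layer: Layer) -> int:
    return int(sum(p.data.size for p in layer.params()))
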