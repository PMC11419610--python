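"""Deformable 2-D convolution with learned fractional offsets.

A regular k x k convolution samples the input on the fixed grid
``R = {(-1,-1), (-1,0), ..., (1,1)}`` around each output position p0:
``y(p0) = sum_n w(p_n) * x(p0 + p_n)``.  The deformable variant displaces
every tap by a learned, input-dependent fractional offset:
``y(p0) = sum_n w(p_n) * x(p0 + p_n + delta_{p0,n})``, with non-integer
positions read by bilinear interpolation and zero padding outside the map.
With all offsets zero the operation reduces exactly to the regular
convolution.  Offsets are predicted by an ordinary convolution applied to the
layer input, so sampling adapts to the geometry of the object under the
kernel — the property that makes the operator effective on soft-bodied,
deforming targets.

Two routes are provided and cross-checked in the tests:

* :func:`bilinear_sample` / :func:`deformable_conv2d` — a plain-numpy
  reference of the forward operation (stride 1, zero padding k//2);
* :class:`DeformConv2d` / :class:`DCNBlock` — differentiable layers built on
  the :mod:`~flexdetect.autograd` ``grid_sample`` primitive, usable inside
  the demo detector.  ``DCNBlock`` is the residual unit: a CBL stem followed
  by two offset-predicting deformable layers whose composition is summed with
  a skip connection from the stem output.

Offset channel layout is interleaved ``(dy_1, dx_1, ..., dy_N, dx_N)``.
Only v1 semantics are implemented (no per-tap modulation mask).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, grid_sample, stack
from .nn import CBL, BatchNorm2d, Conv2d, Module, _ACTS

__all__ = [
    "sampling_grid",
    "bilinear_sample",
    "deformable_conv2d",
    "DeformConv2d",
    "DCNBlock",
]


def sampling_grid(kernel: int) -> np.ndarray:
    """The regular grid R of a k x k kernel as N x 2 (dy, dx) integer rows.

    Centered at 0 for odd k; N = k**2, enumerated row-major.
    """
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    half = (kernel - 1) / 2.0
    offs = np.arange(kernel) - half
    grid = np.array([(dy, dx) for dy in offs for dx in offs])
    return grid if kernel % 2 else grid  # fractional grid for even k is allowed


def bilinear_sample(channel: np.ndarray, p: tuple[float, float]) -> float:
    """Bilinear interpolation of a 2-D map at fractional point ``p = (y, x)``.

    The four integer neighbors are blended; neighbors outside the map
    contribute zero (zero padding), so a point fully outside returns 0.
    """
    channel = np.asarray(channel, dtype=float)
    h, w = channel.shape
    y, x = float(p[0]), float(p[1])
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    val = 0.0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            if 0 <= yy < h and 0 <= xx < w and wy * wx != 0.0:
                val += wy * wx * channel[yy, xx]
    return float(val)


def deformable_conv2d(x: np.ndarray, w: np.ndarray,
                      offsets: np.ndarray | None = None) -> np.ndarray:
    """Reference deformable convolution (numpy, stride 1, zero pad k//2).

    Parameters
    ----------
    x : (C_in, H, W) input feature map.
    w : (C_out, C_in, k, k) kernel weights.
    offsets : (2N, H, W) per-position per-tap displacements, interleaved
        (dy_1, dx_1, ..., dy_N, dx_N); ``None`` means all zero, in which case
        the result equals the regular convolution.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    ci, h, wd = x.shape
    co, ci2, k, k2 = w.shape
    if ci != ci2 or k != k2:
        raise ValueError(f"shape mismatch: x has {ci} channels, w is {w.shape}")
    n_taps = k * k
    if offsets is None:
        offsets = np.zeros((2 * n_taps, h, wd))
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (2 * n_taps, h, wd):
        raise ValueError(f"offsets shape {offsets.shape} != {(2 * n_taps, h, wd)}")

    grid = sampling_grid(k)
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(wd, dtype=float),
                         indexing="ij")
    out = np.zeros((co, h, wd))
    for n in range(n_taps):
        py = yy + grid[n, 0] + offsets[2 * n]
        px = xx + grid[n, 1] + offsets[2 * n + 1]
        sampled = _bilinear_sample_maps(x, py, px)  # (C_in, H, W)
        out += np.einsum("oc,chw->ohw", w[:, :, n // k, n % k], sampled)
    return out


def _bilinear_sample_maps(x: np.ndarray, py: np.ndarray, px: np.ndarray) -> np.ndarray:
    """Vectorized bilinear sampling of all channels at point maps (H, W)."""
    c, h, w = x.shape
    y0 = np.floor(py).astype(int)
    x0 = np.floor(px).astype(int)
    fy, fx = py - y0, px - x0
    out = np.zeros((c, *py.shape))
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yi, xi = y0 + dy, x0 + dx
            valid = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
            yc = np.clip(yi, 0, h - 1)
            xc = np.clip(xi, 0, w - 1)
            out += (wy * wx * valid) * x[:, yc, xc]
    return out


class DeformConv2d(Module):
    """Differentiable deformable convolution layer (stride 1, pad k//2).

    The offset field is produced by an internal regular convolution on the
    layer input (2N output channels, zero-initialized so training starts at
    the plain-convolution limit).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.n_taps = kernel * kernel
        self.conv_weight = Conv2d(in_ch, out_ch, kernel, rng=rng).weight
        self.bias = None
        self.offset_conv = Conv2d(in_ch, 2 * self.n_taps, kernel, rng=rng)
        self.offset_conv.weight.data[:] = 0.0  # start at the regular-conv limit
        if self.offset_conv.bias is not None:
            self.offset_conv.bias.data[:] = 0.0
        self.grid = sampling_grid(kernel)

    def forward(self, x: Tensor, offsets: Tensor | None = None) -> Tensor:
        if offsets is None:
            offsets = self.offset_conv(x)
        return self.apply_offsets(x, offsets)

    def apply_offsets(self, x: Tensor, offsets: Tensor) -> Tensor:
        n, c, h, w = x.shape
        yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                             indexing="ij")
        base = Tensor(np.stack([yy.ravel(), xx.ravel()]))  # (2, H*W)
        wmat = self.conv_weight.reshape(
            self.conv_weight.shape[0], c * self.n_taps)
        samples = []
        for t in range(self.n_taps):
            off = stack([offsets[:, 2 * t].reshape(n, h * w),
                         offsets[:, 2 * t + 1].reshape(n, h * w)], axis=1)
            shift = Tensor(self.grid[t].reshape(2, 1))
            coords = off + base + shift  # (N, 2, H*W)
            samples.append(grid_sample(x, coords))  # (N, C, H*W)
        # (N, C, taps, H*W) -> (N, C*taps, H*W); weight rows follow the same
        # (channel, tap) ordering as w.reshape(out, C*k*k)
        sampled = stack(samples, axis=2).reshape(n, c * self.n_taps, h * w)
        y = wmat.matmul(sampled)  # (N, out, H*W) via broadcasting
        return y.reshape(n, -1, h, w)


class DCNBlock(Module):
    """Residual deformable unit: CBL stem, two deformable layers, skip sum.

    ``h = CBL(x)``; ``out = act(BN(DConv2(act(BN(DConv1(h))))) + h)``.
    Channel counts of the skip and main path must match (enforced by using
    ``out_ch`` throughout after the stem).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, activation: str = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stem = CBL(in_ch, out_ch, kernel=3, stride=stride,
                        activation=activation, rng=rng)
        self.dconv1 = DeformConv2d(out_ch, out_ch, kernel, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.dconv2 = DeformConv2d(out_ch, out_ch, kernel, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.act = activation

    def forward(self, x: Tensor) -> Tensor:
        act = _ACTS[self.act]
        h = self.stem(x)
        y = act(self.bn1(self.dconv1(h)))
        y = self.bn2(self.dconv2(y))
        return act(y + h)
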