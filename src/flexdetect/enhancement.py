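"""Contrast-limited adaptive histogram equalization with a boundary channel.

Underwater imagery suffers low contrast, a blue-green color cast and blurred
foreground/background boundaries.  This module implements a tiled CLAHE whose
clip limit derives from a maximum mapping-function slope, plus a boundary
enhancement channel that extracts gradient structure at two scales and fuses
it additively with the equalized image.

The mapping for a tile of M x M pixels is ``m(i) = 255 * CDF(i) / M**2``
(round-half-up), whose slope is bounded by clipping the tile histogram at a
threshold derived from the maximal admissible slope S_max:
``H_max = S_max * M**2 / 255``.  Clipped mass is redistributed uniformly in a
single pass: bins below the threshold T gain ``L = excess / 256``; clipped
bins are set to ``T + L``.

Color is handled on the luma channel of a YCbCr decomposition by default,
which raises contrast without shifting hue; a per-channel mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ClaheParams",
    "BemParams",
    "clip_redistribute",
    "clip_threshold_from_slope",
    "tile_mapping",
    "clahe",
    "boundary_channel",
    "enhance",
    "global_he",
    "rms_contrast",
]

NBINS = 256

# ITU-R BT.601 luma/chroma weights
_RGB2YCBCR = np.array([[0.299, 0.587, 0.114],
                       [-0.168736, -0.331264, 0.5],
                       [0.5, -0.418688, -0.081312]])
_YCBCR2RGB = np.linalg.inv(_RGB2YCBCR)


@dataclass
class ClaheParams:
    """Tiled-CLAHE configuration.

    tiles_x, tiles_y : number of tiles per axis (>= 1).
    s_max : maximal slope of the local gray-level mapping; the clip threshold
        is ``s_max * n_tile_pixels / 255``.  ``None`` disables clipping.
    channel_mode : 'luminance' equalizes the luma channel only; 'per_channel'
        equalizes R, G, B independently.
    """

    tiles_x: int = 8
    tiles_y: int = 8
    s_max: float | None = 4.0
    channel_mode: str = "luminance"

    def __post_init__(self) -> None:
        if self.tiles_x < 1 or self.tiles_y < 1:
            raise ValueError("tile counts must be >= 1")
        if self.s_max is not None and self.s_max <= 0:
            raise ValueError("s_max must be > 0")
        if self.channel_mode not in ("luminance", "per_channel"):
            raise ValueError(f"unknown channel_mode {self.channel_mode!r}")


@dataclass
class BemParams:
    """Boundary-enhancement channel configuration.

    fine_scale_radius : Gaussian pre-smoothing radius (px) for the
        full-resolution gradient map (0 disables smoothing).
    coarse_downsample : block-average factor for the coarse gradient map.
    mask_threshold : coarse-gradient fraction below which fine structure is
        suppressed (separates boundaries from texture noise).
    fusion_weight : gamma, additive weight of the boundary map at fusion.
    """

    fine_scale_radius: float = 1.0
    coarse_downsample: int = 4
    mask_threshold: float = 0.2
    fusion_weight: float = 0.3

    def __post_init__(self) -> None:
        if self.coarse_downsample < 2:
            raise ValueError("coarse_downsample must be >= 2")
        if not 0.0 <= self.mask_threshold <= 1.0:
            raise ValueError("mask_threshold must be in [0,1]")
        if self.fusion_weight < 0:
            raise ValueError("fusion_weight must be >= 0")


def clip_threshold_from_slope(s_max: float, m: float) -> float:
    """Histogram clip threshold for a tile of side ``m`` (M x M pixels).

    ``H_max = S_max * M**2 / 255``: a bin this tall yields mapping slope S_max.
    """
    if s_max <= 0:
        raise ValueError("s_max must be > 0")
    if m < 1:
        raise ValueError("window side must be >= 1")
    return s_max * m * m / 255.0


def clip_redistribute(hist: np.ndarray, threshold: float) -> np.ndarray:
    """Clip histogram bins at ``threshold`` and redistribute the excess.

    Single-pass uniform redistribution: with ``excess = sum(max(0, h_i - T))``
    and ``L = excess / nbins``, bins below T become ``h_i + L`` and clipped
    bins become ``T + L``.  Total mass is conserved exactly; clipped bins may
    end slightly above T, which is accepted.
    """
    if threshold <= 0:
        raise ValueError("clip threshold must be > 0")
    hist = np.asarray(hist, dtype=float)
    excess = np.maximum(hist - threshold, 0.0).sum()
    lift = excess / hist.size
    return np.where(hist >= threshold, threshold + lift, hist + lift)


def tile_mapping(hist: np.ndarray) -> np.ndarray:
    """Gray-level lookup table from a (possibly clipped) tile histogram.

    ``m(i) = round(255 * CDF(i) / total)`` with round-half-up; monotone
    non-decreasing with ``m(last) = 255``.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty region: histogram total must be > 0")
    cdf = np.cumsum(hist)
    # round-half-up, not banker's rounding
    lut = np.floor(255.0 * cdf / total + 0.5)
    return np.clip(lut, 0, 255).astype(np.uint8)


def _channel_histograms(channel: np.ndarray, tiles_y: int, tiles_x: int):
    """Per-tile histograms plus tile geometry for one uint8 channel."""
    h, w = channel.shape
    ys = np.linspace(0, h, tiles_y + 1).astype(int)
    xs = np.linspace(0, w, tiles_x + 1).astype(int)
    hists = np.empty((tiles_y, tiles_x, NBINS), dtype=float)
    centers_y = np.empty(tiles_y)
    centers_x = np.empty(tiles_x)
    for ti in range(tiles_y):
        for tj in range(tiles_x):
            tile = channel[ys[ti]:ys[ti + 1], xs[tj]:xs[tj + 1]]
            hists[ti, tj] = np.bincount(tile.ravel(), minlength=NBINS)
    centers_y[:] = (ys[:-1] + ys[1:]) / 2.0 - 0.5
    centers_x[:] = (xs[:-1] + xs[1:]) / 2.0 - 0.5
    return hists, centers_y, centers_x


def _interp_axis(coords: np.ndarray, centers: np.ndarray):
    """Lower tile index and blend weight per pixel coordinate (clamped)."""
    idx = np.searchsorted(centers, coords) - 1
    idx = np.clip(idx, 0, max(len(centers) - 2, 0))
    if len(centers) == 1:
        return np.zeros_like(idx), np.zeros(len(coords))
    span = centers[idx + 1] - centers[idx]
    t = (coords - centers[idx]) / span
    return idx, np.clip(t, 0.0, 1.0)


def _clahe_channel(channel: np.ndarray, params: ClaheParams) -> np.ndarray:
    h, w = channel.shape
    if h < params.tiles_y or w < params.tiles_x:
        raise ValueError(
            f"image {h}x{w} smaller than tile grid {params.tiles_y}x{params.tiles_x}")
    hists, cy, cx = _channel_histograms(channel, params.tiles_y, params.tiles_x)
    luts = np.empty((params.tiles_y, params.tiles_x, NBINS), dtype=np.uint8)
    for ti in range(params.tiles_y):
        for tj in range(params.tiles_x):
            hist = hists[ti, tj]
            if params.s_max is not None:
                t = clip_threshold_from_slope(params.s_max, np.sqrt(hist.sum()))
                hist = clip_redistribute(hist, t)
            luts[ti, tj] = tile_mapping(hist)

    yy = np.arange(h, dtype=float)
    xx = np.arange(w, dtype=float)
    iy, ty = _interp_axis(yy, cy)
    ix, tx = _interp_axis(xx, cx)
    iy = iy[:, None] * np.ones(w, dtype=int)
    ix = ix[None, :] * np.ones((h, 1), dtype=int)
    ty = ty[:, None]
    tx = tx[None, :]
    v = channel.astype(int)
    iy1 = np.minimum(iy + 1, params.tiles_y - 1)
    ix1 = np.minimum(ix + 1, params.tiles_x - 1)
    out = ((1 - ty) * (1 - tx) * luts[iy, ix, v]
           + (1 - ty) * tx * luts[iy, ix1, v]
           + ty * (1 - tx) * luts[iy1, ix, v]
           + ty * tx * luts[iy1, ix1, v])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _to_ycbcr(img: np.ndarray) -> np.ndarray:
    ycc = img.astype(float) @ _RGB2YCBCR.T
    ycc[..., 1:] += 128.0
    return ycc


def _from_ycbcr(ycc: np.ndarray) -> np.ndarray:
    ycc = ycc.copy()
    ycc[..., 1:] -= 128.0
    rgb = ycc @ _YCBCR2RGB.T
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _apply_on_channels(img: np.ndarray, fn, channel_mode: str) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    if channel_mode == "per_channel":
        return np.stack([fn(img[..., c]) for c in range(3)], axis=-1)
    ycc = _to_ycbcr(img)
    y8 = np.clip(np.rint(ycc[..., 0]), 0, 255).astype(np.uint8)
    ycc[..., 0] = fn(y8)
    return _from_ycbcr(ycc)


def clahe(img: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Tiled contrast-limited adaptive histogram equalization.

    Per-tile clipped histograms give per-tile lookup tables; each output pixel
    bilinearly blends the four surrounding tile mappings (edge and corner
    regions degrade to linear/constant blending).
    """
    params = params or ClaheParams()
    return _apply_on_channels(img, lambda ch: _clahe_channel(ch, params),
                              params.channel_mode)


def global_he(img: np.ndarray) -> np.ndarray:
    """Plain global histogram equalization on luminance (baseline)."""

    def _he(ch: np.ndarray) -> np.ndarray:
        hist = np.bincount(ch.ravel(), minlength=NBINS)
        return tile_mapping(hist)[ch]

    return _apply_on_channels(img, _he, "luminance")


def _gradient_magnitude(gray: np.ndarray, sigma: float = 0.0) -> np.ndarray:
    g = gray.astype(float)
    if sigma > 0:
        g = ndimage.gaussian_filter(g, sigma)
    gx = ndimage.sobel(g, axis=1)
    gy = ndimage.sobel(g, axis=0)
    return np.hypot(gx, gy)


def _normalize01(a: np.ndarray) -> np.ndarray:
    m = a.max()
    return a / m if m > 0 else a


def boundary_channel(img: np.ndarray, params: BemParams | None = None) -> np.ndarray:
    """Boundary map in [0,1]: fine gradients gated by coarse-scale gradients.

    A full-resolution gradient magnitude map captures detail; the gradient of
    a block-averaged copy, upsampled back, indicates where genuine large-scale
    boundaries exist.  Fine structure without coarse support (texture, noise)
    is zeroed by the mask ``B_coarse > tau``.
    """
    params = params or BemParams()
    img = np.asarray(img)
    gray = img.astype(float) @ _RGB2YCBCR[0]
    fine = _normalize01(_gradient_magnitude(gray, params.fine_scale_radius))

    d = params.coarse_downsample
    h, w = gray.shape
    ph, pw = (-h) % d, (-w) % d
    padded = np.pad(gray, ((0, ph), (0, pw)), mode="edge")
    coarse_img = padded.reshape(padded.shape[0] // d, d,
                                padded.shape[1] // d, d).mean(axis=(1, 3))
    coarse = _normalize01(_gradient_magnitude(coarse_img))
    coarse_up = np.kron(coarse, np.ones((d, d)))[:h, :w]

    return _normalize01(fine * (coarse_up > params.mask_threshold))


def enhance(img: np.ndarray,
            clahe_params: ClaheParams | None = None,
            bem_params: BemParams | None = None) -> np.ndarray:
    """Full enhancement: CLAHE channel plus additive boundary channel.

    ``out = clip(CLAHE(img) + gamma * 255 * B)`` with the boundary map B
    broadcast over color channels.  Pure function of (image, parameters).
    """
    bem_params = bem_params or BemParams()
    eq = clahe(img, clahe_params).astype(float)
    if bem_params.fusion_weight > 0:
        b = boundary_channel(img, bem_params)
        eq = eq + bem_params.fusion_weight * 255.0 * b[..., None]
    return np.clip(np.rint(eq), 0, 255).astype(np.uint8)


def rms_contrast(img: np.ndarray) -> float:
    """Root-mean-square contrast of the luminance channel."""
    gray = np.asarray(img).astype(float) @ _RGB2YCBCR[0]
    return float(gray.std())
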