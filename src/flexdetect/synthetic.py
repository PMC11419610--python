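"""Synthetic underwater detection scenes with ground-truth labels.

Generates images that mimic the statistical difficulties of real underwater
footage of soft-bodied organisms — low contrast, blue-green color cast, blur,
noise, and deformable targets — so every other module can be exercised and
measured without an external dataset.

Objects are Fourier-perturbed ellipses: the radius of an ellipse is modulated
by low-order cosine harmonics, ``r(theta) = r0 * (1 + sum_k a_k cos(k theta
+ phi_k))``, giving smooth, organism-like silhouettes whose deformation
amplitude is a dial.  Four classes with fixed visual signatures are rendered
by default (holothurian: elongated dull-brown body; starfish: orange
five-lobed outline; jellyfish: pale translucent bell; octopus: purple blob
with spots).  Bounding boxes are measured from the rendered masks, so labels
are tight by construction.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_formats import Box, DatasetManifest, write_image, write_yolo_labels

__all__ = ["SceneSpec", "CLASS_NAMES", "generate_scene", "degrade_underwater",
           "perturb_labels", "make_dataset"]

CLASS_NAMES = ["holothurian", "starfish", "jellyfish", "octopus"]

# per-class render signature: base RGB color, aspect ratio, lobes (harmonic)
_CLASS_STYLE = {
    0: {"color": (150, 110, 70), "aspect": 2.6, "lobes": 0},   # holothurian
    1: {"color": (230, 140, 50), "aspect": 1.0, "lobes": 5},   # starfish
    2: {"color": (225, 185, 205), "aspect": 1.1, "lobes": 0},  # jellyfish
    3: {"color": (140, 70, 160), "aspect": 1.3, "lobes": 0},   # octopus
}


@dataclass
class SceneSpec:
    """Generation conditions for one synthetic underwater scene.

    Defaults emulate the documented difficulties of the target imagery:
    1-4 organisms of 4 classes per frame, visible deformation, strong
    blue-green cast, halved contrast, mild blur and sensor noise.
    """

    height: int = 128
    width: int = 128
    class_ids: tuple[int, ...] = (0, 1, 2, 3)
    min_objects: int = 1
    max_objects: int = 4
    min_radius_frac: float = 0.08   # of min(H, W)
    max_radius_frac: float = 0.16
    deformation: float = 0.25       # harmonic amplitude of the silhouette
    # degradation (applied by degrade_underwater)
    red_gain: float = 0.55
    green_gain: float = 1.0
    blue_gain: float = 1.15
    contrast: float = 0.55          # compression toward mid-gray, 1 = off
    blur_sigma: float = 1.0
    noise_sd: float = 4.0
    # label corruption
    label_noise_fraction: float = 0.0
    label_jitter: float = 0.3

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene must be at least 16 x 16")
        if not 0.0 <= self.label_noise_fraction <= 1.0:
            raise ValueError("label_noise_fraction must be in [0, 1]")
        if self.min_objects < 0 or self.max_objects < self.min_objects:
            raise ValueError("invalid objects-per-image range")


def _background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Smooth seabed-like background: low-frequency luminance on a teal base."""
    base = np.array([70.0, 120.0, 125.0])
    lum = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=min(h, w) / 8)
    lum = lum / (np.abs(lum).max() + 1e-9) * 30.0
    grain = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=1.5) * 6.0
    img = base[None, None, :] + (lum + grain)[..., None]
    return img


def _blob_mask(rng: np.random.Generator, h: int, w: int, cy: float, cx: float,
               radius: float, aspect: float, lobes: int,
               deformation: float) -> np.ndarray:
    """Rasterize one Fourier-perturbed ellipse as a boolean mask."""
    n_harm = 3
    amps = rng.uniform(0.3, 1.0, n_harm) * deformation / n_harm
    phases = rng.uniform(0, 2 * math.pi, n_harm)
    lobe_amp = 0.35 if lobes else 0.0
    lobe_phase = rng.uniform(0, 2 * math.pi)
    rot = rng.uniform(0, math.pi)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - cy, xx - cx
    ca, sa = math.cos(rot), math.sin(rot)
    u = (ca * dx + sa * dy) * (1.0 / aspect)
    v = -sa * dx + ca * dy
    rr = np.hypot(u, v)
    theta = np.arctan2(v, u)
    bound = np.full_like(theta, 1.0)
    for k in range(n_harm):
        bound += amps[k] * np.cos((k + 2) * theta + phases[k])
    if lobes:
        bound += lobe_amp * np.cos(lobes * theta + lobe_phase)
    return rr <= radius * np.maximum(bound, 0.15)


def _paint(img: np.ndarray, mask: np.ndarray, cls: int,
           rng: np.random.Generator) -> None:
    color = np.array(_CLASS_STYLE[cls]["color"], dtype=float)
    h, w = mask.shape
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), 1.0) * 12.0
    shade = color[None, None, :] + texture[..., None]
    if cls == 3:  # octopus: bright spots
        spots = ndimage.gaussian_filter(rng.random((h, w)), 1.0) > 0.62
        shade = np.where(spots[..., None], shade + 45.0, shade)
    if cls == 2:  # jellyfish: translucent bell
        shade = 0.55 * shade + 0.45 * img
    img[mask] = shade[mask]


def _mask_to_box(mask: np.ndarray, cls: int) -> Box:
    ys, xs = np.nonzero(mask)
    h, w = mask.shape
    # half-open pixel box -> normalized, continuous coordinates
    x1, x2 = xs.min(), xs.max() + 1
    y1, y2 = ys.min(), ys.max() + 1
    return Box.from_corners(cls, x1 / w, y1 / h, x2 / w, y2 / h)


def generate_scene(spec: SceneSpec, seed: int, degrade: bool = True,
                   return_masks: bool = False):
    """Render one scene; returns (image uint8 HxWx3, tight boxes).

    Deterministic per (spec, seed).  Object placement rejects strong overlap;
    if a non-overlapping placement cannot be found the object count is
    reduced, and a scene that can hold no requested object raises.  With
    ``return_masks=True`` the per-object boolean silhouettes are returned as
    a third element (used by label-tightness oracles).
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    img = _background(rng, h, w)
    n_obj = int(rng.integers(spec.min_objects, spec.max_objects + 1))
    boxes: list[Box] = []
    masks: list[np.ndarray] = []
    placed: list[tuple[float, float, float]] = []
    attempts_per_obj = 40
    for _ in range(n_obj):
        ok = False
        for _try in range(attempts_per_obj):
            radius = rng.uniform(spec.min_radius_frac, spec.max_radius_frac) * min(h, w)
            margin = radius * 1.6
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(np.hypot(cy - py, cx - px) > 1.15 * (radius + pr)
                   for py, px, pr in placed):
                ok = True
                break
        if not ok:
            if not boxes and spec.min_objects > 0:
                raise ValueError("cannot place any object: scene too small/full")
            continue
        cls = int(rng.choice(spec.class_ids))
        style = _CLASS_STYLE[cls]
        mask = _blob_mask(rng, h, w, cy, cx, radius, style["aspect"],
                          style["lobes"], spec.deformation)
        if not mask.any():
            continue
        _paint(img, mask, cls, rng)
        boxes.append(_mask_to_box(mask, cls))
        masks.append(mask)
        placed.append((cy, cx, radius))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if degrade:
        img = degrade_underwater(img, spec, seed=seed + 1)
    if return_masks:
        return img, boxes, masks
    return img, boxes


def degrade_underwater(img: np.ndarray, spec: SceneSpec,
                       seed: int = 0) -> np.ndarray:
    """Apply the underwater degradation chain.

    Channel-wise gain (red suppressed, green/blue boosted), contrast
    compression toward mid-gray, Gaussian blur, additive Gaussian noise; the
    result is clipped to [0, 255].  With all-off parameters (gains 1,
    contrast 1, blur 0, noise 0) this is the identity.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(img, dtype=float)
    gains = np.array([spec.red_gain, spec.green_gain, spec.blue_gain])
    out = out * gains[None, None, :]
    out = 128.0 + spec.contrast * (out - 128.0)
    if spec.blur_sigma > 0:
        out = np.stack([ndimage.gaussian_filter(out[..., c], spec.blur_sigma)
                        for c in range(3)], axis=-1)
    if spec.noise_sd > 0:
        out = out + rng.normal(0, spec.noise_sd, out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def perturb_labels(boxes: Sequence[Box], fraction: float, jitter: float,
                   seed: int) -> tuple[list[Box], np.ndarray]:
    """Corrupt a seeded fraction of boxes with multiplicative jitter.

    Each selected box has its center shifted by ``Normal(0, jitter * size)``
    and its size scaled by ``1 + Normal(0, jitter)`` (clamped positive), then
    clipped to the unit square.  Returns the new boxes and a boolean flag per
    box recording which were corrupted — consumed by the loss-robustness
    experiments.
    """
    rng = np.random.default_rng(seed)
    corrupted = rng.random(len(boxes)) < fraction
    out: list[Box] = []
    for box, bad in zip(boxes, corrupted):
        if not bad or jitter == 0.0:
            out.append(box)
            continue
        cx = box.cx + rng.normal(0, jitter * box.w)
        cy = box.cy + rng.normal(0, jitter * box.h)
        w = box.w * max(1.0 + rng.normal(0, jitter), 0.2)
        h = box.h * max(1.0 + rng.normal(0, jitter), 0.2)
        cx = float(np.clip(cx, 0.0, 1.0))
        cy = float(np.clip(cy, 0.0, 1.0))
        jittered = Box(box.cls, cx, cy, min(w, 1.0), min(h, 1.0), box.conf)
        try:
            out.append(jittered.clipped())
        except Exception:
            out.append(box)  # jitter pushed the box off-image: keep original
    return out, corrupted


def make_dataset(out_dir: str | Path, n_images: int, spec: SceneSpec,
                 seed: int, split: str = "train") -> DatasetManifest:
    """Write ``n_images`` scenes as an images/labels/manifest tree."""
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    labels_dir = out_dir / "labels"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)
    names = [CLASS_NAMES[c] for c in spec.class_ids]
    remap = {c: i for i, c in enumerate(spec.class_ids)}
    for i in range(n_images):
        img, boxes = generate_scene(spec, seed=seed * 100_003 + i)
        if spec.label_noise_fraction > 0:
            boxes, _ = perturb_labels(boxes, spec.label_noise_fraction,
                                      spec.label_jitter, seed=seed * 100_003 + i + 7)
        boxes = [replace(b, cls=remap[b.cls]) for b in boxes]
        stem = f"{split}_{i:05d}"
        write_image(img, images_dir / f"{stem}.png")
        write_yolo_labels(boxes, labels_dir / f"{stem}.txt")
    manifest = DatasetManifest(images_dir, labels_dir, names, split)
    manifest.save(out_dir / "manifest.yaml")
    return manifest
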