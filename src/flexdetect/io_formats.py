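"""Image and label I/O with the coordinate conventions used across the package.

Conventions
-----------
* Images are H x W x 3 ``uint8`` RGB arrays ("ImageU8"), origin at the top-left
  corner, x rightward, y downward.
* Boxes are stored in normalized center form ``(cls, cx, cy, w, h[, conf])``
  with all coordinates in [0, 1], the format written by YOLO-style annotation
  tools (one whitespace-separated line per object).  Corner boxes obtained from
  :meth:`Box.to_corners` are continuous; when rasterized they are half-open,
  ``[x1, x2) x [y1, y2)``.
* A dataset is a directory pair ``images_dir``/``labels_dir`` plus a class-name
  list, described by a small YAML manifest (:class:`DatasetManifest`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Box",
    "DatasetManifest",
    "read_image",
    "write_image",
    "read_yolo_labels",
    "write_yolo_labels",
]


class FormatError(ValueError):
    """Raised when an image or label file violates the expected format."""


@dataclass
class Box:
    """Axis-aligned bounding box in normalized center form.

    Attributes
    ----------
    cls : int
        Non-negative class id.
    cx, cy : float
        Box center in [0, 1] image-fraction coordinates.
    w, h : float
        Box width/height in (0, 1].
    conf : float, optional
        Detection confidence in [0, 1]; ``None`` for ground truth.
    """

    cls: int
    cx: float
    cy: float
    w: float
    h: float
    conf: Optional[float] = None

    def to_corners(self) -> tuple[float, float, float, float]:
        """Return ``(x1, y1, x2, y2)`` corner form (still normalized)."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @staticmethod
    def from_corners(cls: int, x1: float, y1: float, x2: float, y2: float,
                     conf: Optional[float] = None) -> "Box":
        if not (x2 > x1 and y2 > y1):
            raise FormatError(f"degenerate corner box ({x1},{y1},{x2},{y2})")
        return Box(cls, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1, conf)

    def clipped(self) -> "Box":
        """Clip the box to the unit square, preserving validity."""
        x1, y1, x2, y2 = self.to_corners()
        x1, y1 = max(0.0, x1), max(0.0, y1)
        x2, y2 = min(1.0, x2), min(1.0, y2)
        if not (x2 > x1 and y2 > y1):
            raise FormatError("box entirely outside the unit square after clipping")
        return Box.from_corners(self.cls, x1, y1, x2, y2, self.conf)

    def to_pixels(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Corner form scaled to pixel units for a ``width x height`` image."""
        x1, y1, x2, y2 = self.to_corners()
        return x1 * width, y1 * height, x2 * width, y2 * height

    def validate(self, n_classes: Optional[int] = None) -> None:
        if self.cls < 0:
            raise FormatError(f"negative class id {self.cls}")
        if n_classes is not None and self.cls >= n_classes:
            raise FormatError(f"class id {self.cls} >= n_classes {n_classes}")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise FormatError(f"center ({self.cx}, {self.cy}) outside [0,1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise FormatError(f"size ({self.w}, {self.h}) outside (0,1]")
        if self.conf is not None and not (0.0 <= self.conf <= 1.0):
            raise FormatError(f"confidence {self.conf} outside [0,1]")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file into an H x W x 3 uint8 RGB array.

    Four-channel (RGBA) inputs drop the alpha channel with a logged warning;
    single-channel (grayscale) inputs raise :class:`FormatError` because the
    enhancement pipeline is defined on color imagery.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # undecodable bytes
        raise FormatError(f"cannot decode image {path}: {exc}") from exc
    if img.mode == "RGBA":
        logger.warning("dropping alpha channel of %s", path)
        img = img.convert("RGB")
    if img.mode in ("L", "I", "I;16", "1"):
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got single-channel mode {img.mode!r}")
    if img.mode != "RGB":
        img = img.convert("RGB")
    arr = np.asarray(img, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected 3 channels, got shape {arr.shape}")
    return arr


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an H x W x 3 uint8 array as PNG/JPEG (format from the suffix)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected HxWx3 array, got shape {img.shape}")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise FormatError("pixel values outside [0, 255]")
        img = img.astype(np.uint8)
    Image.fromarray(img, mode="RGB").save(Path(path))


def read_yolo_labels(path: str | Path, n_classes: Optional[int] = None) -> list[Box]:
    """Parse a YOLO-format label file into a list of :class:`Box`.

    Each non-empty line must be ``cls cx cy w h`` or ``cls cx cy w h conf``.
    Boxes partially outside the unit square are clipped (annotation tools emit
    them); malformed lines, out-of-range class ids and non-positive sizes raise
    :class:`FormatError` carrying the 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"label file not found: {path}")
    boxes: list[Box] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise FormatError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}")
        try:
            cls = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:5])
            conf = float(fields[5]) if len(fields) == 6 else None
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable value ({exc})") from exc
        if w <= 0 or h <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive box size {w} x {h}")
        if n_classes is not None and cls >= n_classes:
            raise FormatError(
                f"{path}:{lineno}: class id {cls} >= n_classes {n_classes}")
        box = Box(cls, cx, cy, w, h, conf)
        x1, y1, x2, y2 = box.to_corners()
        if x1 < 0 or y1 < 0 or x2 > 1 or y2 > 1:
            # out-of-square boxes are clipped rather than rejected
            try:
                box = box.clipped()
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        try:
            box.validate(n_classes)
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        boxes.append(box)
    return boxes


def write_yolo_labels(boxes: Sequence[Box], path: str | Path) -> None:
    """Write boxes in YOLO text format with 6 decimal places."""
    lines = []
    for b in boxes:
        line = f"{b.cls} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
        if b.conf is not None:
            line += f" {b.conf:.6f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class DatasetManifest:
    """Directory layout of a detection dataset split.

    ``images_dir`` holds PNG/JPEG files, ``labels_dir`` a same-stem ``.txt``
    YOLO label file for every image (possibly empty).  ``names`` maps class id
    to class name; ``split`` tags the subset (``train``/``val``).
    """

    images_dir: Path
    labels_dir: Path
    names: list[str]
    split: str = "train"

    image_paths: list[Path] = field(default_factory=list, repr=False)
    label_paths: list[Path] = field(default_factory=list, repr=False)

    IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")

    def __post_init__(self) -> None:
        self.images_dir = Path(self.images_dir)
        self.labels_dir = Path(self.labels_dir)
        if not self.image_paths:
            self.image_paths = sorted(
                p for p in self.images_dir.iterdir()
                if p.suffix.lower() in self.IMAGE_SUFFIXES) if self.images_dir.is_dir() else []
            self.label_paths = [self.labels_dir / (p.stem + ".txt") for p in self.image_paths]

    def validate(self) -> None:
        """Check the one-label-file-per-image invariant and class-id bounds."""
        for img, lab in zip(self.image_paths, self.label_paths):
            if not lab.exists():
                raise FormatError(f"missing label file {lab} for image {img}")
            read_yolo_labels(lab, n_classes=len(self.names))

    def labels(self) -> list[list[Box]]:
        return [read_yolo_labels(p, n_classes=len(self.names)) for p in self.label_paths]

    def save(self, path: str | Path) -> None:
        data = {
            "images_dir": str(self.images_dir),
            "labels_dir": str(self.labels_dir),
            "names": list(self.names),
            "split": self.split,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @staticmethod
    def load(path: str | Path) -> "DatasetManifest":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        for key in ("images_dir", "labels_dir", "names"):
            if key not in data:
                raise FormatError(f"manifest {path} missing key {key!r}")
        base = path.parent
        images = Path(data["images_dir"])
        labels = Path(data["labels_dir"])
        if not images.is_absolute():
            images = base / images
        if not labels.is_absolute():
            labels = base / labels
        return DatasetManifest(images, labels, list(data["names"]),
                               data.get("split", "train"))
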