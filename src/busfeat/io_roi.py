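"""Image/mask loading, annotation validation, and tumor ROI extraction.

A breast-ultrasound sample is a grayscale image plus a binary tumor mask
(or a closed contour polygon, rasterized on load) and a benign/malignant
label.  The region of interest is the tight tumor bounding box expanded by
a fixed pad (default 30 pixels) on each side, clipped to the image bounds,
so that the classifier also sees the tissue immediately surrounding the
tumor.

Coordinates are row-major and 0-based; bounding boxes are inclusive.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "AnnotationError",
    "AnnotatedImage",
    "RoiPatch",
    "load_annotated_image",
    "load_mask",
    "compute_roi",
    "read_manifest",
]

LABELS = ("benign", "malignant")


class AnnotationError(ValueError):
    """Raised when an image/mask pair violates the annotation contract."""


@dataclass
class AnnotatedImage:
    """A grayscale image with its binary tumor mask and class label."""

    pixels: np.ndarray
    mask: np.ndarray
    label: str
    id: str = ""
    spacing_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.ndim != 2:
            raise AnnotationError(f"image must be 2-D grayscale, got shape {self.pixels.shape}")
        if self.pixels.shape != self.mask.shape:
            raise AnnotationError(
                f"mask shape {self.mask.shape} does not match image shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise AnnotationError("image contains non-finite intensities")
        if self.pixels.min() < 0:
            raise AnnotationError("image contains negative intensities")
        if self.label not in LABELS:
            raise AnnotationError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.mask.any():
            raise AnnotationError("empty tumor mask")
        labeled, n = ndimage.label(self.mask)
        if n > 1:
            warnings.warn(
                f"mask of {self.id or 'sample'} has {n} connected components; keeping largest",
                stacklevel=2,
            )
            sizes = ndimage.sum_labels(self.mask, labeled, index=range(1, n + 1))
            self.mask = labeled == (int(np.argmax(sizes)) + 1)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Tight tumor bounding box (rmin, rmax, cmin, cmax), inclusive."""
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        rmin, rmax = np.nonzero(rows)[0][[0, -1]]
        cmin, cmax = np.nonzero(cols)[0][[0, -1]]
        return int(rmin), int(rmax), int(cmin), int(cmax)


@dataclass
class RoiPatch:
    """Padded rectangular crop around the tumor, with its source offset."""

    pixels: np.ndarray
    mask: np.ndarray
    origin: tuple[int, int]
    pad_requested: int = 30
    source_id: str = ""
    label: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _read_gray(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A) saved grayscale: collapse identical channels
        arr = arr[..., :3].mean(axis=2)
    return arr.astype(float)


def _rasterize_polygon(csv_path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon CSV (x,y per row, 0-based) into a mask."""
    xs, ys = [], []
    with open(csv_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("x", ""):
                continue
            xs.append(float(row[0]))
            ys.append(float(row[1]))
    if len(xs) < 3:
        raise AnnotationError(f"polygon in {csv_path} has fewer than 3 vertices")
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _sk_polygon(np.asarray(ys), np.asarray(xs), shape=shape)
    mask[rr, cc] = True
    return mask


def load_mask(mask_path: str | Path, image_shape: tuple[int, int]) -> np.ndarray:
    """Load a mask image (nonzero = tumor) or polygon CSV into a boolean array."""
    mask_path = Path(mask_path)
    if mask_path.suffix.lower() == ".csv":
        return _rasterize_polygon(mask_path, image_shape)
    arr = _read_gray(mask_path)
    vals = np.unique(arr)
    if len(vals) > 2:
        raise AnnotationError(f"mask {mask_path} is not two-valued (found {len(vals)} levels)")
    return arr != vals.min() if len(vals) == 2 else np.zeros_like(arr, dtype=bool)


def load_annotated_image(
    image_path: str | Path,
    mask_path: str | Path,
    label: str,
    *,
    id: str = "",
    spacing_mm: tuple[float, float] | None = None,
) -> AnnotatedImage:
    """Load and validate an image/mask/label triple.

    The mask may be a PNG/TIFF (nonzero = tumor) or a CSV polygon (one
    ``x,y`` vertex per row, 0-based pixel coordinates, even-odd fill).
    Multi-component masks are reduced to their largest component with a
    warning; an empty mask or a shape mismatch raises
    :class:`AnnotationError`.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    if not image_path.exists():
        raise FileNotFoundError(image_path)
    if not mask_path.exists():
        raise FileNotFoundError(mask_path)
    pixels = _read_gray(image_path)
    mask = load_mask(mask_path, pixels.shape)
    if mask.shape != pixels.shape:
        raise AnnotationError(f"mask shape {mask.shape} != image shape {pixels.shape}")
    return AnnotatedImage(
        pixels=pixels, mask=mask, label=label, id=id or image_path.stem, spacing_mm=spacing_mm
    )


def compute_roi(img: AnnotatedImage, pad: int = 30) -> RoiPatch:
    """Cut the tumor bounding box expanded by ``pad`` pixels on each side.

    The expansion is clipped to the image bounds (no synthetic padding);
    the requested pad is recorded on the patch.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    rmin, rmax, cmin, cmax = img.bbox
    h, w = img.pixels.shape
    r0 = max(rmin - pad, 0)
    r1 = min(rmax + pad, h - 1)
    c0 = max(cmin - pad, 0)
    c1 = min(cmax + pad, w - 1)
    return RoiPatch(
        pixels=img.pixels[r0 : r1 + 1, c0 : c1 + 1].copy(),
        mask=img.mask[r0 : r1 + 1, c0 : c1 + 1].copy(),
        origin=(r0, c0),
        pad_requested=pad,
        source_id=img.id,
        label=img.label,
    )


@dataclass
class ManifestEntry:
    id: str
    image_path: Path
    mask_path: Path
    label: str


def read_manifest(manifest_csv: str | Path) -> list[ManifestEntry]:
    """Read a dataset manifest CSV with columns ``id,image_path,mask_path,label``.

    Relative paths are resolved against the manifest's directory.
    """
    manifest_csv = Path(manifest_csv)
    base = manifest_csv.parent
    entries: list[ManifestEntry] = []
    with open(manifest_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                ManifestEntry(
                    id=row["id"],
                    image_path=base / row["image_path"],
                    mask_path=base / row["mask_path"],
                    label=row["label"].strip().lower(),
                )
            )
    if not entries:
        raise AnnotationError(f"manifest {manifest_csv} is empty")
    return entries


def load_dataset(manifest_csv: str | Path) -> list[AnnotatedImage]:
    """Load every sample referenced by a manifest CSV."""
    return [
        load_annotated_image(e.image_path, e.mask_path, e.label, id=e.id)
        for e in read_manifest(manifest_csv)
    ]
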