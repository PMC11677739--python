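"""Image, annotation, mask and feature-table I/O.

Coordinate conventions used throughout the package are defined here:
0-based, row-major pixel coordinates; bounding boxes are half-open
``[row0, row0+height) x [col0, col0+width)``. Boxes that overflow the image
are clipped with a logged warning (point-ROI exports commonly overflow by a
pixel). BI-RADS grades are stored internally as integers 2..5.
"""

from __future__ import annotations

import json
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: BI-RADS grades handled by the package (BR-1 has no mass, BR-6 is biopsy-proven).
VALID_GRADES = (2, 3, 4, 5)

#: Stable column order of the descriptor table.
FEATURE_COLUMNS = [
    "id",
    "np",
    "nb",
    "is",
    "n_lobes",
    "p_mean",
    "p_var",
    "p_std",
    "p_kurt",
    "p_skew",
    "mr",
    "rr",
    "mor",
    "circ",
    "cm",
    "cs",
    "dms_gray",
    "dms_dm",
    "grade",
]


class FormatError(ValueError):
    """Raised when a file cannot be read as the expected format."""


class AnnotationError(ValueError):
    """Raised when an annotation file fails validation."""


@dataclass
class GrayImage:
    """A 2-D grayscale image with an explicit maximum gray level ``L``."""

    pixels: np.ndarray
    L: int
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D pixel array")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError("GrayImage must be at least 8x8 pixels")
        if self.pixels.min() < 0 or self.pixels.max() > self.L:
            raise ValueError("pixel values must lie in [0, L]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, suffix: str = "") -> "GrayImage":
        new_id = f"{self.id}{suffix}" if suffix else self.id
        return GrayImage(pixels=pixels, L=self.L, id=new_id)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box: rows [row0, row0+height), cols [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("box extents must be positive")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    @property
    def area(self) -> int:
        return self.height * self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def clip(self, shape: tuple[int, int]) -> "BoundingBox":
        """Clip to an image extent, warning if anything was cut off."""
        r0 = max(self.row0, 0)
        c0 = max(self.col0, 0)
        r1 = min(self.row1, shape[0])
        c1 = min(self.col1, shape[1])
        if r1 - r0 < 1 or c1 - c0 < 1:
            raise ValueError(f"box {self} lies outside image of shape {shape}")
        clipped = BoundingBox(r0, c0, r1 - r0, c1 - c0)
        if clipped != self:
            logger.warning("bounding box %s clipped to image shape %s", self, shape)
        return clipped

    def expand(self, frac: float, shape: Optional[tuple[int, int]] = None) -> "BoundingBox":
        """Expand by ``frac`` of height/width on each side (clipped to ``shape``)."""
        dr = int(round(frac * self.height))
        dc = int(round(frac * self.width))
        box = BoundingBox(self.row0 - dr, self.col0 - dc, self.height + 2 * dr, self.width + 2 * dc)
        if shape is not None:
            box = box.clip(shape)
        return box

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union under half-open semantics."""
        ir = max(0, min(self.row1, other.row1) - max(self.row0, other.row0))
        ic = max(0, min(self.col1, other.col1) - max(self.col0, other.col0))
        inter = ir * ic
        union = self.area + other.area - inter
        return inter / union if union else 0.0


@dataclass
class SampleRecord:
    """One annotated mass: image reference, box, grade, optional mask/density type."""

    image: str
    box: BoundingBox
    grade: int
    mask: Optional[str] = None
    acr: Optional[str] = None

    def __post_init__(self) -> None:
        if self.grade not in VALID_GRADES:
            raise AnnotationError(f"grade must be one of {VALID_GRADES}, got {self.grade!r}")


def _grade_to_int(value) -> int:
    if isinstance(value, str):
        m = re.fullmatch(r"(?:BR-?)?([2-5])", value.strip(), flags=re.IGNORECASE)
        if not m:
            raise AnnotationError(f"unknown grade string {value!r} (expected BR-2..BR-5)")
        return int(m.group(1))
    g = int(value)
    if g not in VALID_GRADES:
        raise AnnotationError(f"grade {value!r} outside BR-2..BR-5")
    return g


def _max_level_for_dtype(dtype: np.dtype) -> int:
    dtype = np.dtype(dtype)
    if dtype.kind == "u" or dtype.kind == "i":
        return int(np.iinfo(dtype).max)
    raise FormatError(f"cannot infer gray-level range for dtype {dtype}")


def read_image(path) -> GrayImage:
    """Read a grayscale PNG/TIFF/DICOM image.

    ``L`` is inferred from the stored bit depth (255 for 8-bit, 65535 for
    16-bit, ``2**BitsStored - 1`` for DICOM). RGB inputs are converted with
    Rec.601 luminance weights.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        import pydicom

        try:
            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array
        except Exception as exc:  # pragma: no cover - exercised via FormatError test
            raise FormatError(f"cannot read DICOM {path}: {exc}") from exc
        bits = int(getattr(ds, "BitsStored", 8 * arr.dtype.itemsize))
        L = 2**bits - 1
    else:
        try:
            if suffix in {".tif", ".tiff"}:
                arr = tifffile.imread(str(path))
            else:
                arr = iio.imread(str(path))
        except Exception as exc:
            raise FormatError(f"cannot read image {path}: {exc}") from exc
        if arr.ndim == 3:
            arr = np.round(
                0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
            ).astype(arr.dtype)
        L = _max_level_for_dtype(arr.dtype)
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-frame grayscale image")
    return GrayImage(pixels=arr, L=L, id=path.stem)


def write_image(img: GrayImage, path) -> None:
    """Write a GrayImage as PNG/TIFF at its native bit depth."""
    path = Path(path)
    dtype = np.uint8 if img.L <= 255 else np.uint16
    arr = np.asarray(img.pixels).astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(str(path), arr)


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG (foreground = nonzero)."""
    arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


_ANNOT_FIELDS = ["image", "row0", "col0", "height", "width", "grade", "mask", "acr"]


def _record_from_row(row: dict, where: str) -> SampleRecord:
    try:
        box = BoundingBox(int(row["row0"]), int(row["col0"]), int(row["height"]), int(row["width"]))
        mask = row.get("mask")
        acr = row.get("acr")
        return SampleRecord(
            image=str(row["image"]),
            box=box,
            grade=_grade_to_int(row["grade"]),
            mask=None if mask in (None, "", float("nan")) or (isinstance(mask, float) and np.isnan(mask)) else str(mask),
            acr=None if acr in (None, "") or (isinstance(acr, float) and np.isnan(acr)) else str(acr),
        )
    except AnnotationError as exc:
        raise AnnotationError(f"{where}: {exc}") from exc


def read_annotations(path) -> list[SampleRecord]:
    """Read sample annotations from CSV (header required) or JSON.

    Columns/keys: ``image,row0,col0,height,width,grade[,mask,acr]``. Grades
    are validated against BR-2..BR-5; offending rows are reported.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text() or "[]")
    else:
        if path.stat().st_size == 0:
            logger.warning("annotation file %s is empty", path)
            return []
        df = pd.read_csv(path)
        if df.empty:
            logger.warning("annotation file %s has no rows", path)
            return []
        rows = df.to_dict("records")
    if not rows:
        logger.warning("annotation file %s is empty", path)
    return [_record_from_row(row, f"{path} row {i}") for i, row in enumerate(rows)]


def write_annotations(records: Sequence[SampleRecord], path) -> None:
    """Write annotations as CSV (or JSON for a .json path); round-trips losslessly."""
    path = Path(path)
    rows = [
        {
            "image": r.image,
            "row0": r.box.row0,
            "col0": r.box.col0,
            "height": r.box.height,
            "width": r.box.width,
            "grade": f"BR-{r.grade}",
            "mask": "" if r.mask is None else r.mask,
            "acr": "" if r.acr is None else r.acr,
        }
        for r in records
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=_ANNOT_FIELDS).to_csv(path, index=False)


def read_pointroi_xml(path, image_shape: Optional[tuple[int, int]] = None):
    """Read a point-ROI XML polygon (plist-style dict with ``Point_px`` entries).

    Returns ``(BoundingBox, mask-or-None)``; the mask (requires
    ``image_shape``) is the filled polygon. Points are stored as
    ``"(x, y)"`` strings, i.e. (col, row).
    """
    from skimage.draw import polygon as _polygon

    tree = ET.parse(str(path))
    pts = []
    for s in tree.iter("string"):
        m = re.fullmatch(r"\(\s*([-\d.]+)\s*,\s*([-\d.]+)\s*\)", (s.text or "").strip())
        if m:
            pts.append((float(m.group(2)), float(m.group(1))))  # (row, col)
    if len(pts) < 3:
        raise AnnotationError(f"{path}: fewer than 3 ROI points found")
    rows = np.array([p[0] for p in pts])
    cols = np.array([p[1] for p in pts])
    r0, c0 = int(np.floor(rows.min())), int(np.floor(cols.min()))
    # half-open extent: the pixel under the maximum coordinate is covered
    r1, c1 = int(np.floor(rows.max())) + 1, int(np.floor(cols.max())) + 1
    box = BoundingBox(r0, c0, max(r1 - r0, 1), max(c1 - c0, 1))
    mask = None
    if image_shape is not None:
        mask = np.zeros(image_shape, bool)
        rr, cc = _polygon(rows, cols, shape=image_shape)
        mask[rr, cc] = True
        box = box.clip(image_shape)
    return box, mask


def write_feature_table(records: Sequence[dict], path) -> None:
    """Write descriptor vectors to CSV with the stable column order."""
    df = pd.DataFrame(list(records))
    extra = [c for c in df.columns if c not in FEATURE_COLUMNS]
    cols = [c for c in FEATURE_COLUMNS if c in df.columns] + extra
    df[cols].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a descriptor table written by :func:`write_feature_table`."""
    return pd.read_csv(path, dtype={"id": str})
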