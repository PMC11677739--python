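"""Mass segmentation inside a bounding-box patch, plus overlap metrics.

A mass is dense tissue, hence the bright majority structure inside its own
bounding box; its gray levels occupy the upper part of the patch histogram.
Pixels above ``median - offset * std`` of the patch are kept, small artifacts
are removed with a binary opening, and only the largest 8-connected
component survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.morphology import disk, opening

from .io import BoundingBox, GrayImage


@dataclass(frozen=True)
class SegmentParams:
    """Thresholding/cleanup parameters for mass segmentation."""

    offset: float = 1.0        # standard deviations below the median
    opening_radius: int = 3    # cleanup binary opening SE radius
    min_area: int = 16

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be positive")
        if self.opening_radius < 1:
            raise ValueError("opening radius must be >= 1")


class SegmentationError(RuntimeError):
    """Raised when no mass survives filtering; carries the threshold used."""

    def __init__(self, message: str, threshold: float | None = None):
        super().__init__(message)
        self.threshold = threshold


def segment_mass(patch, params: SegmentParams = SegmentParams()) -> tuple[np.ndarray, float]:
    """Segment the mass in a bounding-box crop.

    Returns ``(mask, threshold)``. The mask is strictly a subset of
    ``patch > threshold`` (the opening only removes pixels) and contains
    exactly one 8-connected component. Raises :class:`SegmentationError` on
    degenerate input (fewer than two gray levels) or an empty result.
    """
    pix = patch.pixels if isinstance(patch, GrayImage) else np.asarray(patch)
    pix = pix.astype(float)
    if np.unique(pix).size < 2:
        raise SegmentationError("patch has fewer than 2 distinct gray levels")
    threshold = float(np.median(pix) - params.offset * pix.std())
    fg = pix > threshold
    fg = opening(fg, disk(params.opening_radius))
    lab = label(fg, connectivity=2)
    if lab.max() == 0:
        raise SegmentationError("no foreground after threshold/opening", threshold)
    areas = np.bincount(lab.ravel())[1:]
    # ties broken by earliest raster-scan label (argmax returns the first max)
    mask = lab == (int(np.argmax(areas)) + 1)
    if mask.sum() < params.min_area:
        raise SegmentationError("largest component below minimum area", threshold)
    if mask.sum() >= 0.98 * mask.size:
        # the threshold failed to separate anything: a mass never fills its box
        raise SegmentationError("mask covers the whole patch", threshold)
    return mask, threshold


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Bounding-box intersection-over-union under half-open semantics."""
    return box_a.iou(box_b)
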