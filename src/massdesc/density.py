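"""Density description: GLCM-homogeneity density map, tissue clustering, dms.

The density map ``DM(x, y) = I(x, y) * H(x, y)`` multiplies each intensity by
the local gray-level co-occurrence homogeneity
``H = sum_ij p(i, j) / (1 + (i - j)^2)`` of the window centered there, so
smooth dense tissue keeps its brightness while noisy regions are attenuated.
The map (or the raw gray levels) is split into four tissue classes with
fuzzy C-means — fatty (1), low (2), medium (3), high density (4) — and the
mass is labeled low / equal / high density (``dms`` = 1 / 2 / 3) by comparing
the predominant class inside the mass against the predominant class of the
surrounding ring (the annotation box expanded by 20% of its dimensions,
minus the mass).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import BoundingBox, GrayImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensityParams:
    """Homogeneity-map and clustering parameters."""

    window: int = 11       # odd homogeneity window
    distance: int = 1      # co-occurrence offset
    n_levels: int = 32     # quantization bins
    expansion: float = 0.20
    equal_tol: float = 0.10
    cluster_method: str = "fcm"  # or "kmeans"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.n_levels < 2:
            raise ValueError("need at least 2 quantization levels")


@dataclass(frozen=True)
class DensityRelation:
    """Predominant classes inside/outside the mass and the dms label."""

    cm: int
    cs: int
    occurrence_in: np.ndarray
    occurrence_out: np.ndarray
    dms: int            # 1=low, 2=equal, 3=high
    dms_max: int        # auxiliary max(cm, cs)


def _box_sum(arr: np.ndarray, window: int) -> np.ndarray:
    """Sum of ``arr`` over a centered window clipped at the borders."""
    h = window // 2
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    ii[1:, 1:] = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    r = np.arange(arr.shape[0])
    c = np.arange(arr.shape[1])
    r0 = np.clip(r - h, 0, arr.shape[0])
    r1 = np.clip(r + h + 1, 0, arr.shape[0])
    c0 = np.clip(c - h, 0, arr.shape[1])
    c1 = np.clip(c + h + 1, 0, arr.shape[1])
    return (
        ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]
    )


def quantize(pix: np.ndarray, n_levels: int, value_range=None) -> np.ndarray:
    """Equal-width quantization into levels 0..n_levels-1 over ``value_range``
    (the patch's own range by default; a constant patch maps to level 0)."""
    pix = np.asarray(pix, float)
    lo, hi = (pix.min(), pix.max()) if value_range is None else value_range
    if hi <= lo:
        return np.zeros(pix.shape, dtype=np.int32)
    q = np.floor((pix - lo) / (hi - lo) * n_levels).astype(np.int32)
    return np.clip(q, 0, n_levels - 1)


def homogeneity_map(
    patch,
    window: int = 11,
    distance: int = 1,
    n_levels: int = 32,
    value_range=None,
    directions: str = "axial",
) -> np.ndarray:
    """Per-pixel GLCM homogeneity in (0, 1].

    For every pixel, the co-occurrence pairs of the quantized window at the
    given offset distance are accumulated over the symmetric directions,
    normalized to probabilities, and weighted by ``1 / (1 + (i - j)^2)``.
    The default pairs each pixel with its neighbors at Euclidean offset
    ``distance`` along the two axes ("axial": 0 and 90 degrees);
    ``directions="all"`` adds the two diagonals. A pair belongs to the
    window of its origin pixel; windows are clipped at the patch borders.
    """
    pix = patch.pixels if isinstance(patch, GrayImage) else np.asarray(patch)
    pix = pix.astype(float)
    if window > min(pix.shape):
        raise ValueError("window larger than patch")
    q = quantize(pix, n_levels, value_range)
    d = int(distance)
    if directions == "axial":
        offsets = [(0, d), (d, 0)]
    elif directions == "all":
        offsets = [(0, d), (d, 0), (d, d), (d, -d)]
    else:
        raise ValueError("directions must be 'axial' or 'all'")
    weight_sum = np.zeros(pix.shape, np.float64)
    count_sum = np.zeros(pix.shape, np.float64)
    for dr, dc in offsets:
        w = np.zeros(pix.shape, np.float64)
        cnt = np.zeros(pix.shape, np.float64)
        r_sl = slice(0, pix.shape[0] - dr) if dr >= 0 else slice(-dr, pix.shape[0])
        c_sl = slice(0, pix.shape[1] - dc) if dc >= 0 else slice(-dc, pix.shape[1])
        r_sh = slice(dr, pix.shape[0]) if dr >= 0 else slice(0, pix.shape[0] + dr)
        c_sh = slice(dc, pix.shape[1]) if dc >= 0 else slice(0, pix.shape[1] + dc)
        diff = q[r_sl, c_sl].astype(float) - q[r_sh, c_sh]
        w[r_sl, c_sl] = 1.0 / (1.0 + diff**2)
        cnt[r_sl, c_sl] = 1.0
        weight_sum += _box_sum(w, window)
        count_sum += _box_sum(cnt, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(count_sum > 0, weight_sum / np.maximum(count_sum, 1e-12), 1.0)
    return np.clip(H, 0.0, 1.0)


def density_map(patch, params: DensityParams = DensityParams(), value_range=None) -> np.ndarray:
    """DM = I * H; bounded above by the intensity, equal to it on constant patches."""
    pix = patch.pixels if isinstance(patch, GrayImage) else np.asarray(patch)
    H = homogeneity_map(pix, params.window, params.distance, params.n_levels, value_range)
    return pix.astype(float) * H


def _fcm_1d(
    x: np.ndarray,
    weights: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted fuzzy C-means on scalar values; returns (centers, memberships)."""
    lo, hi = x.min(), x.max()
    centers = lo + (hi - lo) * (2 * np.arange(c) + 1) / (2 * c)  # deterministic quantile-like init
    exponent = 2.0 / (m - 1.0)
    u = np.empty((x.size, c))
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        d = np.maximum(d, 1e-12)
        u = d ** (-exponent)
        u /= u.sum(axis=1, keepdims=True)
        w = (u**m) * weights[:, None]
        new_centers = (w * x[:, None]).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-300)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return centers, u


def cluster_density(
    values: np.ndarray,
    c: int = 4,
    seed: int = 0,
    method: str = "fcm",
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> np.ndarray:
    """Cluster scalar values into ``c`` tissue classes, numbered 1..c by ascending center.

    Default is fuzzy C-means (fuzzifier ``m``) with hard labels by maximum
    membership and a deterministic quantile initialization; ``method="kmeans"``
    switches to hard k-means (seeded). Inputs with fewer than ``c`` distinct
    values are assigned classes by value ordering with a warning.
    """
    arr = np.asarray(values, float)
    flat = arr.ravel()
    uniq, inv, counts = np.unique(flat, return_inverse=True, return_counts=True)
    if uniq.size < c:
        warnings.warn(
            f"only {uniq.size} distinct values for {c} classes; assigning by value order",
            stacklevel=2,
        )
        labels_u = np.arange(1, uniq.size + 1)
        return labels_u[inv].reshape(arr.shape)
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=c, random_state=int(seed) % (2**31), n_init=4)
        lab_u = km.fit_predict(uniq.reshape(-1, 1), sample_weight=counts)
        centers = km.cluster_centers_.ravel()
    elif method == "fcm":
        centers, u = _fcm_1d(uniq, counts.astype(float), c, m=m, tol=tol, max_iter=max_iter)
        lab_u = np.argmax(u, axis=1)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    order = np.argsort(centers, kind="stable")
    rank = np.empty(c, int)
    rank[order] = np.arange(1, c + 1)  # 1 = darkest/fattiest ... c = densest
    return rank[lab_u][inv].reshape(arr.shape)


def surrounding_ring(
    box: BoundingBox,
    image_shape: tuple[int, int],
    mask: np.ndarray,
    expansion: float = 0.20,
) -> tuple[np.ndarray, BoundingBox]:
    """Ring = (box expanded by ``expansion`` of its dimensions, clipped) minus the mask."""
    expanded = box.expand(expansion, image_shape)
    ring = np.zeros(image_shape, bool)
    ring[expanded.slices()] = True
    ring &= ~np.asarray(mask, bool)
    return ring, expanded


def density_relation(
    class_img: np.ndarray,
    mask: np.ndarray,
    ring: np.ndarray,
    n_classes: int = 4,
    equal_tol: float = 0.10,
) -> DensityRelation:
    """Compare predominant density classes inside the mass vs. its surround.

    ``dms`` is 2 (equal) when the predominant classes coincide or the two
    class-occurrence distributions differ by at most ``equal_tol`` per class
    on average (L1 distance <= 2 * equal_tol); otherwise 3 (high) when
    ``cm > cs`` and 1 (low) when ``cm < cs``. Ties in the predominant class
    go to the higher class.
    """
    class_img = np.asarray(class_img)
    mask = np.asarray(mask, bool)
    ring = np.asarray(ring, bool)
    if not mask.any() or not ring.any():
        raise ValueError("mask and ring must both be nonempty")

    def occurrence(region: np.ndarray) -> np.ndarray:
        occ = np.bincount(class_img[region].ravel(), minlength=n_classes + 1)[1:].astype(float)
        return occ / occ.sum()

    occ_in = occurrence(mask)
    occ_out = occurrence(ring)
    cm = n_classes - int(np.argmax(occ_in[::-1]))
    cs = n_classes - int(np.argmax(occ_out[::-1]))
    if cm == cs or np.abs(occ_in - occ_out).sum() <= 2 * equal_tol:
        dms = 2
    else:
        dms = 3 if cm > cs else 1
    return DensityRelation(
        cm=cm,
        cs=cs,
        occurrence_in=occ_in,
        occurrence_out=occ_out,
        dms=dms,
        dms_max=max(cm, cs),
    )


def describe_density(
    image,
    mask: np.ndarray,
    box: BoundingBox,
    params: DensityParams = DensityParams(),
    seed: int = 0,
) -> dict:
    """Density features of one mass: dms from gray levels (D1) and from DM (D2).

    Clustering is fit on the pixels of the 20%-expanded region only, so each
    mass is described in its own local context.
    """
    pix = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    ring, expanded = surrounding_ring(box, pix.shape, mask, params.expansion)
    sl = expanded.slices()
    crop = pix[sl].astype(float)
    mask_c = np.asarray(mask, bool)[sl]
    ring_c = ring[sl]

    gray_classes = cluster_density(crop, seed=seed, method=params.cluster_method)
    rel_gray = density_relation(gray_classes, mask_c, ring_c, equal_tol=params.equal_tol)

    dm = density_map(crop, params)
    dm_classes = cluster_density(dm, seed=seed, method=params.cluster_method)
    rel_dm = density_relation(dm_classes, mask_c, ring_c, equal_tol=params.equal_tol)

    return {
        "cm": rel_dm.cm,
        "cs": rel_dm.cs,
        "dms_gray": rel_gray.dms,
        "dms_dm": rel_dm.dms,
        "relation_gray": rel_gray,
        "relation_dm": rel_dm,
    }
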