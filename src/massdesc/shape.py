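"""Skeleton-based shape description of a mass mask.

The shape of a mass is summarized by its thinning skeleton: the number of
endpoints ``Np`` and bifurcations ``Nb`` give the shape-irregularity index
``IS = Np + Nb``; the number of lobes is ``max(Np - 2, 0)`` (a smooth
elongated mass has a two-endpoint line skeleton and zero lobes); and the
Euclidean distances from the skeleton center to the endpoints form the set
``p`` whose moments (mean, variance, std, kurtosis, skewness) quantify how
evenly the lobes spread around the mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import convolve, distance_transform_edt
from skimage.measure import label
from skimage.morphology import skeletonize as _sk_skeletonize

_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass
class SkeletonSummary:
    """Skeleton pixels, endpoints/bifurcations, medial center and endpoint distances."""

    skeleton: np.ndarray
    center: tuple[int, int]
    endpoints: list[tuple[int, int]]
    n_endpoints: int
    n_bifurcations: int
    distances: np.ndarray


@dataclass(frozen=True)
class ShapeFeatures:
    """IS, lobe count and sample moments of the endpoint-distance set."""

    is_: int
    n_lobes: int
    p_mean: float
    p_var: float
    p_std: float
    p_kurt: float
    p_skew: float
    n_endpoints: int
    n_bifurcations: int
    degenerate: bool = False


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning of a single-component mask (8-connected, 1 px wide)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    return _sk_skeletonize(mask)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return convolve(skel.astype(np.uint8), _NEIGH_KERNEL, mode="constant")


def _trace_branch(skel: np.ndarray, start: tuple[int, int], counts: np.ndarray):
    """Walk from an endpoint until a junction (>=3 neighbors) or a dead end.

    Returns ``(path, hit_junction)``; the path excludes the junction pixel.
    """
    path = [start]
    prev = None
    cur = start
    while True:
        r, c = cur
        nbrs = [
            (rr, cc)
            for rr in range(max(r - 1, 0), min(r + 2, skel.shape[0]))
            for cc in range(max(c - 1, 0), min(c + 2, skel.shape[1]))
            if (rr, cc) != (r, c) and skel[rr, cc] and (rr, cc) != prev
        ]
        if not nbrs:
            return path, False  # isolated segment: ends at another endpoint
        if len(nbrs) > 1:
            return path, True  # shouldn't happen mid-branch; treat as junction
        nxt = nbrs[0]
        if counts[nxt] >= 3:
            return path, True
        prev, cur = cur, nxt
        path.append(cur)
        if counts[cur] == 1 and len(path) > 1:
            return path, False


def prune_spurs(skel: np.ndarray, min_length: float) -> np.ndarray:
    """Iteratively remove endpoint branches shorter than ``min_length`` pixels.

    Only branches terminating at a junction are removed, so a bare line
    skeleton is never pruned away.
    """
    skel = np.asarray(skel, bool).copy()
    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(skel)
        endpoints = list(zip(*np.nonzero(skel & (counts == 1))))
        for ep in endpoints:
            if not skel[ep]:
                continue
            path, hit_junction = _trace_branch(skel, ep, counts)
            if hit_junction and len(path) < min_length:
                for p in path:
                    skel[p] = False
                changed = True
        if changed and not skel.any():  # safety: never return an empty skeleton
            raise RuntimeError("pruning removed the whole skeleton")
    return skel


def analyze_skeleton(
    skel: np.ndarray,
    mask: np.ndarray,
    prune_frac: float = 0.02,
) -> SkeletonSummary:
    """Endpoints, bifurcation clusters, medial center and endpoint distances.

    Branches shorter than ``prune_frac`` times the mask bounding-box diagonal
    are pruned first (raw thinning sprouts short spurs from boundary
    rasterization noise). An endpoint is a skeleton pixel with at most one
    8-neighbor on the skeleton; a bifurcation is a maximal 8-connected
    cluster of pixels each having >= 3 skeleton neighbors, counted once per
    cluster. The center is the skeleton pixel maximizing the distance
    transform of the mask (ties: smallest row, then column).
    """
    skel = np.asarray(skel, bool)
    mask = np.asarray(mask, bool)
    if not skel.any():
        raise ValueError("empty skeleton")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    diag = float(np.hypot(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))
    if prune_frac > 0:
        skel = prune_spurs(skel, prune_frac * diag)

    counts = _neighbor_counts(skel)
    endpoints = [tuple(p) for p in np.argwhere(skel & (counts <= 1))]
    branch_px = skel & (counts >= 3)
    nb = int(label(branch_px, connectivity=2).max())

    dt = distance_transform_edt(mask)
    dt_on_skel = np.where(skel, dt, -np.inf)
    best = dt_on_skel.max()
    cand = np.argwhere(dt_on_skel == best)
    center = tuple(cand[np.lexsort((cand[:, 1], cand[:, 0]))[0]])

    dists = np.array([np.hypot(r - center[0], c - center[1]) for r, c in endpoints])
    return SkeletonSummary(
        skeleton=skel,
        center=(int(center[0]), int(center[1])),
        endpoints=[(int(r), int(c)) for r, c in endpoints],
        n_endpoints=len(endpoints),
        n_bifurcations=nb,
        distances=dists,
    )


def shape_features(summary: SkeletonSummary) -> ShapeFeatures:
    """IS = Np + Nb, lobe count, and sample moments of the distance set.

    Moment conventions: variance with n-1 denominator; skewness is the
    adjusted Fisher-Pearson sample skewness; kurtosis is the bias-corrected
    Pearson (non-excess) kurtosis. With fewer than two distances the moments
    are reported as 0 and the result is flagged degenerate.
    """
    p = summary.distances
    np_, nb = summary.n_endpoints, summary.n_bifurcations
    degenerate = p.size < 2
    if degenerate:
        mean = var = std = kurt = skew = 0.0
    else:
        mean = float(p.mean())
        var = float(p.var(ddof=1))
        std = float(np.sqrt(var))
        skew = float(stats.skew(p, bias=False)) if p.size >= 3 else 0.0
        kurt = float(stats.kurtosis(p, fisher=False, bias=False)) if p.size >= 4 else 0.0
        if not np.isfinite(skew):
            skew = 0.0
        if not np.isfinite(kurt):
            kurt = 0.0
    return ShapeFeatures(
        is_=np_ + nb,
        n_lobes=max(np_ - 2, 0),
        p_mean=mean,
        p_var=var,
        p_std=std,
        p_kurt=kurt,
        p_skew=skew,
        n_endpoints=np_,
        n_bifurcations=nb,
        degenerate=degenerate,
    )


def describe_shape(mask: np.ndarray, prune_frac: float = 0.02) -> ShapeFeatures:
    """Convenience: skeletonize + analyze + featurize a mask in one call."""
    return shape_features(analyze_skeleton(skeletonize(mask), mask, prune_frac))
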