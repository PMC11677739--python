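"""End-to-end orchestration: segment -> describe -> select -> classify.

A single :class:`RunConfig` drives every stage; one global seed fans out to
per-stage seeds through a fixed derivation so stage-level reruns are
independently reproducible. Stage failures on a single mass are isolated:
the mass is flagged in the QC output and the rest of the run proceeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as mio
from .augment import AugmentParams, augment_set
from .classify import MLPConfig, cross_validate
from .density import DensityParams, describe_density
from .features import FEATURE_SETS, build_feature_set, correlation_profile
from .margin import describe_margin
from .segment import SegmentParams, SegmentationError, dice, segment_mass
from .shape import describe_shape

logger = logging.getLogger(__name__)


class ShapeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prune_frac: float = 0.02


class SegmentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    offset: float = 1.0
    opening_radius: int = 3
    min_area: int = 16


class AugmentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    rho_threshold: float = 70.0
    gamma_low: float = 0.5
    gamma_high: float = 0.3
    opening_radius: int = 5


class DensityBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window: int = 11
    distance: int = 1
    n_levels: int = 32
    expansion: float = 0.20
    equal_tol: float = 0.10
    cluster_method: str = "fcm"


class ClassifyBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden_layers: tuple[int, ...] = (10, 10)
    learning_rate: float = 0.001
    epochs: int = 500
    folds: int = 10


class RunConfig(BaseModel):
    """Serializable configuration of a full pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    annotations: str
    image_root: str = "."
    out_dir: str = "run"
    feature_set: str = "FINAL"
    mode: str = "grade"  # or "binary"
    seed: int = 0
    augment: AugmentBlock = AugmentBlock()
    segment: SegmentBlock = SegmentBlock()
    shape: ShapeParams = ShapeParams()
    density: DensityBlock = DensityBlock()
    classify: ClassifyBlock = ClassifyBlock()


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed per-stage seed derivation from the global seed."""
    offsets = {"phantoms": 1, "augment": 2, "segment": 3, "density": 4, "classify": 5}
    return (int(global_seed) * 1000003 + offsets.get(stage, 99)) % (2**31)


def describe_mass(
    image: mio.GrayImage,
    box: mio.BoundingBox,
    segment_params: SegmentParams = SegmentParams(),
    density_params: DensityParams = DensityParams(),
    prune_frac: float = 0.02,
    seed: int = 0,
    truth_mask: Optional[np.ndarray] = None,
) -> dict:
    """Segment one mass and assemble its full descriptor vector.

    Returns a dict with the stable feature-table schema; also carries the
    segmentation mask ("mask", image-aligned) and, when a truth mask is
    given, the Dice overlap ("dice_truth").
    """
    box = box.clip(image.shape)
    crop = np.asarray(image.pixels)[box.slices()]
    mask_crop, threshold = segment_mass(crop, segment_params)
    mask = np.zeros(image.shape, bool)
    mask[box.slices()] = mask_crop

    sf = describe_shape(mask_crop, prune_frac=prune_frac)
    mf = describe_margin(mask_crop)
    df = describe_density(image, mask, box, density_params, seed=seed)

    out = {
        "id": image.id,
        "np": sf.n_endpoints,
        "nb": sf.n_bifurcations,
        "is": sf.is_,
        "n_lobes": sf.n_lobes,
        "p_mean": sf.p_mean,
        "p_var": sf.p_var,
        "p_std": sf.p_std,
        "p_kurt": sf.p_kurt,
        "p_skew": sf.p_skew,
        "mr": mf.mr,
        "rr": mf.rr,
        "mor": mf.mor,
        "circ": mf.circ,
        "cm": df["cm"],
        "cs": df["cs"],
        "dms_gray": df["dms_gray"],
        "dms_dm": df["dms_dm"],
        "mask": mask,
        "threshold": threshold,
    }
    if truth_mask is not None:
        out["dice_truth"] = dice(mask, truth_mask)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Outputs: per-mass mask PNGs, ``features.csv``, ``correlations.csv``,
    ``cv_report.json``, ``qc.csv`` and a ``manifest.json`` recording every
    parameter and derived seed.
    """
    out = Path(config.out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    root = Path(config.image_root)
    records = mio.read_annotations(config.annotations)
    if not records:
        raise ValueError("no annotation records found")

    seg_params = SegmentParams(**config.segment.model_dump())
    den_params = DensityParams(**config.density.model_dump())
    den_seed = stage_seed(config.seed, "density")

    rows, qc = [], []
    failures = 0
    for rec in records:
        img = mio.read_image(root / rec.image)
        if config.augment.enabled:
            params = AugmentParams(
                rho_threshold=config.augment.rho_threshold,
                gamma_low=config.augment.gamma_low,
                gamma_high=config.augment.gamma_high,
                opening_radius=config.augment.opening_radius,
            )
            variants = augment_set([img], params)
        else:
            variants = [img]
        truth = mio.read_mask(root / rec.mask) if rec.mask else None
        for var in variants:
            try:
                vec = describe_mass(
                    var,
                    rec.box,
                    segment_params=seg_params,
                    density_params=den_params,
                    prune_frac=config.shape.prune_frac,
                    seed=den_seed,
                    truth_mask=truth,
                )
            except (SegmentationError, ValueError) as exc:
                failures += 1
                logger.warning("mass %s failed: %s", var.id, exc)
                qc.append({"id": var.id, "status": "failed", "error": str(exc)})
                continue
            mask = vec.pop("mask")
            mio.write_mask(mask, out / "masks" / f"{var.id}.png")
            qc.append(
                {
                    "id": var.id,
                    "status": "ok",
                    "threshold": vec.pop("threshold"),
                    "area": int(mask.sum()),
                    "dice": vec.pop("dice_truth", np.nan),
                }
            )
            vec["grade"] = rec.grade
            rows.append(vec)

    pd.DataFrame(qc).to_csv(out / "qc.csv", index=False)
    if not rows:
        raise RuntimeError("every mass failed; see qc.csv")
    mio.write_feature_table(rows, out / "features.csv")
    table = mio.read_feature_table(out / "features.csv")

    corr = correlation_profile(table)
    corr.to_csv(out / "correlations.csv", index=False)

    X, y, names = build_feature_set(
        table, "BINARY" if config.mode == "binary" else config.feature_set
    )
    mlp = MLPConfig(
        hidden_layers=tuple(config.classify.hidden_layers),
        learning_rate=config.classify.learning_rate,
        epochs=config.classify.epochs,
        seed=stage_seed(config.seed, "classify"),
    )
    report = cross_validate(X, y, mlp, k=config.classify.folds, seed=stage_seed(config.seed, "classify"))
    (out / "cv_report.json").write_text(json.dumps(report.summary(), indent=1))

    manifest = {
        "config": config.model_dump(),
        "derived_seeds": {s: stage_seed(config.seed, s) for s in ("augment", "segment", "density", "classify")},
        "n_masses": len(rows),
        "n_failures": failures,
        "feature_names": names,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
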