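"""Synthetic mammogram-patch phantoms with ground truth.

A phantom mass is a star-convex region whose boundary is a harmonic
perturbation of a circle, ``r(theta) = r0 * (1 + sum_k a_k cos(k theta + phi_k))``,
optionally decorated with narrow radial spicule triangles. The rendered patch
places the mass plateau at the intensity level of its target density class,
rings it with a thin dark fatty moat (the halo sign of circumscribed
masses), and fills the rest of the scene with a smooth tissue field at the
background class level. Inside its own annotation box the mass is therefore
always the dominant bright structure — the operating assumption of the
histogram segmentation — while the 20%-expanded surround is dominated by
the background tissue class, as the density relation expects.

Every generated sample comes with its exact rasterized truth mask and
parameter-determined labels, so downstream descriptors have an oracle
without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.measure import label
from skimage.morphology import dilation, disk

from .io import BoundingBox, GrayImage, SampleRecord, write_annotations, write_image, write_mask

#: Intensity plateaus of the four tissue-density classes (fatty .. high) for L=255.
CLASS_LEVELS = (40, 100, 160, 220)

#: Width (px) of the dark fatty moat around the mass (halo sign).
MOAT_WIDTH = 4
#: Annotation box = mass-body bounding box padded by this many pixels.
ANNOT_PAD = 2
#: Texture noise inside the mass (px intensity units); surround field amplitude; field smoothing.
MASS_TEXTURE_SD = 5.0
FIELD_SD = 3.0
FIELD_SMOOTH = 6.0

MARGIN_CLASSES = ("round", "oval", "lobulated", "spiculated")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic mass patch."""

    patch_size: int = 128
    r0: float = 24.0
    harmonics: tuple[tuple[float, int, float], ...] = ()  # (amplitude, k, phase)
    n_spicules: int = 0
    spicule_len_frac: float = 0.10
    spicule_width: float = 4.0
    cm_class: int = 3  # mass density class target (1..4)
    cs_class: int = 2  # surrounding density class target (1..4)
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 < 8:
            raise ValueError("r0 must be at least 8 px")
        if sum(abs(a) for a, _, _ in self.harmonics) >= 1.0:
            raise ValueError("harmonic amplitudes must satisfy sum|a_k| < 1")
        if not (1 <= self.cm_class <= 4 and 1 <= self.cs_class <= 4):
            raise ValueError("density class targets must be in 1..4")


@dataclass
class PhantomTruth:
    """A rendered phantom with its generative ground truth."""

    image: GrayImage
    mask: np.ndarray
    box: BoundingBox
    true_lobes: int
    margin_class: str
    density_relation: int  # 1=low, 2=equal, 3=high
    grade: int
    spec: PhantomSpec


def boundary_polygon(spec: PhantomSpec, n_theta: int = 1440) -> np.ndarray:
    """Analytic mass boundary (without spicules) as an (n, 2) row/col polygon."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r = np.full_like(theta, spec.r0)
    for a, k, phi in spec.harmonics:
        r = r + spec.r0 * a * np.cos(k * theta + phi)
    if np.any(r <= 1.0):
        raise ValueError("degenerate radius: boundary collapses to the centre")
    c = spec.patch_size / 2.0
    return np.column_stack([c + r * np.sin(theta), c + r * np.cos(theta)])


def _radius_at(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    r = np.full_like(theta, spec.r0, dtype=float)
    for a, k, phi in spec.harmonics:
        r = r + spec.r0 * a * np.cos(k * theta + phi)
    return r


def make_mask(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the phantom boundary (plus spicules) into a binary mask.

    Returns ``(mask, boundary)`` where ``boundary`` is the analytic body
    polygon in row/col coordinates. The mask is guaranteed to be a single
    8-connected component.
    """
    shape = (spec.patch_size, spec.patch_size)
    poly = boundary_polygon(spec)
    mask = np.zeros(shape, bool)
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    mask[rr, cc] = True

    if spec.n_spicules > 0:
        rng = np.random.default_rng([int(spec.seed) % (2**31), 11])
        c = spec.patch_size / 2.0
        base_angles = np.linspace(0, 2 * np.pi, spec.n_spicules, endpoint=False)
        base_angles = base_angles + rng.uniform(-0.15, 0.15, spec.n_spicules)
        half_w = max(spec.spicule_width, 2.0) / 2.0
        for ang in base_angles:
            rb = float(_radius_at(spec, np.array([ang]))[0])
            tip = rb + spec.spicule_len_frac * spec.r0
            dang = half_w / max(rb, 1.0)
            tri_theta = np.array([ang - dang, ang + dang, ang])
            tri_r = np.array([rb - 3.0, rb - 3.0, tip])
            tri = np.column_stack(
                [c + tri_r * np.sin(tri_theta), c + tri_r * np.cos(tri_theta)]
            )
            rr, cc = draw_polygon(tri[:, 0], tri[:, 1], shape=shape)
            mask[rr, cc] = True

    lab = label(mask, connectivity=2)
    if lab.max() > 1:  # keep the body component (spicules always overlap it)
        areas = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(areas)) + 1)
    if mask.sum() < 16:
        raise ValueError("phantom mask smaller than 16 px")
    return mask, poly


def truth_box(mask: np.ndarray, pad: int = ANNOT_PAD) -> BoundingBox:
    """Bounding box of a mask padded by ``pad`` pixels (clipped to the patch)."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = BoundingBox(
        int(rows[0]) - pad,
        int(cols[0]) - pad,
        int(rows[-1] - rows[0] + 1) + 2 * pad,
        int(cols[-1] - cols[0] + 1) + 2 * pad,
    )
    return box.clip(mask.shape)


def body_box(spec: PhantomSpec, shape: tuple[int, int], pad: int = ANNOT_PAD) -> BoundingBox:
    """Annotation box: the extent of the mass *body* (harmonic boundary only).

    Spicules are excluded on purpose — like a detector box on a real
    spiculated mass, the annotation frames the dominant blob while narrow
    spicules may stray past it. This keeps the mass the majority structure
    inside its own crop, the operating assumption of the histogram
    segmentation.
    """
    poly = boundary_polygon(spec)
    box = BoundingBox(
        int(np.floor(poly[:, 0].min())) - pad,
        int(np.floor(poly[:, 1].min())) - pad,
        int(np.ceil(np.ptp(poly[:, 0]))) + 2 * pad + 1,
        int(np.ceil(np.ptp(poly[:, 1]))) + 2 * pad + 1,
    )
    return box.clip(shape)


def render_patch(spec: PhantomSpec, mask: np.ndarray) -> GrayImage:
    """Render the intensity patch for a phantom mask (deterministic per seed)."""
    shape = mask.shape
    rng = np.random.default_rng([int(spec.seed) % (2**31), 23])

    field = gaussian_filter(rng.normal(0.0, 1.0, shape), FIELD_SMOOTH)
    sd = field.std()
    if sd > 0:
        field *= FIELD_SD / sd
    img = CLASS_LEVELS[spec.cs_class - 1] + field

    moat = dilation(mask, disk(MOAT_WIDTH)) & ~mask
    img[moat] = CLASS_LEVELS[0]

    img[mask] = CLASS_LEVELS[spec.cm_class - 1] + rng.normal(
        0.0, MASS_TEXTURE_SD, int(mask.sum())
    )
    img = img + rng.normal(0.0, spec.noise_sd, shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return GrayImage(pixels=img, L=255, id=f"phantom_{spec.seed}")


def _density_relation(cm: int, cs: int) -> int:
    return 2 if cm == cs else (3 if cm > cs else 1)


def _spec_for_grade(grade: int, rng: np.random.Generator, patch_size: int, seed: int) -> tuple[PhantomSpec, int, str]:
    """Draw generative parameters for one sample of a BI-RADS grade.

    Grade semantics: BR-2 round/oval, no lobes, low density; BR-3 oval,
    0-2 lobes, low/equal; BR-4 lobulated, 3-8 lobes, equal/high;
    BR-5 spiculated, >=8 lobes, high density.
    """
    r0 = rng.uniform(22.0, 28.0)
    phase = rng.uniform(0, 2 * np.pi)
    if grade == 2:
        if rng.random() < 0.5:
            harmonics: tuple = ()
            margin = "round"
        else:
            harmonics = ((rng.uniform(0.03, 0.07), 2, phase),)
            margin = "oval"
        lobes, spic = 0, 0
        cm, cs = 2, int(rng.choice([3, 4]))
    elif grade == 3:
        if rng.random() < 0.5:
            harmonics = ((rng.uniform(0.10, 0.16), 2, phase),)
            lobes = 0
        else:
            harmonics = ((rng.uniform(0.08, 0.12), 2, phase), (rng.uniform(0.05, 0.08), 4, phase))
            lobes = 2
        margin, spic = "oval", 0
        if rng.random() < 0.5:
            cm, cs = 2, int(rng.choice([3, 4]))  # low
        else:
            cm = int(rng.choice([2, 3]))
            cs = cm  # equal
    elif grade == 4:
        k = int(rng.integers(4, 9))
        harmonics = ((rng.uniform(0.11, 0.15), k, phase),)
        lobes, margin, spic = k, "lobulated", 0
        if rng.random() < 0.5:
            cm = int(rng.choice([3, 4]))
            cs = cm  # equal
        else:
            cm, cs = int(rng.choice([3, 4])), 2  # high
    elif grade == 5:
        k = int(rng.integers(8, 13))
        harmonics = ((rng.uniform(0.09, 0.13), k, phase),)
        lobes, margin = k, "spiculated"
        spic = int(rng.integers(8, 13))
        cm, cs = 4, int(rng.choice([1, 2]))  # high
    else:
        raise ValueError(f"grade must be 2..5, got {grade}")
    spec = PhantomSpec(
        patch_size=patch_size,
        r0=r0,
        harmonics=harmonics,
        n_spicules=spic,
        spicule_len_frac=0.22 if spic else 0.10,
        spicule_width=8.0,
        cm_class=cm,
        cs_class=cs,
        noise_sd=4.0,
        seed=seed,
    )
    return spec, lobes, margin


def make_phantom(spec: PhantomSpec, grade: int, true_lobes: int, margin_class: str) -> PhantomTruth:
    """Rasterize + render a spec and bundle it with its ground truth."""
    mask, _ = make_mask(spec)
    img = render_patch(spec, mask)
    return PhantomTruth(
        image=img,
        mask=mask,
        box=body_box(spec, mask.shape),
        true_lobes=true_lobes,
        margin_class=margin_class,
        density_relation=_density_relation(spec.cm_class, spec.cs_class),
        grade=grade,
        spec=spec,
    )


def sample_dataset(
    n_per_grade: Sequence[int] = (20, 13, 22, 21),
    seed: int = 0,
    out_dir: Optional[Path] = None,
    patch_size: int = 128,
) -> list[PhantomTruth]:
    """Generate a graded phantom dataset (BR-2..BR-5), optionally writing it to disk.

    ``n_per_grade`` follows the BR-2..BR-5 order. With an ``out_dir`` the
    images and truth masks are written as PNG, the annotations as CSV, and
    the generative truth as JSON — the same formats the I/O module reads.
    """
    if len(n_per_grade) != 4:
        raise ValueError("n_per_grade must list counts for BR-2..BR-5")
    master = np.random.default_rng(int(seed) % (2**31))
    phantoms: list[PhantomTruth] = []
    for grade, n in zip((2, 3, 4, 5), n_per_grade):
        for i in range(int(n)):
            sample_seed = int(master.integers(0, 2**31 - 1))
            spec, lobes, margin = _spec_for_grade(grade, master, patch_size, sample_seed)
            ph = make_phantom(spec, grade, lobes, margin)
            ph.image.id = f"ph{grade}_{i:03d}"
            phantoms.append(ph)

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        records, truth = [], []
        for ph in phantoms:
            img_path = out_dir / "images" / f"{ph.image.id}.png"
            mask_path = out_dir / "masks" / f"{ph.image.id}.png"
            write_image(ph.image, img_path)
            write_mask(ph.mask, mask_path)
            records.append(
                SampleRecord(
                    image=f"images/{ph.image.id}.png",
                    box=ph.box,
                    grade=ph.grade,
                    mask=f"masks/{ph.image.id}.png",
                )
            )
            truth.append(
                {
                    "id": ph.image.id,
                    "grade": ph.grade,
                    "true_lobes": ph.true_lobes,
                    "margin_class": ph.margin_class,
                    "density_relation": ph.density_relation,
                    "cm_class": ph.spec.cm_class,
                    "cs_class": ph.spec.cs_class,
                    "seed": ph.spec.seed,
                }
            )
        write_annotations(records, out_dir / "annotations.csv")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return phantoms
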