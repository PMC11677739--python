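"""Contrast data augmentation.

Two variants per image, emulating acquisition-device contrast differences:

* a gamma correction whose exponent is chosen from the image's gray-level
  proportion ``rho = 100 * (mu + sigma) / L`` (bright images, ``rho > 70``,
  get the stronger exponent), and
* a grayscale morphological opening with a circular structuring element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.morphology import disk, opening

from .io import GrayImage


@dataclass(frozen=True)
class AugmentParams:
    """Parameters of the two augmentation transforms."""

    rho_threshold: float = 70.0
    gamma_low: float = 0.5   # exponent for low-brightness images
    gamma_high: float = 0.3  # exponent for high-brightness images
    opening_radius: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.gamma_low <= 1 and 0 < self.gamma_high <= 1):
            raise ValueError("gamma exponents must lie in (0, 1]")
        if self.opening_radius < 1:
            raise ValueError("opening radius must be >= 1")


@dataclass(frozen=True)
class IntensityRatio:
    """Gray-level proportion rho = 100*(mu+sigma)/L and its ingredients."""

    rho: float
    mu: float
    sigma: float


def compute_rho(img: GrayImage) -> IntensityRatio:
    """Gray-level proportion of an image (population mean/std over all pixels)."""
    pix = np.asarray(img.pixels, dtype=float)
    mu = float(pix.mean())
    sigma = float(pix.std())
    return IntensityRatio(rho=100.0 * (mu + sigma) / img.L, mu=mu, sigma=sigma)


def gamma_variant(img: GrayImage, params: AugmentParams = AugmentParams()) -> GrayImage:
    """Gamma-corrected variant, exponent selected by the image's brightness.

    Intensities are normalized to [0, 1], raised to the selected exponent and
    rescaled to [0, L] with half-up rounding, so 0 and L are fixed points.
    """
    rho = compute_rho(img).rho
    gamma = params.gamma_high if rho > params.rho_threshold else params.gamma_low
    norm = np.asarray(img.pixels, dtype=float) / img.L
    out = np.floor(img.L * np.power(norm, gamma) + 0.5)
    out = np.clip(out, 0, img.L).astype(np.asarray(img.pixels).dtype)
    return img.with_pixels(out, suffix="_gamma")


def opening_variant(img: GrayImage, params: AugmentParams = AugmentParams()) -> GrayImage:
    """Grayscale opening with a discrete disk (Euclidean radius) structuring element."""
    out = opening(np.asarray(img.pixels), disk(params.opening_radius))
    return img.with_pixels(out, suffix="_open")


def augment_set(
    images: Sequence[GrayImage], params: AugmentParams = AugmentParams()
) -> list[GrayImage]:
    """Originals plus one gamma and one opening variant each (3n outputs)."""
    out: list[GrayImage] = []
    for img in images:
        out.append(img.with_pixels(np.asarray(img.pixels), suffix="_orig"))
        out.append(gamma_variant(img, params))
        out.append(opening_variant(img, params))
    return out
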