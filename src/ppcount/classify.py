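"""Per-pixel HSI stain classification.

Each RGB pixel is converted to hue / saturation / intensity, where
intensity is the plain mean of the three 8-bit channels, saturation is
``1 - 3 min(R,G,B) / (R+G+B)`` and hue is the standard arccos definition
normalized to [0, 1). A pixel is "stained" when it is chromatic, its hue
falls inside the configured circular window and its saturation clears the
threshold; stained pixels are then binned by intensity into strong /
medium / weak positive or background, and unstained pixels are negative
(counterstain) tissue below the negative ceiling, background otherwise.

Intensity bins are half-open ``[low, high)`` so every boundary value lands
in exactly one class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .params import PixelClassParams

__all__ = [
    "PixelClassLabel",
    "HSIPixel",
    "ClassCounts",
    "rgb_to_hsi",
    "circular_hue_distance",
    "classify_pixel",
    "classify_image",
]

_TWO_PI = 2.0 * math.pi


class PixelClassLabel(IntEnum):
    """Stain class of a single pixel."""

    STRONG_POSITIVE = 0
    MEDIUM_POSITIVE = 1
    WEAK_POSITIVE = 2
    NEGATIVE = 3
    BACKGROUND = 4


# The four classes that count as tissue (everything but BACKGROUND).
TISSUE_LABELS = (
    PixelClassLabel.STRONG_POSITIVE,
    PixelClassLabel.MEDIUM_POSITIVE,
    PixelClassLabel.WEAK_POSITIVE,
    PixelClassLabel.NEGATIVE,
)


@dataclass(frozen=True)
class HSIPixel:
    """Hue (circular [0,1), undefined when achromatic), saturation [0,1],
    intensity [0,255]."""

    hue: float
    saturation: float
    intensity: float
    achromatic: bool = False


@dataclass(frozen=True)
class ClassCounts:
    """Per-class pixel tallies for a region; the five fields sum to the
    number of pixels classified."""

    n_strong: int = 0
    n_medium: int = 0
    n_weak: int = 0
    n_negative: int = 0
    n_background: int = 0

    def __post_init__(self) -> None:
        for name, v in self.to_dict().items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.n_strong + self.n_medium + self.n_weak + self.n_negative + self.n_background

    @property
    def n_tissue(self) -> int:
        """Tissue pixels: all non-background classes."""
        return self.n_strong + self.n_medium + self.n_weak + self.n_negative

    def to_dict(self) -> dict[str, int]:
        return {
            "n_strong": self.n_strong,
            "n_medium": self.n_medium,
            "n_weak": self.n_weak,
            "n_negative": self.n_negative,
            "n_background": self.n_background,
        }

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "ClassCounts":
        counts = np.bincount(np.asarray(labels, dtype=np.int64).ravel(), minlength=5)
        return cls(*(int(c) for c in counts[:5]))

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts(
            self.n_strong + other.n_strong,
            self.n_medium + other.n_medium,
            self.n_weak + other.n_weak,
            self.n_negative + other.n_negative,
            self.n_background + other.n_background,
        )


def rgb_to_hsi(r: int, g: int, b: int) -> HSIPixel:
    """Convert one 8-bit RGB triple to HSI.

    Intensity is ``(r+g+b)/3`` (unrounded); saturation is
    ``1 - 3*min/(r+g+b)`` (0 for black); hue follows the arccos formula
    with the ``b > g`` reflection, scaled from radians to [0, 1). Gray
    pixels (r = g = b) are flagged achromatic with hue 0.
    """
    for name, c in (("r", r), ("g", g), ("b", b)):
        if not 0 <= c <= 255:
            raise ValueError(f"channel {name} out of [0, 255]: {c}")
    s = r + g + b
    intensity = s / 3.0
    if s == 0:
        return HSIPixel(hue=0.0, saturation=0.0, intensity=0.0, achromatic=True)
    saturation = 1.0 - 3.0 * min(r, g, b) / s
    if r == g == b:
        return HSIPixel(hue=0.0, saturation=0.0, intensity=intensity, achromatic=True)
    num = 0.5 * ((r - g) + (r - b))
    den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = math.acos(max(-1.0, min(1.0, num / den)))
    hue = theta / _TWO_PI
    if b > g:
        hue = 1.0 - hue
    return HSIPixel(hue=hue % 1.0, saturation=saturation, intensity=intensity)


def circular_hue_distance(h1: float, h2: float) -> float:
    """Shortest distance between two hues on the circular [0, 1) axis."""
    d = abs(h1 - h2) % 1.0
    return min(d, 1.0 - d)


def classify_pixel(p: HSIPixel, params: PixelClassParams) -> PixelClassLabel:
    """Assign the stain class of a single HSI pixel.

    Stained pixels (chromatic, hue within ``hue_value +/- hue_width/2``
    circularly, saturation >= threshold) bin by intensity: strong on
    ``[isp_low, isp_high)``, medium on ``[isp_high, ip_high)``, weak on
    ``[ip_high, iwp_high)``, background at or above ``iwp_high``. Stained
    pixels darker than ``isp_low`` fall back to negative. Unstained pixels
    are negative below the effective negative ceiling, else background.
    """
    stained = (
        not p.achromatic
        and circular_hue_distance(p.hue, params.hue_value) <= params.hue_width / 2.0
        and p.saturation >= params.saturation_threshold
    )
    i = p.intensity
    if stained:
        if i >= params.iwp_high:
            return PixelClassLabel.BACKGROUND
        if i >= params.ip_high:
            return PixelClassLabel.WEAK_POSITIVE
        if i >= params.isp_high:
            return PixelClassLabel.MEDIUM_POSITIVE
        if i >= params.isp_low:
            return PixelClassLabel.STRONG_POSITIVE
        return PixelClassLabel.NEGATIVE
    if i < params.effective_inp_high:
        return PixelClassLabel.NEGATIVE
    return PixelClassLabel.BACKGROUND


def _hsi_arrays(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized HSI decomposition of an H x W x 3 uint8 image.

    Returns (hue, saturation, intensity, achromatic); hue is 0 where
    achromatic.
    """
    rgb = img.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    s = r + g + b
    intensity = s / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(s > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / s, 0.0)
    achromatic = (img[..., 0] == img[..., 1]) & (img[..., 1] == img[..., 2])
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(den > 0, num / den, 1.0), -1.0, 1.0))
    hue = theta / _TWO_PI
    hue = np.where(b > g, 1.0 - hue, hue) % 1.0
    hue = np.where(achromatic, 0.0, hue)
    return hue, saturation, intensity, achromatic


def classify_image(
    img: np.ndarray,
    params: PixelClassParams,
    exclusion_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, ClassCounts]:
    """Classify every pixel of an RGB raster.

    Applies :func:`classify_pixel` independently per pixel (vectorized).
    Pixels under ``exclusion_mask`` are removed from tissue and counted as
    background. Returns the label raster (uint8 of
    :class:`PixelClassLabel`) and the aggregate :class:`ClassCounts`.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError(f"expected 8-bit channels, got dtype {img.dtype}")

    hue, sat, intensity, achromatic = _hsi_arrays(img)
    hue_dist = np.abs(hue - params.hue_value) % 1.0
    hue_dist = np.minimum(hue_dist, 1.0 - hue_dist)
    stained = (
        ~achromatic
        & (hue_dist <= params.hue_width / 2.0)
        & (sat >= params.saturation_threshold)
    )

    labels = np.empty(img.shape[:2], dtype=np.uint8)
    # Unstained pixels first, then overwrite stained ones bin by bin.
    labels[...] = np.where(
        intensity < params.effective_inp_high,
        np.uint8(PixelClassLabel.NEGATIVE),
        np.uint8(PixelClassLabel.BACKGROUND),
    )
    labels[stained & (intensity < params.isp_low)] = PixelClassLabel.NEGATIVE
    labels[stained & (intensity >= params.isp_low) & (intensity < params.isp_high)] = (
        PixelClassLabel.STRONG_POSITIVE
    )
    labels[stained & (intensity >= params.isp_high) & (intensity < params.ip_high)] = (
        PixelClassLabel.MEDIUM_POSITIVE
    )
    labels[stained & (intensity >= params.ip_high) & (intensity < params.iwp_high)] = (
        PixelClassLabel.WEAK_POSITIVE
    )
    labels[stained & (intensity >= params.iwp_high)] = PixelClassLabel.BACKGROUND

    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask).astype(bool)
        if exclusion_mask.shape != img.shape[:2]:
            raise ValueError(
                f"exclusion mask shape {exclusion_mask.shape} does not match "
                f"image shape {img.shape[:2]}"
            )
        labels[exclusion_mask] = PixelClassLabel.BACKGROUND

    return labels, ClassCounts.from_labels(labels)
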