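"""Whole-slide quantification: tiled classification, mark-up image, NSR.

The slide score (NSR) is the number of strong-positive (DAB) pixels
divided by the total tissue pixels — every non-background class — times
100. Background (bright unstained pixels, plus anything excluded by a
stroma mask) is not tissue and never enters the denominator.

Slides are processed in tiles (default 1000 x 1000 px, no overlap) purely
as a memory-bounding device: classification is per-pixel, so the
aggregated counts are identical to a single full-raster pass regardless
of the tiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassCounts, PixelClassLabel, classify_image
from .params import PixelClassParams

__all__ = [
    "NoTissueError",
    "SlideImage",
    "TileSpec",
    "SlideQuantification",
    "compute_nsr",
    "analyze_slide",
    "render_markup",
    "MARKUP_PALETTE",
]


class NoTissueError(ValueError):
    """Raised when a region contains no tissue pixels (NSR undefined)."""


@dataclass
class SlideImage:
    """An RGB slide raster with its physical resolution and identity.

    ``mpp`` is microns per pixel (isotropic). ``stroma_mask`` marks pixels
    to exclude from tissue (True = stroma / exclude).
    """

    pixels: np.ndarray
    mpp: float
    slide_id: str = ""
    marker: str = ""
    stroma_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"slide raster must be H x W x 3, got {self.pixels.shape}")
        if not (self.mpp is not None and self.mpp > 0):
            raise ValueError(f"mpp must be > 0, got {self.mpp}")
        if self.stroma_mask is not None:
            self.stroma_mask = np.asarray(self.stroma_mask).astype(bool)
            if self.stroma_mask.shape != self.pixels.shape[:2]:
                raise ValueError(
                    f"stroma mask shape {self.stroma_mask.shape} does not match "
                    f"raster {self.pixels.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class TileSpec:
    """Tile geometry for whole-slide processing (0-based, row-major,
    half-open [start, end) intervals; edge tiles may be smaller)."""

    view_width: int = 1000
    view_height: int = 1000
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.view_width <= 0 or self.view_height <= 0:
            raise ValueError("tile dimensions must be positive")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")
        if self.overlap >= min(self.view_width, self.view_height):
            raise ValueError("overlap must be smaller than the tile size")


@dataclass
class SlideQuantification:
    """Whole-slide result: class counts, NSR %, label + mark-up rasters,
    tissue mask."""

    counts: ClassCounts
    nsr_percent: float
    labels: np.ndarray
    markup: np.ndarray
    tissue_mask: np.ndarray
    slide_id: str = ""
    marker: str = ""


def compute_nsr(counts: ClassCounts) -> float:
    """Strong-positive pixels over total tissue pixels, as a percentage.

    Raises :class:`NoTissueError` when there are no tissue pixels rather
    than silently returning 0.
    """
    tissue = counts.n_tissue
    if tissue == 0:
        raise NoTissueError("no tissue pixels: NSR is undefined")
    return 100.0 * counts.n_strong / tissue


# Vendor-style mark-up palette: strong red, medium orange, weak yellow,
# negative blue; background keeps the original pixel.
MARKUP_PALETTE: dict[PixelClassLabel, tuple[int, int, int]] = {
    PixelClassLabel.STRONG_POSITIVE: (255, 0, 0),
    PixelClassLabel.MEDIUM_POSITIVE: (255, 165, 0),
    PixelClassLabel.WEAK_POSITIVE: (255, 255, 0),
    PixelClassLabel.NEGATIVE: (0, 0, 255),
}


def render_markup(labels: np.ndarray, original: np.ndarray) -> np.ndarray:
    """False-color overlay of the label raster (background shows through)."""
    labels = np.asarray(labels)
    original = np.asarray(original)
    if original.shape[:2] != labels.shape:
        raise ValueError(
            f"label raster {labels.shape} and image {original.shape[:2]} differ in size"
        )
    markup = original.astype(np.uint8).copy()
    for label, color in MARKUP_PALETTE.items():
        markup[labels == label] = color
    return markup


def analyze_slide(
    slide: SlideImage,
    params: PixelClassParams,
    tiles: TileSpec = TileSpec(),
) -> SlideQuantification:
    """Classify a whole slide tile-by-tile and score it.

    Stroma-mask pixels are excluded from tissue (classified background).
    Raises :class:`NoTissueError` if nothing on the slide is tissue.
    """
    h, w = slide.shape
    labels = np.empty((h, w), dtype=np.uint8)
    step_r = tiles.view_height - tiles.overlap
    step_c = tiles.view_width - tiles.overlap
    for r0 in range(0, h, step_r):
        r1 = min(r0 + tiles.view_height, h)
        for c0 in range(0, w, step_c):
            c1 = min(c0 + tiles.view_width, w)
            mask_tile = (
                slide.stroma_mask[r0:r1, c0:c1] if slide.stroma_mask is not None else None
            )
            tile_labels, _ = classify_image(slide.pixels[r0:r1, c0:c1], params, mask_tile)
            labels[r0:r1, c0:c1] = tile_labels
    counts = ClassCounts.from_labels(labels)
    nsr = compute_nsr(counts)
    tissue_mask = labels != PixelClassLabel.BACKGROUND
    markup = render_markup(labels, slide.pixels)
    return SlideQuantification(
        counts=counts,
        nsr_percent=nsr,
        labels=labels,
        markup=markup,
        tissue_mask=tissue_mask,
        slide_id=slide.slide_id,
        marker=slide.marker,
    )
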