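"""Hot-spot detection: the square window of fixed physical area (default
2 mm²) with the highest concentration of strong-positive staining.

Windows are scanned on a stride grid; a window is admissible when its
tissue fraction clears ``min_tissue_fraction`` and its overlap with the
stroma mask does not exceed ``max_stroma_fraction``. Among admissible
windows the one maximizing window NSR (strong / tissue within the window)
wins, ties broken by smallest (row, col). Window sums come from integral
images, so the scan is O(H·W) regardless of window size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassCounts, PixelClassLabel
from .slide import compute_nsr

__all__ = [
    "HotspotParams",
    "HotspotWindow",
    "NoAdmissibleWindowError",
    "window_side_px",
    "find_hotspot",
]


class NoAdmissibleWindowError(ValueError):
    """No window on the scan grid satisfies the admissibility rules."""


@dataclass(frozen=True)
class HotspotParams:
    """Hot-spot scan settings.

    area_mm2: physical window area in mm² (square window).
    stride_px: scan step in pixels; None means one full window side.
    min_tissue_fraction: minimum fraction of window pixels that are tissue.
    max_stroma_fraction: maximum fraction of window pixels inside the
        stroma mask before the window is discarded (stroma pixels never
        enter the NSR either way; this only rejects stroma-dominated
        windows).
    """

    area_mm2: float = 2.0
    stride_px: int | None = None
    min_tissue_fraction: float = 0.5
    max_stroma_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError(f"area_mm2 must be > 0, got {self.area_mm2}")
        if self.stride_px is not None and self.stride_px < 1:
            raise ValueError(f"stride_px must be >= 1, got {self.stride_px}")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must be in [0, 1]")


@dataclass(frozen=True)
class HotspotWindow:
    """Winning window: top-left (row, col), side in px, its NSR % and counts."""

    row: int
    col: int
    side_px: int
    nsr_percent: float
    counts: ClassCounts


def window_side_px(area_mm2: float, mpp: float) -> int:
    """Side of the square window covering ``area_mm2`` at resolution
    ``mpp`` µm/px: round(sqrt(area)·1000/mpp), at least 1 px."""
    if area_mm2 <= 0 or mpp <= 0:
        raise ValueError(f"area_mm2 and mpp must be > 0, got {area_mm2}, {mpp}")
    return max(1, round(float(np.sqrt(area_mm2)) * 1000.0 / mpp))


def _integral(mask: np.ndarray) -> np.ndarray:
    """Zero-padded summed-area table of a boolean/count raster."""
    s = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0, dtype=np.int64), axis=1, out=s[1:, 1:])
    return s


def _window_sums(sat: np.ndarray, rows: np.ndarray, cols: np.ndarray, side: int) -> np.ndarray:
    """Sums over all side x side windows whose top-left corners are the
    (rows x cols) grid, from a summed-area table."""
    r0 = rows[:, None]
    c0 = cols[None, :]
    return (
        sat[r0 + side, c0 + side]
        - sat[r0, c0 + side]
        - sat[r0 + side, c0]
        + sat[r0, c0]
    )


def find_hotspot(
    labels: np.ndarray,
    tissue_mask: np.ndarray | None = None,
    stroma_mask: np.ndarray | None = None,
    params: HotspotParams = HotspotParams(),
    mpp: float = 0.25,
) -> HotspotWindow:
    """Scan the label raster for the maximal-NSR window of the configured
    physical area.

    ``tissue_mask`` defaults to all non-background labels; stroma pixels
    are removed from both the strong and tissue tallies before scoring.
    Raises :class:`NoAdmissibleWindowError` when no window qualifies and
    ``ValueError`` when the window does not fit inside the raster.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    side = window_side_px(params.area_mm2, mpp)
    if side > h or side > w:
        raise ValueError(
            f"hot-spot window of {side} px does not fit inside a {h} x {w} raster"
        )
    if tissue_mask is None:
        tissue_mask = labels != PixelClassLabel.BACKGROUND
    tissue_mask = np.asarray(tissue_mask).astype(bool)
    if stroma_mask is not None:
        stroma_mask = np.asarray(stroma_mask).astype(bool)
        if stroma_mask.shape != labels.shape:
            raise ValueError("stroma mask does not match the label raster")
        effective_tissue = tissue_mask & ~stroma_mask
        strong = (labels == PixelClassLabel.STRONG_POSITIVE) & ~stroma_mask
    else:
        effective_tissue = tissue_mask
        strong = labels == PixelClassLabel.STRONG_POSITIVE

    stride = params.stride_px if params.stride_px is not None else side
    # flush bottom/right positions keep the scan a full cover even when the
    # stride does not divide the raster
    rows = np.unique(np.append(np.arange(0, h - side + 1, stride), h - side))
    cols = np.unique(np.append(np.arange(0, w - side + 1, stride), w - side))

    strong_sums = _window_sums(_integral(strong), rows, cols, side)
    tissue_sums = _window_sums(_integral(effective_tissue), rows, cols, side)
    area = side * side
    admissible = tissue_sums >= params.min_tissue_fraction * area
    admissible &= tissue_sums > 0
    if stroma_mask is not None:
        stroma_sums = _window_sums(_integral(stroma_mask), rows, cols, side)
        admissible &= stroma_sums <= params.max_stroma_fraction * area
    if not admissible.any():
        raise NoAdmissibleWindowError(
            "no window satisfies the tissue-fraction / stroma constraints"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        nsr = np.where(admissible, 100.0 * strong_sums / tissue_sums, -np.inf)
    # argmax on the row-major flat array: first maximum = smallest (row, col).
    flat_idx = int(np.argmax(nsr))
    ri, ci = divmod(flat_idx, len(cols))
    row, col = int(rows[ri]), int(cols[ci])

    window_labels = labels[row : row + side, col : col + side].copy()
    if stroma_mask is not None:
        window_labels[stroma_mask[row : row + side, col : col + side]] = (
            PixelClassLabel.BACKGROUND
        )
    counts = ClassCounts.from_labels(window_labels)
    return HotspotWindow(
        row=row, col=col, side_px=side, nsr_percent=compute_nsr(counts), counts=counts
    )
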