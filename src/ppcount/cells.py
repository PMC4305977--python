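"""Positive-cell counting and density estimation from the label raster.

An automated analogue of a pathologist's per-mm² positive-cell count:
connected components (8-connectivity) of positively stained pixels whose
physical area clears a minimum cell size are counted as cells, and the
count is normalized by the analyzed tissue area. Touching cells merge into
one component — no watershed splitting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skimage import measure

from .classify import PixelClassLabel, TISSUE_LABELS
from .slide import NoTissueError

__all__ = [
    "CellCountResult",
    "count_positive_cells",
    "density_per_hpf",
    "DEFAULT_HPF_AREA_MM2",
    "DEFAULT_MIN_CELL_AREA_UM2",
]

# Conventional defaults; the field area of a 40x high-power field and a
# minimum plausible cell footprint. Both are configurable call parameters.
DEFAULT_HPF_AREA_MM2 = 0.237
DEFAULT_MIN_CELL_AREA_UM2 = 20.0

POSITIVE_LABELS = frozenset(
    {
        PixelClassLabel.STRONG_POSITIVE,
        PixelClassLabel.MEDIUM_POSITIVE,
        PixelClassLabel.WEAK_POSITIVE,
    }
)


@dataclass(frozen=True)
class CellCountResult:
    """Cell count with its tissue-area normalizations."""

    n_cells: int
    area_mm2: float
    density_per_mm2: float
    density_per_hpf: float


def density_per_hpf(density_per_mm2: float, hpf_area_mm2: float = DEFAULT_HPF_AREA_MM2) -> float:
    """Convert a per-mm² density to cells per high-power field."""
    if density_per_mm2 < 0 or hpf_area_mm2 < 0:
        raise ValueError("densities and field areas must be non-negative")
    return density_per_mm2 * hpf_area_mm2


def count_positive_cells(
    labels: np.ndarray,
    mpp: float,
    min_cell_area_um2: float = DEFAULT_MIN_CELL_AREA_UM2,
    classes: Iterable[PixelClassLabel] = (PixelClassLabel.STRONG_POSITIVE,),
    hpf_area_mm2: float = DEFAULT_HPF_AREA_MM2,
) -> CellCountResult:
    """Count positively stained cells on a classified raster.

    ``classes`` selects which positive bins form a cell (default strong
    only) and must be a subset of the positive classes. The tissue area
    (all non-background pixels) provides the density denominator.
    Raises :class:`NoTissueError` on a raster without tissue.
    """
    if mpp <= 0:
        raise ValueError(f"mpp must be > 0, got {mpp}")
    classes = frozenset(PixelClassLabel(c) for c in classes)
    if not classes <= POSITIVE_LABELS:
        raise ValueError(f"classes must be positive stain classes, got {sorted(classes)}")
    labels = np.asarray(labels)
    tissue_px = int(np.isin(labels, [int(l) for l in TISSUE_LABELS]).sum())
    if tissue_px == 0:
        raise NoTissueError("no tissue pixels: cell density is undefined")
    area_mm2 = tissue_px * (mpp / 1000.0) ** 2

    positive = np.isin(labels, [int(c) for c in classes])
    components = measure.label(positive, connectivity=2)
    if components.max() == 0:
        n_cells = 0
    else:
        px_per_cell = mpp * mpp  # µm² per pixel
        areas_um2 = np.bincount(components.ravel())[1:] * px_per_cell
        n_cells = int((areas_um2 >= min_cell_area_um2).sum())

    density = n_cells / area_mm2
    return CellCountResult(
        n_cells=n_cells,
        area_mm2=area_mm2,
        density_per_mm2=density,
        density_per_hpf=density_per_hpf(density, hpf_area_mm2),
    )
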