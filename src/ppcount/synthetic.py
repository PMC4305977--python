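"""Synthetic slide and study generation with exact ground truth.

Slides emulate the content of a DAB-stained oesophageal biopsy scan at the
level the classifier cares about: a white background, a pale blue
counterstained tissue region, dark-blue negative (hematoxylin) nuclei,
brown positive cells at two intensity levels (strong and weak exemplar
colors), an optional pale stroma band (reported as a mask, never
segmented), and an optional planted high-density hot spot. There is no
attempt at morphological realism — cells are disks — because every pixel's
intended class must remain provable ground truth.

Noise is Gaussian per channel but class-preserving: after adding noise the
raster is reclassified and any pixel whose class flipped is reverted to
its exemplar color, so designed class fractions are exact at every noise
level. Everything is driven by one seeded generator per call; identical
(spec, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import PixelClassLabel, classify_image, classify_pixel, rgb_to_hsi
from .params import PixelClassParams, default_params
from .slide import SlideImage

__all__ = [
    "SyntheticSlideSpec",
    "HotspotPlant",
    "GroundTruth",
    "StudySimSpec",
    "class_exemplar_rgb",
    "generate_slide",
    "generate_study",
    "draw_group_fractions",
    "GROUPS",
]

GROUPS = ("GERD", "EoE_pre", "EoE_post")

# Fixed representative colors, verified against the classifier at use time.
_EXEMPLARS: dict[PixelClassLabel, tuple[int, int, int]] = {
    PixelClassLabel.STRONG_POSITIVE: (120, 60, 20),   # dark DAB brown
    PixelClassLabel.WEAK_POSITIVE: (170, 110, 50),    # light DAB brown
    PixelClassLabel.NEGATIVE: (70, 70, 140),          # hematoxylin blue
    PixelClassLabel.BACKGROUND: (250, 250, 250),      # glass / no tissue
}
# Pale counterstained mucosa (classifies NEGATIVE: low saturation, I < 230).
TISSUE_BASE_RGB = (190, 180, 220)
# Pale stroma: still tissue-like to the classifier; excluded via the mask.
STROMA_RGB = (225, 210, 225)


def class_exemplar_rgb(
    label: PixelClassLabel, params: PixelClassParams | None = None
) -> tuple[int, int, int]:
    """A fixed RGB color that the classifier maps to ``label``.

    Verified against :func:`classify_pixel` on every call; raises if the
    stored color is not representable under ``params`` (e.g. the medium
    bin, which is empty under the default equal cut points).
    """
    params = params or default_params()
    color = _EXEMPLARS.get(PixelClassLabel(label))
    if color is None or classify_pixel(rgb_to_hsi(*color), params) != label:
        raise ValueError(f"no exemplar color for {label!r} under the given parameters")
    return color


@dataclass(frozen=True)
class HotspotPlant:
    """A planted high-density disk: positive staining inside the disk is
    ``density_multiplier`` times more likely than outside."""

    center_row: int
    center_col: int
    radius_px: int
    density_multiplier: float = 10.0


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide.

    ``target_strong_fraction`` / ``target_weak_fraction`` are the intended
    fractions of tissue pixels (stroma excluded) rendered in the strong /
    weak exemplar colors; positive cell disks count toward the strong
    budget, and any remainder is scattered as single-pixel speckle.
    ``stroma_band`` is (row_start, row_end) of a horizontal pale band.
    ``noise_sd`` is the per-channel Gaussian sd (class-preserving, see
    module docstring).
    """

    width_px: int = 512
    height_px: int = 512
    mpp: float = 4.0
    target_strong_fraction: float = 0.0
    target_weak_fraction: float = 0.0
    n_cells_positive: int = 0
    n_cells_negative: int = 0
    cell_radius_um: float = 8.0
    hotspot: HotspotPlant | None = None
    stroma_band: tuple[int, int] | None = None
    noise_sd: float = 0.0
    tissue_margin_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        if self.target_strong_fraction + self.target_weak_fraction > 1.0:
            raise ValueError("target class fractions must sum to at most 1")
        if min(self.target_strong_fraction, self.target_weak_fraction) < 0:
            raise ValueError("target fractions must be non-negative")


@dataclass
class GroundTruth:
    """What was actually rendered, recomputable bit-exactly from the spec."""

    strong_fraction: float
    weak_fraction: float
    n_tissue_px: int
    cell_centroids: list[tuple[int, int, PixelClassLabel]]
    hotspot: HotspotPlant | None
    stroma_mask: np.ndarray | None
    intended_labels: np.ndarray = field(repr=False, default=None)
    seed: int = 0


def _weighted_sample_without_replacement(
    rng: np.random.Generator, candidates: np.ndarray, weights: np.ndarray, k: int
) -> np.ndarray:
    """k draws without replacement, probability proportional to weight
    (exponential-race keys: smallest Exp(1)/w win)."""
    if k >= len(candidates):
        return candidates
    keys = rng.exponential(1.0, size=len(candidates)) / weights
    return candidates[np.argpartition(keys, k)[:k]]


def _place_cells(
    rng: np.random.Generator,
    free: np.ndarray,
    n_cells: int,
    radius_px: int,
    hotspot: HotspotPlant | None,
    shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping disk centers on the free raster.

    ``free`` marks pixels still available (tissue base, outside stroma);
    accepted disks are carved out of it in place. With a planted hot spot,
    centers fall inside its disk with odds boosted by the density
    multiplier.
    """
    h, w = shape
    yy, xx = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = (yy * yy + xx * xx) <= radius_px * radius_px
    # carve a dilated footprint so placed cells never touch (a pixel
    # 8-adjacent to a disk pixel lies within radius + sqrt(2) of its
    # center, so radius + 2 guarantees separation under 8-connectivity)
    pad = radius_px + 2
    yy2, xx2 = np.ogrid[-pad : pad + 1, -pad : pad + 1]
    carve = (yy2 * yy2 + xx2 * xx2) <= pad * pad

    p_in = 0.0
    if hotspot is not None:
        a = np.pi * hotspot.radius_px**2 / (h * w)
        a = min(a, 1.0)
        m = hotspot.density_multiplier
        p_in = (m * a) / (m * a + (1.0 - a)) if a < 1.0 else 1.0

    centers: list[tuple[int, int]] = []
    budget = 1000 * max(1, n_cells)
    while len(centers) < n_cells and budget > 0:
        budget -= 1
        if hotspot is not None and rng.random() < p_in:
            rad = hotspot.radius_px * np.sqrt(rng.random())
            ang = rng.random() * 2 * np.pi
            r = int(round(hotspot.center_row + rad * np.sin(ang)))
            c = int(round(hotspot.center_col + rad * np.cos(ang)))
        else:
            r = int(rng.integers(radius_px, h - radius_px))
            c = int(rng.integers(radius_px, w - radius_px))
        if not (radius_px <= r < h - radius_px and radius_px <= c < w - radius_px):
            continue
        window = free[r - radius_px : r + radius_px + 1, c - radius_px : c + radius_px + 1]
        if not window[disk].all():
            continue
        r0, c0 = max(0, r - pad), max(0, c - pad)
        cw = free[r0 : r + pad + 1, c0 : c + pad + 1]
        cw[carve[pad - (r - r0) :, pad - (c - c0) :][: cw.shape[0], : cw.shape[1]]] = False
        centers.append((r, c))
    if len(centers) < n_cells:
        raise RuntimeError(
            f"could only place {len(centers)} of {n_cells} non-overlapping cells "
            "within the retry budget"
        )
    return centers


def _paint_disks(
    canvas: np.ndarray,
    intended: np.ndarray,
    centers: list[tuple[int, int]],
    radius_px: int,
    color: tuple[int, int, int],
    label: PixelClassLabel,
) -> None:
    yy, xx = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = (yy * yy + xx * xx) <= radius_px * radius_px
    for r, c in centers:
        sl = np.s_[r - radius_px : r + radius_px + 1, c - radius_px : c + radius_px + 1]
        canvas[sl][disk] = color
        intended[sl][disk] = label


def generate_slide(
    spec: SyntheticSlideSpec,
    params: PixelClassParams | None = None,
    slide_id: str = "synthetic",
    marker: str = "",
) -> tuple[SlideImage, GroundTruth]:
    """Render one synthetic slide and its exact ground truth.

    Deterministic in (spec, spec.seed). Raises ``RuntimeError`` when the
    requested cells cannot be placed without overlap.
    """
    params = params or default_params()
    h, w = spec.height_px, spec.width_px
    rng = np.random.default_rng(spec.seed)

    strong_rgb = class_exemplar_rgb(PixelClassLabel.STRONG_POSITIVE, params)
    weak_rgb = class_exemplar_rgb(PixelClassLabel.WEAK_POSITIVE, params)
    negative_rgb = class_exemplar_rgb(PixelClassLabel.NEGATIVE, params)
    background_rgb = class_exemplar_rgb(PixelClassLabel.BACKGROUND, params)

    canvas = np.empty((h, w, 3), dtype=np.uint8)
    canvas[...] = background_rgb
    intended = np.full((h, w), int(PixelClassLabel.BACKGROUND), dtype=np.uint8)

    m = spec.tissue_margin_px
    if h - 2 * m <= 0 or w - 2 * m <= 0:
        raise ValueError("tissue margin leaves no tissue region")
    tissue_region = np.zeros((h, w), dtype=bool)
    tissue_region[m : h - m, m : w - m] = True
    canvas[tissue_region] = TISSUE_BASE_RGB
    intended[tissue_region] = PixelClassLabel.NEGATIVE

    stroma_mask = None
    if spec.stroma_band is not None:
        r0, r1 = spec.stroma_band
        stroma_mask = np.zeros((h, w), dtype=bool)
        stroma_mask[r0:r1, :] = tissue_region[r0:r1, :]
        canvas[stroma_mask] = STROMA_RGB
        # stroma stays NEGATIVE-intended to the classifier but is excluded
        # from tissue accounting through the mask
    in_stroma = stroma_mask if stroma_mask is not None else np.zeros((h, w), dtype=bool)
    countable = tissue_region & ~in_stroma
    n_tissue = int(countable.sum())

    radius_px = max(1, round(spec.cell_radius_um / spec.mpp))
    free = countable.copy()
    free[: radius_px + m, :] = False  # keep disks inside the tissue rectangle
    free[h - radius_px - m :, :] = False
    free[:, : radius_px + m] = False
    free[:, w - radius_px - m :] = False

    centroids: list[tuple[int, int, PixelClassLabel]] = []
    neg_centers = _place_cells(rng, free, spec.n_cells_negative, radius_px, None, (h, w))
    _paint_disks(canvas, intended, neg_centers, radius_px, negative_rgb, PixelClassLabel.NEGATIVE)
    centroids += [(r, c, PixelClassLabel.NEGATIVE) for r, c in neg_centers]

    pos_centers = _place_cells(
        rng, free, spec.n_cells_positive, radius_px, spec.hotspot, (h, w)
    )
    _paint_disks(
        canvas, intended, pos_centers, radius_px, strong_rgb, PixelClassLabel.STRONG_POSITIVE
    )
    centroids += [(r, c, PixelClassLabel.STRONG_POSITIVE) for r, c in pos_centers]

    # Speckle fills the gap between the disk pixels and the target fractions.
    for label, rgb, target in (
        (PixelClassLabel.STRONG_POSITIVE, strong_rgb, spec.target_strong_fraction),
        (PixelClassLabel.WEAK_POSITIVE, weak_rgb, spec.target_weak_fraction),
    ):
        budget = round(target * n_tissue)
        painted = int(((intended == label) & countable).sum())
        need = budget - painted
        if need <= 0:
            continue
        avail = np.flatnonzero((intended.ravel() == PixelClassLabel.NEGATIVE) & countable.ravel())
        if len(avail) < need:
            raise RuntimeError("not enough free tissue pixels to reach the target fraction")
        if spec.hotspot is not None and label == PixelClassLabel.STRONG_POSITIVE:
            rr, cc = np.divmod(avail, w)
            inside = (rr - spec.hotspot.center_row) ** 2 + (
                cc - spec.hotspot.center_col
            ) ** 2 <= spec.hotspot.radius_px**2
            weights = np.where(inside, spec.hotspot.density_multiplier, 1.0)
            chosen = _weighted_sample_without_replacement(rng, avail, weights, need)
        else:
            chosen = rng.choice(avail, size=need, replace=False)
        intended.ravel()[chosen] = label
        canvas.reshape(-1, 3)[chosen] = rgb

    if spec.noise_sd > 0:
        noisy = np.clip(
            canvas.astype(np.float64) + rng.normal(0.0, spec.noise_sd, canvas.shape),
            0,
            255,
        ).round().astype(np.uint8)
        observed, _ = classify_image(noisy, params)
        flipped = observed != intended
        # class-preserving clip: pixels pushed across a class boundary
        # revert to their exemplar color
        exemplar_lut = np.zeros((5, 3), dtype=np.uint8)
        for lab in (
            PixelClassLabel.STRONG_POSITIVE,
            PixelClassLabel.WEAK_POSITIVE,
            PixelClassLabel.NEGATIVE,
            PixelClassLabel.BACKGROUND,
        ):
            exemplar_lut[lab] = _EXEMPLARS[lab]
        noisy[flipped] = exemplar_lut[intended[flipped]]
        canvas = noisy

    strong_px = int(((intended == PixelClassLabel.STRONG_POSITIVE) & countable).sum())
    weak_px = int(((intended == PixelClassLabel.WEAK_POSITIVE) & countable).sum())
    truth = GroundTruth(
        strong_fraction=strong_px / n_tissue,
        weak_fraction=weak_px / n_tissue,
        n_tissue_px=n_tissue,
        cell_centroids=centroids,
        hotspot=spec.hotspot,
        stroma_mask=stroma_mask,
        intended_labels=intended,
        seed=spec.seed,
    )
    slide = SlideImage(
        pixels=canvas, mpp=spec.mpp, slide_id=slide_id, marker=marker, stroma_mask=stroma_mask
    )
    return slide, truth


# ---------------------------------------------------------------------------
# Two-group study simulation

# Group-level whole-slide strong fractions per marker, patterned on typical
# lymphocyte / dendritic / mast-cell DAB loads in oesophageal biopsies
# (reflux-disease baseline; the disease effect multiplies these).
DEFAULT_BASE_FRACTIONS: dict[str, float] = {
    "CD3": 0.0123,
    "CD8": 0.0062,
    "CD4": 0.0025,
    "CD20": 0.0005,
    "CD1a": 0.0135,
    "CD117": 0.0008,
}
DEFAULT_EFFECTS: dict[str, float] = {"GERD": 1.0, "EoE_pre": 2.0, "EoE_post": 1.1}
# Between-biopsy spread of the strong fraction (lognormal sigma).
DEFAULT_SIGMA = 0.3


@dataclass(frozen=True)
class StudySimSpec:
    """Recipe for a two/three-group study with a controllable effect on
    the positive-pixel fraction.

    ``effects`` multiply the per-marker base fraction for each group;
    effect 1.0 for every group is the null study.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"GERD": 10, "EoE_pre": 10, "EoE_post": 6}
    )
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    markers: tuple[str, ...] = ("CD3", "CD8")
    base_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_FRACTIONS)
    )
    sigma: float = DEFAULT_SIGMA
    slide_px: int = 512
    mpp: float = 4.0
    cell_radius_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("subject counts must be non-negative")
        if not any(n >= 1 for n in self.n_per_group.values()):
            raise ValueError("at least one group needs a subject")
        missing = set(self.markers) - set(self.base_fractions)
        if missing:
            raise ValueError(f"no base fraction for markers {sorted(missing)}")


def draw_group_fractions(
    n: int, base_fraction: float, effect: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject designed strong fractions: lognormal spread around
    ``base_fraction * effect``, capped at 0.5 of tissue."""
    return np.minimum(0.5, base_fraction * effect * rng.lognormal(0.0, sigma, size=n))


def generate_study(spec: StudySimSpec) -> tuple[list[SlideImage], pd.DataFrame]:
    """Generate one slide per subject x marker plus the design table.

    Returns the slides and a tidy ground-truth table with columns
    slide_id, subject, group, marker, designed_strong_fraction, seed.
    Deterministic in spec.seed.
    """
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    slides: list[SlideImage] = []
    rows: list[dict] = []
    side = spec.slide_px
    disk_r = max(1, round(spec.cell_radius_um / spec.mpp))
    disk_area = np.count_nonzero(
        (np.arange(-disk_r, disk_r + 1)[:, None] ** 2 + np.arange(-disk_r, disk_r + 1) ** 2)
        <= disk_r * disk_r
    )
    tissue_area = (side - 16) ** 2

    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        effect = spec.effects.get(group, 1.0)
        for i in range(n):
            subject = f"{group}_{i:02d}"
            for marker in spec.markers:
                frac = float(
                    draw_group_fractions(1, spec.base_fractions[marker], effect, spec.sigma, rng)[0]
                )
                slide_seed = int(rng.integers(0, 2**31 - 1))
                n_cells = min(200, int(frac * tissue_area / disk_area * 0.5))
                center = side // 2 + int(rng.integers(-side // 8, side // 8 + 1))
                sspec = SyntheticSlideSpec(
                    width_px=side,
                    height_px=side,
                    mpp=spec.mpp,
                    target_strong_fraction=frac,
                    n_cells_positive=n_cells,
                    n_cells_negative=20,
                    cell_radius_um=spec.cell_radius_um,
                    hotspot=HotspotPlant(center, center, radius_px=side // 6,
                                         density_multiplier=3.0),
                    noise_sd=4.0,
                    seed=slide_seed,
                )
                slide_id = f"{subject}_{marker}"
                slide, _ = generate_slide(sspec, slide_id=slide_id, marker=marker)
                slides.append(slide)
                rows.append(
                    {
                        "slide_id": slide_id,
                        "subject": subject,
                        "group": group,
                        "marker": marker,
                        "designed_strong_fraction": frac,
                        "seed": slide_seed,
                    }
                )
    return slides, pd.DataFrame(rows)
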