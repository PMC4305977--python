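"""Independent reference implementations used only as test oracles.

Each oracle is written directly from the quantification rules via a
different route than the package (scalar math loops instead of vectorized
numpy, explicit window slicing instead of integral images, pairwise-win
counting instead of rank sums) so agreement is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

# label codes mirrored here on purpose (independent of the package enum)
STRONG, MEDIUM, WEAK, NEGATIVE, BACKGROUND = 0, 1, 2, 3, 4


def classify_rgb_reference(r: int, g: int, b: int, p) -> int:
    """Scalar re-statement of the threshold rules for one RGB pixel."""
    total = r + g + b
    intensity = total / 3.0
    saturation = 0.0 if total == 0 else 1.0 - 3.0 * min(r, g, b) / total
    achromatic = r == g == b
    stained = False
    if not achromatic:
        num = ((r - g) + (r - b)) / 2.0
        den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = math.acos(max(-1.0, min(1.0, num / den)))
        hue = theta / (2.0 * math.pi)
        if b > g:
            hue = 1.0 - hue
        hue %= 1.0
        d = abs(hue - p.hue_value) % 1.0
        d = min(d, 1.0 - d)
        stained = d <= p.hue_width / 2.0 and saturation >= p.saturation_threshold
    if stained:
        if intensity >= p.iwp_high:
            return BACKGROUND
        if intensity >= p.ip_high:
            return WEAK
        if intensity >= p.isp_high:
            return MEDIUM
        if intensity >= p.isp_low:
            return STRONG
        return NEGATIVE
    ceiling = p.iwp_high if p.inp_high == -1 else p.inp_high
    return NEGATIVE if intensity < ceiling else BACKGROUND


def classify_image_reference(img: np.ndarray, p) -> np.ndarray:
    """Per-pixel python-loop classification of an H x W x 3 raster."""
    h, w, _ = img.shape
    out = np.empty((h, w), dtype=np.uint8)
    px = img.reshape(-1, 3)
    flat = out.reshape(-1)
    for i in range(px.shape[0]):
        flat[i] = classify_rgb_reference(int(px[i, 0]), int(px[i, 1]), int(px[i, 2]), p)
    return out


def find_hotspot_reference(
    labels: np.ndarray,
    side: int,
    stride: int,
    min_tissue_fraction: float,
    stroma_mask: np.ndarray | None = None,
    max_stroma_fraction: float = 0.25,
) -> tuple[int, int, float] | None:
    """Exhaustive window scan by explicit slicing; returns (row, col, nsr%)
    of the best admissible window or None."""
    h, w = labels.shape
    tissue = labels != BACKGROUND
    strong = labels == STRONG
    if stroma_mask is not None:
        tissue = tissue & ~stroma_mask
        strong = strong & ~stroma_mask
    best = None
    area = side * side
    rows = sorted(set(list(range(0, h - side + 1, stride)) + [h - side]))
    cols = sorted(set(list(range(0, w - side + 1, stride)) + [w - side]))
    for r in rows:
        for c in cols:
            t = int(tissue[r : r + side, c : c + side].sum())
            if t == 0 or t < min_tissue_fraction * area:
                continue
            if stroma_mask is not None:
                s = int(stroma_mask[r : r + side, c : c + side].sum())
                if s > max_stroma_fraction * area:
                    continue
            nsr = 100.0 * int(strong[r : r + side, c : c + side].sum()) / t
            if best is None or nsr > best[2]:
                best = (r, c, nsr)
    return best


def mann_whitney_exact_reference(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments and
    counting pairwise wins (U = #{x_i > y_j} + 0.5 #ties)."""

    def u_of(first, second):
        u = 0.0
        for a in first:
            for b in second:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_of(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        first = [pooled[i] for i in idx]
        second = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_of(first, second))
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, float(min(1.0, 2.0 * min(p_low, p_high)))
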