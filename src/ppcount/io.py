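"""File I/O, run configuration, and the end-to-end study pipeline.

Rasters travel as 8-bit RGB TIFF or PNG with a sidecar JSON carrying at
minimum the scan resolution (``mpp``, microns per pixel) — resolution is
never guessed from vendor tags. Masks are single-channel PNGs with 255
marking excluded (stroma) pixels. Reports are RFC-4180 CSV plus a JSON
summary, written so that re-reading reproduces every numeric field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .cells import (
    DEFAULT_HPF_AREA_MM2,
    DEFAULT_MIN_CELL_AREA_UM2,
    count_positive_cells,
)
from .classify import PixelClassLabel
from .hotspot import HotspotParams, find_hotspot
from .params import PixelClassParams, default_params
from .slide import SlideImage, TileSpec, analyze_slide
from .stats import (
    bonferroni_adjust,
    compare_groups,
    diagnostic_performance,
    pearson_correlation,
)

__all__ = [
    "InputError",
    "RunConfig",
    "StudyReport",
    "read_slide",
    "read_mask",
    "write_raster",
    "run_study_pipeline",
    "write_report",
]

logger = logging.getLogger("ppcount")


class InputError(ValueError):
    """Malformed or missing input (bad raster, sidecar, or annotation)."""


@dataclass
class RunConfig:
    """Everything the pipeline needs; defaults reproduce the shipped
    threshold set, 1000 px tiles, and a 2 mm² hot spot."""

    params: PixelClassParams = field(default_factory=default_params)
    tiles: TileSpec = field(default_factory=TileSpec)
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    hpf_area_mm2: float = DEFAULT_HPF_AREA_MM2
    min_cell_area_um2: float = DEFAULT_MIN_CELL_AREA_UM2
    threshold_pct: float = 2.0
    diagnostic_markers: tuple[str, ...] = ("CD3", "CD8")
    bonferroni_m: int | None = None  # None: number of markers in the study
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class StudyReport:
    """Pipeline output: per-slide metrics, per-marker comparisons and
    correlations, the threshold-rule diagnostics, and a summary dict."""

    slides: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    summary: dict


def _load_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path))
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputError(f"{path}: expected an RGB raster, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise InputError(f"{path}: unsupported bit depth {img.dtype} (need 8-bit/channel)")
    return img


def read_slide(path: str | Path, sidecar: str | Path) -> SlideImage:
    """Load a TIFF/PNG raster with its sidecar JSON metadata.

    The sidecar must provide ``mpp``; ``slide_id`` defaults to the file
    stem. A missing or non-positive mpp is an error, never a default.
    """
    path, sidecar = Path(path), Path(sidecar)
    img = _load_raster(path)
    try:
        meta = json.loads(sidecar.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read sidecar {sidecar}: {exc}") from exc
    if "mpp" not in meta:
        raise InputError(f"sidecar {sidecar} lacks the required 'mpp' key")
    try:
        return SlideImage(
            pixels=img,
            mpp=float(meta["mpp"]),
            slide_id=str(meta.get("slide_id", path.stem)),
            marker=str(meta.get("marker", "")),
        )
    except ValueError as exc:
        raise InputError(str(exc)) from exc


def read_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel mask PNG; 255 (any nonzero) means exclude."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise InputError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    return arr > 0


def write_raster(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB raster (or a boolean mask as 0/255) as TIFF or PNG."""
    path = Path(path)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img).save(path)


def _quantify_one(slide: SlideImage, config: RunConfig) -> dict:
    quant = analyze_slide(slide, config.params, config.tiles)
    hs = find_hotspot(
        quant.labels,
        tissue_mask=quant.tissue_mask,
        stroma_mask=slide.stroma_mask,
        params=config.hotspot,
        mpp=slide.mpp,
    )
    cells = count_positive_cells(
        quant.labels,
        slide.mpp,
        min_cell_area_um2=config.min_cell_area_um2,
        hpf_area_mm2=config.hpf_area_mm2,
    )
    c = quant.counts
    return {
        "slide_id": slide.slide_id,
        "marker": slide.marker,
        "n_strong": c.n_strong,
        "n_medium": c.n_medium,
        "n_weak": c.n_weak,
        "n_negative": c.n_negative,
        "n_background": c.n_background,
        "whole_slide_pct": quant.nsr_percent,
        "hotspot_pct": hs.nsr_percent,
        "hotspot_row": hs.row,
        "hotspot_col": hs.col,
        "hotspot_side_px": hs.side_px,
        "n_cells": cells.n_cells,
        "area_mm2": cells.area_mm2,
        "density_per_mm2": cells.density_per_mm2,
        "density_per_hpf": cells.density_per_hpf,
    }


_METHOD_COLUMNS = ("whole_slide_pct", "hotspot_pct", "density_per_mm2")


def run_study_pipeline(
    slides: Sequence[SlideImage],
    annotations: pd.DataFrame,
    config: RunConfig | None = None,
) -> StudyReport:
    """Quantify every slide, assemble the study table, and run the
    statistics stage.

    ``annotations`` needs columns slide_id, group, marker (and optionally
    subject). Per marker and scoring method the two primary groups (GERD
    vs EoE_pre) are compared with Mann-Whitney (Kruskal-Wallis across all
    three groups when a third is present), p-values Bonferroni-adjusted
    across the marker family; densities are correlated with the two NSR
    scores per marker; and the >threshold whole-slide rule is evaluated
    against the disease labels.
    """
    config = config or RunConfig()
    logging.basicConfig(level=config.log_level)
    required = {"slide_id", "group", "marker"}
    if not required <= set(annotations.columns):
        raise InputError(f"annotations must have columns {sorted(required)}")
    ann = annotations.set_index("slide_id")
    missing = [s.slide_id for s in slides if s.slide_id not in ann.index]
    if missing:
        raise InputError(f"slides without annotation: {missing}")

    rows = []
    for slide in slides:
        logger.info("quantifying %s", slide.slide_id)
        try:
            row = _quantify_one(slide, config)
        except Exception as exc:
            raise type(exc)(f"slide {slide.slide_id!r}: {exc}") from exc
        meta = ann.loc[slide.slide_id]
        row["group"] = meta["group"]
        row["marker"] = row["marker"] or meta["marker"]
        row["subject"] = meta["subject"] if "subject" in ann.columns else slide.slide_id
        rows.append(row)
    table = pd.DataFrame(rows)

    markers = sorted(table["marker"].unique())
    m_family = config.bonferroni_m if config.bonferroni_m is not None else len(markers)

    comp_rows = []
    for marker in markers:
        sub = table[table["marker"] == marker]
        by_group = {g: sub.loc[sub["group"] == g] for g in sub["group"].unique()}
        for method in _METHOD_COLUMNS:
            if "GERD" in by_group and "EoE_pre" in by_group:
                res = compare_groups(
                    [by_group["GERD"][method], by_group["EoE_pre"][method]],
                    "mann_whitney",
                    m_comparisons=m_family,
                )
                comp_rows.append(
                    {
                        "marker": marker,
                        "method": method,
                        "test": res.test_name,
                        "groups": "GERD|EoE_pre",
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "p_adjusted": res.p_adjusted,
                        "significant": res.p_adjusted < 0.05,
                    }
                )
            if len(by_group) >= 3:
                res = compare_groups(
                    [by_group[g][method] for g in sorted(by_group)],
                    "kruskal_wallis",
                    m_comparisons=m_family,
                )
                comp_rows.append(
                    {
                        "marker": marker,
                        "method": method,
                        "test": res.test_name,
                        "groups": "|".join(sorted(by_group)),
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "p_adjusted": res.p_adjusted,
                        "significant": res.p_adjusted < 0.05,
                    }
                )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=[
            "marker",
            "method",
            "test",
            "groups",
            "statistic",
            "p_value",
            "p_adjusted",
            "significant",
        ],
    )

    corr_rows = []
    for marker in markers:
        sub = table[table["marker"] == marker]
        for score in ("whole_slide_pct", "hotspot_pct"):
            try:
                r, p = pearson_correlation(sub["density_per_mm2"], sub[score])
            except ValueError:
                r, p = float("nan"), float("nan")
            corr_rows.append({"marker": marker, "score": score, "r": r, "p_value": p})
    correlations = pd.DataFrame(corr_rows, columns=["marker", "score", "r", "p_value"])

    diag = None
    diag_markers = [m for m in config.diagnostic_markers if m in markers] or markers
    two_group = table[table["group"].isin(["GERD", "EoE_pre"])]
    two_group = two_group[two_group["marker"].isin(diag_markers)]
    if not two_group.empty:
        per_subject = two_group.groupby("subject").agg(
            score=("whole_slide_pct", "max"), group=("group", "first")
        )
        labels = (per_subject["group"] == "EoE_pre").to_numpy()
        if labels.any() and not labels.all():
            d = diagnostic_performance(
                per_subject["score"].to_numpy(), labels, config.threshold_pct
            )
            diag = {
                "threshold_pct": d.threshold_pct,
                "markers": diag_markers,
                "tp": d.tp,
                "fp": d.fp,
                "tn": d.tn,
                "fn": d.fn,
                "ppv": d.ppv,
                "npv": d.npv,
            }

    summary = {
        "n_slides": len(table),
        "n_markers": len(markers),
        "markers": markers,
        "groups": sorted(table["group"].unique()),
        "bonferroni_m": m_family,
        "diagnostics": diag,
    }
    return StudyReport(
        slides=table, comparisons=comparisons, correlations=correlations, summary=summary
    )


def write_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write slides.csv, comparisons.csv, correlations.csv and
    summary.json; numeric fields survive a CSV round trip exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "slides": outdir / "slides.csv",
        "comparisons": outdir / "comparisons.csv",
        "correlations": outdir / "correlations.csv",
        "summary": outdir / "summary.json",
    }
    # str(float) round-trips in Python 3, so default to_csv is lossless
    report.slides.to_csv(paths["slides"], index=False, lineterminator="\r\n")
    report.comparisons.to_csv(paths["comparisons"], index=False, lineterminator="\r\n")
    report.correlations.to_csv(paths["correlations"], index=False, lineterminator="\r\n")
    paths["summary"].write_text(json.dumps(report.summary, indent=2, sort_keys=True))
    return paths
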