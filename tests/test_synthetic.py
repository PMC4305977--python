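import numpy as np
import pytest

from ppcount.classify import PixelClassLabel, classify_image, classify_pixel, rgb_to_hsi
from ppcount.slide import analyze_slide
from ppcount.synthetic import (
    HotspotPlant,
    StudySimSpec,
    SyntheticSlideSpec,
    class_exemplar_rgb,
    draw_group_fractions,
    generate_slide,
    generate_study,
)


@pytest.mark.parametrize(
    "label",
    [
        PixelClassLabel.STRONG_POSITIVE,
        PixelClassLabel.WEAK_POSITIVE,
        PixelClassLabel.NEGATIVE,
        PixelClassLabel.BACKGROUND,
    ],
)
def test_exemplar_colors_classify_to_their_label(label, params):
    rgb = class_exemplar_rgb(label, params)
    assert classify_pixel(rgb_to_hsi(*rgb), params) == label


def test_medium_exemplar_unrepresentable(params):
    """The default equal cut points leave no representable medium color."""
    with pytest.raises(ValueError):
        class_exemplar_rgb(PixelClassLabel.MEDIUM_POSITIVE, params)


def test_generation_is_deterministic():
    spec = SyntheticSlideSpec(
        width_px=128, height_px=128, target_strong_fraction=0.05,
        n_cells_positive=5, noise_sd=6.0, seed=42,
    )
    s1, t1 = generate_slide(spec)
    s2, t2 = generate_slide(spec)
    assert (s1.pixels == s2.pixels).all()
    assert t1.strong_fraction == t2.strong_fraction
    assert t1.cell_centroids == t2.cell_centroids


def test_realized_fraction_near_target():
    spec = SyntheticSlideSpec(width_px=256, height_px=256,
                              target_strong_fraction=0.10, seed=1)
    _, truth = generate_slide(spec)
    assert abs(truth.strong_fraction - 0.10) <= 0.02


def test_noiseless_closing_loop_is_exact(params):
    """Classifying a noiseless generated slide recovers the rendered
    fractions as a pixel-count identity."""
    spec = SyntheticSlideSpec(width_px=256, height_px=256,
                              target_strong_fraction=0.07,
                              target_weak_fraction=0.05, seed=9)
    slide, truth = generate_slide(spec)
    quant = analyze_slide(slide, params)
    assert quant.counts.n_strong == round(truth.strong_fraction * truth.n_tissue_px)
    assert quant.counts.n_tissue == truth.n_tissue_px
    assert quant.nsr_percent == pytest.approx(100.0 * truth.strong_fraction, abs=1e-9)


def test_noise_preserves_classes(params):
    """Class-preserving noise: every rendered pixel keeps its intended
    class under classification (>= 99 % required, construction gives 100 %)."""
    spec = SyntheticSlideSpec(width_px=256, height_px=256,
                              target_strong_fraction=0.10,
                              n_cells_positive=10, noise_sd=8.0, seed=3)
    slide, truth = generate_slide(spec)
    labels, _ = classify_image(slide.pixels, params)
    agree = (labels == truth.intended_labels).mean()
    assert agree >= 0.99
    # noise actually perturbs the raster
    noiseless, _ = generate_slide(
        SyntheticSlideSpec(**{**spec.__dict__, "noise_sd": 0.0})
    )
    assert (slide.pixels != noiseless.pixels).any()


def test_planted_hotspot_concentrates_staining():
    spec = SyntheticSlideSpec(
        width_px=256, height_px=256, target_strong_fraction=0.05,
        hotspot=HotspotPlant(128, 128, radius_px=40, density_multiplier=10.0), seed=4,
    )
    _, truth = generate_slide(spec)
    labels = truth.intended_labels
    yy, xx = np.mgrid[:256, :256]
    inside = (yy - 128) ** 2 + (xx - 128) ** 2 <= 40 * 40
    tissue = labels != PixelClassLabel.BACKGROUND
    strong = labels == PixelClassLabel.STRONG_POSITIVE
    density_in = strong[inside & tissue].mean()
    density_out = strong[~inside & tissue].mean()
    assert density_in > 2 * density_out


def test_stroma_band_masked_not_tissue():
    spec = SyntheticSlideSpec(width_px=128, height_px=128,
                              stroma_band=(30, 50), seed=0)
    slide, truth = generate_slide(spec)
    assert truth.stroma_mask is not None
    assert truth.stroma_mask[35, 64]
    assert not truth.stroma_mask[100, 64]
    assert (slide.stroma_mask == truth.stroma_mask).all()


def test_cell_overlap_exhaustion_errors():
    spec = SyntheticSlideSpec(width_px=64, height_px=64, mpp=1.0,
                              n_cells_positive=500, cell_radius_um=8.0, seed=0)
    with pytest.raises(RuntimeError):
        generate_slide(spec)


def test_fraction_validation():
    with pytest.raises(ValueError):
        SyntheticSlideSpec(target_strong_fraction=0.8, target_weak_fraction=0.4)


def test_draw_group_fractions_null_means_equal():
    rng = np.random.default_rng(0)
    a = draw_group_fractions(2000, 0.01, 1.0, 0.0, rng)
    assert np.allclose(a, 0.01)  # sigma 0, effect 1: designed means identical


def test_generate_study_cardinality_and_determinism():
    spec = StudySimSpec(n_per_group={"GERD": 2, "EoE_pre": 2, "EoE_post": 2},
                        markers=("CD3",), seed=8)
    slides, table = generate_study(spec)
    assert len(slides) == 6
    assert len(table) == 6
    assert set(table["group"]) == {"GERD", "EoE_pre", "EoE_post"}
    slides2, table2 = generate_study(spec)
    assert all((a.pixels == b.pixels).all() for a, b in zip(slides, slides2))
    assert table.equals(table2)
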