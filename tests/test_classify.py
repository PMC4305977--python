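import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppcount.classify import (
    ClassCounts,
    PixelClassLabel,
    circular_hue_distance,
    classify_image,
    classify_pixel,
    rgb_to_hsi,
)
from ppcount.synthetic import class_exemplar_rgb

from _oracles import classify_image_reference

channel = st.integers(0, 255)


@pytest.mark.parametrize(
    "rgb, hue, sat, intensity, achromatic",
    [
        ((255, 0, 0), 0.0, 1.0, 85.0, False),
        ((100, 100, 100), None, 0.0, 100.0, True),
        ((120, 60, 20), 0.065, 0.70, 66.667, False),  # hand-evaluated arccos hue
        ((170, 110, 50), 0.0833, 0.5455, 110.0, False),
    ],
)
def test_rgb_to_hsi_known_values(rgb, hue, sat, intensity, achromatic):
    p = rgb_to_hsi(*rgb)
    assert p.achromatic == achromatic
    if hue is not None:
        assert p.hue == pytest.approx(hue, abs=5e-3)
    assert p.saturation == pytest.approx(sat, abs=5e-4)
    assert p.intensity == pytest.approx(intensity, abs=5e-3)


@given(channel, channel, channel)
def test_rgb_to_hsi_invariants(r, g, b):
    p = rgb_to_hsi(r, g, b)
    assert p.intensity == (r + g + b) / 3.0
    assert 0.0 <= p.saturation <= 1.0
    assert 0.0 <= p.hue < 1.0
    assert p.achromatic == (r == g == b)
    if p.achromatic:
        assert p.saturation == 0.0


def test_rgb_to_hsi_rejects_out_of_range():
    with pytest.raises(ValueError):
        rgb_to_hsi(300, 0, 0)


def test_circular_hue_distance_wraps():
    assert circular_hue_distance(0.95, 0.1) == pytest.approx(0.15)
    assert circular_hue_distance(0.1, 0.95) == pytest.approx(0.15)
    assert circular_hue_distance(0.5, 0.5) == 0.0


@pytest.mark.parametrize(
    "rgb, expected",
    [
        ((120, 60, 20), PixelClassLabel.STRONG_POSITIVE),  # dark DAB brown, I < 70
        ((255, 255, 255), PixelClassLabel.BACKGROUND),  # white glass
        ((170, 110, 50), PixelClassLabel.WEAK_POSITIVE),  # 70 <= I < 230, in hue window
        ((70, 70, 140), PixelClassLabel.NEGATIVE),  # hematoxylin blue, low saturation
    ],
)
def test_classify_pixel_examples(rgb, expected, params):
    assert classify_pixel(rgb_to_hsi(*rgb), params) == expected


def test_classify_pixel_hue_window_is_circular(params):
    """Hue 0.95 is 0.15 from the 0.1 window center: inside a 0.5-wide window."""
    from ppcount.classify import HSIPixel

    inside = HSIPixel(hue=0.95, saturation=0.9, intensity=50.0)
    assert classify_pixel(inside, params) == PixelClassLabel.STRONG_POSITIVE
    outside = HSIPixel(hue=0.50, saturation=0.9, intensity=90.0)
    assert classify_pixel(outside, params) == PixelClassLabel.NEGATIVE


def test_classify_image_all_white(params):
    img = np.full((10, 10, 3), 255, dtype=np.uint8)
    labels, counts = classify_image(img, params)
    assert counts == ClassCounts(0, 0, 0, 0, 100)
    assert (labels == PixelClassLabel.BACKGROUND).all()


def test_classify_image_assembled_exemplars(params):
    """An image built from known exemplar colors yields the designed counts."""
    px = (
        [class_exemplar_rgb(PixelClassLabel.STRONG_POSITIVE)] * 30
        + [class_exemplar_rgb(PixelClassLabel.WEAK_POSITIVE)] * 20
        + [class_exemplar_rgb(PixelClassLabel.NEGATIVE)] * 50
    )
    img = np.array(px, dtype=np.uint8).reshape(10, 10, 3)
    _, counts = classify_image(img, params)
    assert counts == ClassCounts(30, 0, 20, 50, 0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_classify_image_matches_per_pixel_oracle(seed, params):
    """Vectorized classification agrees pixel-for-pixel with an independent
    scalar re-statement of the threshold rules."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
    labels, counts = classify_image(img, params)
    expected = classify_image_reference(img, params)
    assert (labels == expected).all()
    assert counts.total == 64 * 64


def test_medium_bin_empty_under_default_thresholds(params, rng):
    """Equal middle cut points (ip_high = isp_high) leave no medium bin."""
    img = rng.integers(0, 256, size=(128, 128, 3), dtype=np.uint8)
    _, counts = classify_image(img, params)
    assert counts.n_medium == 0


def test_classify_image_deterministic(params, rng):
    img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
    l1, _ = classify_image(img, params)
    l2, _ = classify_image(img, params)
    assert (l1 == l2).all()


def test_exclusion_mask_moves_pixels_to_background(params):
    img = np.tile(
        np.array(class_exemplar_rgb(PixelClassLabel.STRONG_POSITIVE), dtype=np.uint8),
        (4, 4, 1),
    )
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, :] = True
    labels, counts = classify_image(img, params, exclusion_mask=mask)
    assert counts.n_strong == 12
    assert counts.n_background == 4
    assert (labels[0] == PixelClassLabel.BACKGROUND).all()


def test_classify_image_input_validation(params):
    with pytest.raises(ValueError):
        classify_image(np.zeros((0, 0, 3), dtype=np.uint8), params)
    with pytest.raises(ValueError):
        classify_image(
            np.zeros((4, 4, 3), dtype=np.uint8),
            params,
            exclusion_mask=np.zeros((5, 5), dtype=bool),
        )
    with pytest.raises(ValueError):
        classify_image(np.zeros((4, 4, 3), dtype=np.float64) + 0.5, params)


def test_class_counts_conservation(params, rng):
    img = rng.integers(0, 256, size=(37, 23, 3), dtype=np.uint8)
    _, counts = classify_image(img, params)
    assert counts.total == 37 * 23
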