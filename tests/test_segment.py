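"""Plant-mask construction: thresholding, cross erosion, Otsu, full detectors."""

import numpy as np
import pytest

from hsirow.errors import DegenerateInputError
from hsirow.hypercube import HyperCube
from hsirow.segment import (
    SegmentationParams,
    detect_plants_swir,
    detect_plants_vnir,
    erode_cross,
    otsu_threshold,
    threshold_mask,
)
from hsirow.simulate import SceneConfig, default_endmembers, generate_scene

from conftest import small_scene_config


def brute_force_erode(mask: np.ndarray) -> np.ndarray:
    """Per-pixel 4-neighbourhood check with outside-image neighbours false."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            ok = mask[y, x]
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                yy, xx = y + dy, x + dx
                ok &= 0 <= yy < h and 0 <= xx < w and mask[yy, xx]
            out[y, x] = ok
    return out


def otsu_oracle_bins(img: np.ndarray, nbins: int = 256) -> set[int]:
    """Exhaustive between-class-variance scan over all histogram boundaries.

    Returns every boundary bin achieving the maximum: moving the boundary
    across empty valley bins leaves both classes unchanged, so the optimum is
    a plateau of exactly tied bins.
    """
    counts, edges = np.histogram(img, bins=nbins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    variances = np.full(nbins - 1, -np.inf)
    for i in range(nbins - 1):
        w1 = counts[: i + 1].sum()
        w2 = total - w1
        if w1 == 0 or w2 == 0:
            continue
        m1 = (counts[: i + 1] * centres[: i + 1]).sum() / w1
        m2 = (counts[i + 1 :] * centres[i + 1 :]).sum() / w2
        variances[i] = w1 * w2 * (m1 - m2) ** 2
    best = variances.max()
    return set(np.flatnonzero(variances >= best * (1 - 1e-12)))


def test_threshold_mask_extremes_and_two_level(rng):
    img = rng.uniform(0.2, 0.8, (4, 5))
    assert threshold_mask(img, 0.0).all()
    assert not threshold_mask(img, 1.0).any()
    two = np.where(rng.uniform(size=(6, 6)) < 0.5, 0.1, 0.8)
    np.testing.assert_array_equal(threshold_mask(two, 0.4), two == 0.8)


def test_erosion_removes_isolated_pixels():
    mask = np.zeros((7, 7), dtype=bool)
    mask[3, 3] = True
    assert not erode_cross(mask).any()


def test_erosion_border_pixels_need_full_support():
    mask = np.ones((4, 4), dtype=bool)
    out = erode_cross(mask)
    assert out[1:3, 1:3].all()
    assert not out[0, :].any() and not out[:, 0].any()


def test_erosion_matches_brute_force_and_is_anti_extensive(rng):
    for _ in range(5):
        mask = rng.uniform(size=(10, 10)) < 0.6
        out = erode_cross(mask)
        np.testing.assert_array_equal(out, brute_force_erode(mask))
        assert not np.any(out & ~mask)


def test_otsu_on_balanced_two_value_image_lies_between_the_values(rng):
    img = np.where(np.arange(100).reshape(10, 10) < 50, 0.0, 1.0)
    thr = otsu_threshold(img)
    assert 0.0 < thr < 1.0


def test_otsu_rejects_constant_image():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full((5, 5), 0.3))


def test_otsu_matches_brute_force_bin(rng):
    for _ in range(5):
        img = np.concatenate([
            rng.normal(0.2, 0.05, 400),
            rng.normal(0.7, 0.05, 600),
        ]).reshape(20, 50)
        thr = otsu_threshold(img)
        _, edges = np.histogram(img, bins=256)
        thr_bin = int(np.clip(np.searchsorted(edges, thr, side="right") - 1, 0, 255))
        assert thr_bin in otsu_oracle_bins(img)


def _cardboard_cube(n_bands: int = 40) -> HyperCube:
    members = default_endmembers(np.linspace(400, 896, n_bands))
    data = np.tile(members.vnir_of("cardboard"), (30, 40, 1))
    return HyperCube(data, members.vnir_wavelengths)


def test_pure_cardboard_cube_yields_empty_vnir_mask():
    assert not detect_plants_vnir(_cardboard_cube()).any()


def test_vnir_mask_never_extends_below_the_detected_boundary():
    cfg = small_scene_config(5)
    vnir, _, truth = generate_scene(cfg)
    mask = detect_plants_vnir(vnir)
    rows = np.arange(vnir.height)[:, None]
    # nothing below the true background bottom + 1
    assert not (mask & (rows > truth.vnir.boundary_row[None, :] + 1)).any()


def test_swir_crop_fraction_blanks_exactly_the_bottom_rows():
    cfg = small_scene_config(6)
    _, swir, truth = generate_scene(cfg)
    from hsirow.preprocess import subtract_dark_current

    cube = subtract_dark_current(swir, truth.swir.dark)
    full = detect_plants_swir(cube, SegmentationParams(swir_bottom_crop_fraction=0.0))
    f = 0.25
    cropped = detect_plants_swir(cube, SegmentationParams(swir_bottom_crop_fraction=f))
    n = int(np.floor(f * cube.height))
    assert not cropped[cube.height - n :, :].any()
    np.testing.assert_array_equal(cropped[: cube.height - n], full[: cube.height - n])


def test_segmentation_params_validate():
    with pytest.raises(ValueError):
        SegmentationParams(ndvi_threshold=1.5)
    with pytest.raises(ValueError):
        SegmentationParams(swir_bottom_crop_fraction=1.0)
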