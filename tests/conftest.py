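"""Shared fixtures: scaled synthetic scenes and detection results.

Test scenes keep every generator default that defines the study conditions
(endmember spectra, noise, drift, dark current, thresholds) but use reduced
spatial/spectral grids so the whole suite runs in minutes.  The reduced
heights are chosen so that mask-discretisation effects (e.g. the one-pixel
erosion bias on the tile strip) stay small relative to the recovery
tolerances, as they are at the full scanner geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from hsirow.preprocess import subtract_dark_current
from hsirow.segment import detect_plants_swir, detect_plants_vnir, erode_cross
from hsirow.simulate import SceneConfig, generate_scene
from hsirow.whiteref import detect_whiteref_swir, detect_whiteref_vnir

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: Scaled scene geometry used throughout the suite.
SMALL = dict(
    n_plants=12,
    plant_spacing_px=100,
    vnir_height=180,
    swir_height=200,
    vnir_bands=40,
    swir_bands=100,
)

N_SEEDS = 20


def small_scene_config(seed: int, **overrides) -> SceneConfig:
    params = dict(SMALL)
    params.update(overrides)
    return SceneConfig(seed=seed, **params)


def tile_height_px(cfg: SceneConfig, height: int) -> int:
    return int(round(cfg.tile_bottom_frac * height)) - int(round(cfg.tile_top_frac * height))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    return 1.0 if union == 0 else np.count_nonzero(a & b) / union


@dataclass
class SceneDetections:
    """Everything the recovery tests need from one seeded scene (masks only)."""

    seed: int
    vnir_plant_mask: np.ndarray
    swir_plant_mask: np.ndarray
    vnir_plant_truth: np.ndarray  # eroded + boundary-clipped comparator
    swir_plant_truth: np.ndarray  # bottom-cropped comparator
    vnir_tile_mask: np.ndarray
    swir_tile_mask: np.ndarray
    vnir_tile_truth: np.ndarray
    swir_tile_truth: np.ndarray
    vnir_column_valid: np.ndarray
    swir_column_valid: np.ndarray
    post_columns: np.ndarray
    boundary_row: np.ndarray
    plant_centres: np.ndarray
    plant_missing: np.ndarray
    regions_width: int


def _detect_scene(seed: int) -> SceneDetections:
    cfg = small_scene_config(seed)
    vnir, swir, truth = generate_scene(cfg)
    swir_dc = subtract_dark_current(swir, truth.swir.dark)

    vnir_mask = detect_plants_vnir(vnir)
    swir_mask = detect_plants_swir(swir_dc)

    rows_v = np.arange(vnir.height)[:, None]
    vnir_truth = erode_cross(truth.vnir.plant_mask) & (
        rows_v <= truth.vnir.boundary_row[None, :]
    )
    n_crop = int(np.floor(0.15 * swir.height))
    swir_truth = truth.swir.plant_mask.copy()
    swir_truth[swir.height - n_crop :, :] = False

    panel_v = detect_whiteref_vnir(vnir, expected_width=tile_height_px(cfg, vnir.height))
    panel_s = detect_whiteref_swir(swir_dc)

    return SceneDetections(
        seed=seed,
        vnir_plant_mask=vnir_mask,
        swir_plant_mask=swir_mask,
        vnir_plant_truth=vnir_truth,
        swir_plant_truth=swir_truth,
        vnir_tile_mask=panel_v.mask,
        swir_tile_mask=panel_s.mask,
        vnir_tile_truth=truth.vnir.tile_mask,
        swir_tile_truth=truth.swir.tile_mask,
        vnir_column_valid=panel_v.column_valid,
        swir_column_valid=panel_s.column_valid,
        post_columns=truth.vnir.post_mask.any(axis=0),
        boundary_row=truth.vnir.boundary_row,
        plant_centres=np.array([p.centre_x for p in truth.plants]),
        plant_missing=np.array([p.missing for p in truth.plants]),
        regions_width=vnir.width,
    )


@pytest.fixture(scope="session")
def scene_bank() -> list[SceneDetections]:
    """Detection results on the scaled default scene for 20 seeds."""
    return [_detect_scene(seed) for seed in range(N_SEEDS)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
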