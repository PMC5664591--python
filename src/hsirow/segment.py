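"""Binary plant masks for each scanner.

VNIR: threshold the NDVI image, erode with a 3x3 cross to drop stray and
mixed edge pixels, then remove everything below the grass/background seam.
SWIR: threshold the 1375/1411 nm water-absorption contrast at the Otsu
optimum and blank a fixed fraction of bottom rows (the grass strip, which the
seam approach does not handle as cleanly in the noisier SWIR data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .boundary import DEFAULT_LAMBDA_VER, BoundaryPath, cost_grass_boundary, min_cost_path
from .errors import DegenerateInputError
from .hypercube import HyperCube
from .indices import PLANT_SWIR_WINDOWS, ndvi, normalized_difference

__all__ = [
    "SegmentationParams",
    "CROSS_ELEMENT",
    "threshold_mask",
    "erode_cross",
    "otsu_threshold",
    "grass_boundary",
    "detect_plants_vnir",
    "detect_plants_swir",
]

#: 3x3 cross (4-connected) structuring element.
CROSS_ELEMENT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class SegmentationParams:
    """Tunables for plant detection.

    ndvi_threshold
        Fixed NDVI cut for vegetation; 0.3 is a conventional green-vegetation
        threshold and the detectors tolerate a wide band around it.
    swir_bottom_crop_fraction
        Fraction of bottom rows blanked in the SWIR mask.
    """

    ndvi_threshold: float = 0.3
    swir_bottom_crop_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not -1.0 < self.ndvi_threshold < 1.0:
            raise ValueError(f"ndvi_threshold must be in (-1, 1), got {self.ndvi_threshold}")
        if not 0.0 <= self.swir_bottom_crop_fraction < 1.0:
            raise ValueError(
                f"swir_bottom_crop_fraction must be in [0, 1), got "
                f"{self.swir_bottom_crop_fraction}"
            )


def threshold_mask(img: np.ndarray, thr: float) -> np.ndarray:
    """Strict threshold: pixels with value > thr."""
    return np.asarray(img) > thr


def erode_cross(mask: np.ndarray) -> np.ndarray:
    """Binary erosion with the 3x3 cross; outside-image neighbours count false.

    Border pixels therefore survive only with full in-image support, which
    conservatively drops mixed pixels at image edges.
    """
    return ndimage.binary_erosion(np.asarray(mask, dtype=bool), CROSS_ELEMENT, border_value=0)


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's between-class-variance threshold over a 256-bin histogram."""
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        raise DegenerateInputError("constant image has no Otsu threshold")
    return float(threshold_otsu(img, nbins=256))


def grass_boundary(cube: HyperCube, lambda_ver: float = DEFAULT_LAMBDA_VER) -> BoundaryPath:
    """Seam along the background/grass boundary of a VNIR cube."""
    return min_cost_path(cost_grass_boundary(ndvi(cube)), lambda_ver)


def detect_plants_vnir(
    cube: HyperCube,
    params: SegmentationParams | None = None,
    lambda_ver: float = DEFAULT_LAMBDA_VER,
) -> np.ndarray:
    """Plant mask from a VNIR cube (NDVI threshold, erosion, grass removal)."""
    params = params or SegmentationParams()
    index = ndvi(cube)
    mask = erode_cross(threshold_mask(index, params.ndvi_threshold))
    path = min_cost_path(cost_grass_boundary(index), lambda_ver)
    rows = np.arange(cube.height)[:, None]
    mask &= rows <= path.y_at[None, :]
    return mask


def detect_plants_swir(
    cube: HyperCube, params: SegmentationParams | None = None
) -> np.ndarray:
    """Plant mask from a SWIR cube (water-band contrast, Otsu, bottom crop)."""
    params = params or SegmentationParams()
    index = normalized_difference(cube, *PLANT_SWIR_WINDOWS)
    mask = threshold_mask(index, otsu_threshold(index))
    n_crop = int(np.floor(params.swir_bottom_crop_fraction * cube.height))
    if n_crop > 0:
        mask[cube.height - n_crop :, :] = False
    return mask
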