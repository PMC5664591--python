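"""White-reference tile detection and occlusion filtering.

The reflectance standard is a bright, spectrally flat tile kept in-frame for
the whole scan.  In the VNIR its two horizontal edges are found as seams on
the 455-480 nm mean image (the lower edge first, then the upper edge with a
distance penalty anchored one expected tile width above).  In the SWIR the
tile is the low mode of a 1620/1537 nm normalised-difference image and is cut
out by a histogram-valley threshold.  Columns where posts or leaves occlude
the tile are flagged invalid so they never contribute to normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .boundary import (
    DEFAULT_LAMBDA_DIST,
    DEFAULT_LAMBDA_VER,
    cost_edge,
    cost_edge_with_shape,
    min_cost_path,
    shape_function_from_edge,
)
from .errors import DetectionError
from .hypercube import HyperCube
from .indices import BLUE_REF_WINDOW, WHITEREF_SWIR_WINDOWS, band_mean, normalized_difference
from .segment import erode_cross

__all__ = [
    "WhiteRefPanel",
    "detect_whiteref_vnir",
    "detect_whiteref_swir",
    "filter_occluded_columns",
]


@dataclass
class WhiteRefPanel:
    """Tile mask, per-column usability flags, and per-column mean spectra.

    ``per_column_spectrum[x]`` is the mean cube spectrum over the column's
    mask pixels; NaN where the column is invalid or empty.  An invalid column
    contributes nothing to reflectance normalisation.
    """

    mask: np.ndarray
    column_valid: np.ndarray
    per_column_spectrum: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.column_valid = np.asarray(self.column_valid, dtype=bool)
        if self.mask.shape[1] != self.column_valid.size:
            raise ValueError("column_valid length must equal mask width")
        if self.per_column_spectrum.shape[0] != self.column_valid.size:
            raise ValueError("per_column_spectrum must have one row per column")


def _column_spectra(cube: HyperCube, mask: np.ndarray, valid: np.ndarray) -> np.ndarray:
    spectra = np.full((cube.width, cube.n_bands), np.nan)
    for x in np.flatnonzero(valid):
        rows = np.flatnonzero(mask[:, x])
        if rows.size:
            spectra[x] = cube.data[rows, x, :].mean(axis=0)
    return spectra


def _make_panel(cube: HyperCube, mask: np.ndarray) -> WhiteRefPanel:
    valid = mask.any(axis=0)
    return WhiteRefPanel(
        mask=mask & valid[None, :],
        column_valid=valid,
        per_column_spectrum=_column_spectra(cube, mask, valid),
    )


def detect_whiteref_vnir(
    cube: HyperCube,
    expected_width: int,
    lambda_ver: float = DEFAULT_LAMBDA_VER,
    lambda_dist: float = DEFAULT_LAMBDA_DIST,
    darkness_fraction: float = 0.8,
    variance_factor: float = 2.0,
) -> WhiteRefPanel:
    """Detect the tile in a VNIR cube via two seams on the 455-480 nm image.

    The tile's lower edge is a bright-above/dark-below transition, so the
    first seam runs on the negated image; the upper edge is then found with a
    distance penalty whose vertex sits ``expected_width`` rows above the lower
    edge.  The initial between-seam mask is filtered for occluded columns.
    """
    img = band_mean(cube, BLUE_REF_WINDOW)
    bottom = min_cost_path(cost_edge(-img), lambda_ver)
    d = shape_function_from_edge(bottom, expected_width, cube.height)
    top = min_cost_path(cost_edge_with_shape(img, d, lambda_dist), lambda_ver)
    if np.count_nonzero(top.y_at < bottom.y_at) < cube.width / 2:
        raise DetectionError(
            "white reference not found: top edge is not above the bottom edge "
            "in at least half of the columns"
        )
    rows = np.arange(cube.height)[:, None]
    mask = (rows > top.y_at[None, :]) & (rows < bottom.y_at[None, :])
    panel = _make_panel(cube, mask)
    return filter_occluded_columns(
        panel,
        cube,
        darkness_fraction=darkness_fraction,
        variance_factor=variance_factor,
    )


def filter_occluded_columns(
    panel: WhiteRefPanel,
    cube: HyperCube,
    darkness_fraction: float = 0.8,
    variance_factor: float = 2.0,
) -> WhiteRefPanel:
    """Invalidate columns whose tile pixels look occluded.

    Two rules, applied to the 455-480 nm band-mean values of each column's
    mask pixels: (1) variance above ``variance_factor`` times the mean column
    variance (partial occlusion by a leaf edge); (2) mean intensity below
    ``darkness_fraction`` of the median of the surviving columns (full
    occlusion by a dark post or leaf).
    """
    img = band_mean(cube, BLUE_REF_WINDOW)
    valid = panel.column_valid.copy()
    cols = np.flatnonzero(valid)
    if cols.size == 0:
        raise DetectionError("white reference mask is empty in every column")

    variances = np.full(panel.column_valid.size, np.nan)
    means = np.full(panel.column_valid.size, np.nan)
    for x in cols:
        vals = img[panel.mask[:, x], x]
        variances[x] = vals.var()
        means[x] = vals.mean()

    mean_var = np.nanmean(variances[cols])
    if mean_var > 0:
        valid &= ~(variances > variance_factor * mean_var)
    survivors = np.flatnonzero(valid)
    if survivors.size == 0:
        raise DetectionError("variance filter removed every white-reference column")
    median_mean = np.median(means[survivors])
    valid &= ~(means < darkness_fraction * median_mean)
    if not valid.any():
        raise DetectionError("darkness filter removed every white-reference column")

    mask = panel.mask & valid[None, :]
    return WhiteRefPanel(
        mask=mask,
        column_valid=valid,
        per_column_spectrum=_column_spectra(cube, mask, valid),
    )


def _histogram_valley(img: np.ndarray, nbins: int = 256, smooth: int = 5) -> float:
    """Threshold at the histogram local minimum nearest the 10 % quantile.

    The histogram is smoothed with a moving average; a bin counts as a local
    minimum when it is <= both neighbours and strictly below at least one
    (so the first bin of an empty valley plateau qualifies).  The search walks
    outward from the quantile bin, nearest bins first.
    """
    counts, edges = np.histogram(img, bins=nbins)
    smoothed = uniform_filter1d(counts.astype(float), size=smooth, mode="nearest")
    q = np.quantile(img, 0.10)
    start = int(np.clip(np.searchsorted(edges, q) - 1, 0, nbins - 1))

    def is_min(i: int) -> bool:
        if i <= 0 or i >= nbins - 1:
            return False
        left, mid, right = smoothed[i - 1], smoothed[i], smoothed[i + 1]
        return mid <= left and mid <= right and (mid < left or mid < right)

    for offset in range(nbins):
        for i in (start + offset, start - offset) if offset else (start,):
            if 0 <= i < nbins and is_min(i):
                return float(0.5 * (edges[i] + edges[i + 1]))
    raise DetectionError("index histogram has no interior local minimum")


def detect_whiteref_swir(cube: HyperCube) -> WhiteRefPanel:
    """Detect the tile in a SWIR cube by thresholding the 1620/1537 nm index.

    The spectrally flat tile forms the lowest mode of this index; pixels
    below the histogram-valley threshold are kept and eroded with the 3x3
    cross to drop stray detections.
    """
    img = normalized_difference(cube, *WHITEREF_SWIR_WINDOWS)
    thr = _histogram_valley(img)
    mask = erode_cross(img < thr)
    if not mask.any():
        raise DetectionError("no white-reference pixels below the histogram threshold")
    return _make_panel(cube, mask)
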