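"""Reflectance normalisation and per-plant trait extraction.

Intensities are converted to reflectance by dividing each pixel's spectrum by
the mean white-reference spectrum of its image section (fixed-width column
blocks), which cancels the smooth illumination drift along the travel
direction.  Traits per plant: height (rows of the mask's vertical extent, and
metres via the scanner's swath calibration), density (mean plant pixels per
column), and the mean reflectance spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DetectionError
from .hypercube import HyperCube
from .split import PlantRegion
from .whiteref import WhiteRefPanel

__all__ = [
    "PlantTraits",
    "normalize_reflectance",
    "plant_height",
    "plant_density",
    "plant_mean_spectrum",
    "extract_traits",
    "DEFAULT_SECTION_WIDTH",
    "VNIR_SWATH_PX",
    "SWIR_SWATH_PX",
    "SWATH_M",
]

DEFAULT_SECTION_WIDTH = 100
#: Scanner swath calibration: vertical pixels covering ~1.2 m at target range.
VNIR_SWATH_PX = 402
SWIR_SWATH_PX = 378
SWATH_M = 1.2


@dataclass
class PlantTraits:
    plant_id: int
    height_px: int
    height_m: float
    density: float
    mean_spectrum: np.ndarray | None


def normalize_reflectance(
    cube: HyperCube,
    panel: WhiteRefPanel,
    section_width_px: int = DEFAULT_SECTION_WIDTH,
) -> HyperCube:
    """Divide every pixel by its section's mean white-reference spectrum.

    Sections are consecutive column blocks of ``section_width_px`` (the last
    may be short).  A section with no valid reference columns borrows the
    nearest valid section's spectrum (ties toward the left).
    """
    if section_width_px < 1:
        raise ValueError("section_width_px must be >= 1")
    if not panel.column_valid.any():
        raise DetectionError("white-reference panel has no valid columns")
    width = cube.width
    n_sections = int(np.ceil(width / section_width_px))
    refs = np.full((n_sections, cube.n_bands), np.nan)
    for s in range(n_sections):
        a, b = s * section_width_px, min((s + 1) * section_width_px, width)
        cols = np.flatnonzero(panel.column_valid[a:b]) + a
        if cols.size:
            refs[s] = panel.per_column_spectrum[cols].mean(axis=0)
    have = np.flatnonzero(~np.isnan(refs[:, 0]))
    for s in np.flatnonzero(np.isnan(refs[:, 0])):
        nearest = have[np.argmin(np.abs(have - s))]  # argmin tie -> lower index
        refs[s] = refs[nearest]

    for s in range(n_sections):
        zero = np.flatnonzero(refs[s] == 0)
        if zero.size:
            b = int(zero[0])
            raise DetectionError(
                f"white-reference spectrum is zero in band {b} "
                f"({cube.wavelengths_nm[b]:.1f} nm) of section {s}"
            )

    section_of_col = np.arange(width) // section_width_px
    ref_per_col = refs[section_of_col]  # (width, bands)
    out = cube.data.astype(float) / ref_per_col[None, :, :]
    return cube.with_data(out, kind="reflectance")


def plant_height(
    mask: np.ndarray,
    region: PlantRegion,
    swath_m: float = SWATH_M,
    swath_px: int = VNIR_SWATH_PX,
) -> tuple[int, float]:
    """Vertical extent of the plant mask within the analysis span.

    Returns ``(height_px, height_m)``; the metre value uses the scanner's
    swath calibration (``swath_m`` metres over ``swath_px`` rows).
    """
    a, b = region.analysis_span
    sub = np.asarray(mask, dtype=bool)[:, a:b]
    rows = np.flatnonzero(sub.any(axis=1))
    if rows.size == 0:
        return 0, 0.0
    height_px = int(rows[-1] - rows[0] + 1)
    return height_px, height_px * swath_m / swath_px


def plant_density(mask: np.ndarray, region: PlantRegion) -> float:
    """Mean plant pixels per column within the analysis span."""
    a, b = region.analysis_span
    if b <= a:
        raise ValueError(f"zero-width analysis span {region.analysis_span}")
    sub = np.asarray(mask, dtype=bool)[:, a:b]
    return float(np.count_nonzero(sub) / (b - a))


def plant_mean_spectrum(
    refl_cube: HyperCube, mask: np.ndarray, region: PlantRegion
) -> np.ndarray:
    """Per-band mean reflectance over the plant's mask pixels."""
    a, b = region.analysis_span
    sub = np.asarray(mask, dtype=bool)[:, a:b]
    ys, xs = np.nonzero(sub)
    if ys.size == 0:
        raise DetectionError(f"plant {region.plant_id}: no plant pixels in analysis span")
    return refl_cube.data[ys, xs + a, :].mean(axis=0)


def extract_traits(
    refl_cube: HyperCube,
    mask: np.ndarray,
    regions: list[PlantRegion],
    swath_m: float = SWATH_M,
    swath_px: int = VNIR_SWATH_PX,
) -> list[PlantTraits]:
    """Traits for every region; spectra are None for empty (missing) plants."""
    traits = []
    for region in regions:
        h_px, h_m = plant_height(mask, region, swath_m, swath_px)
        try:
            spectrum = plant_mean_spectrum(refl_cube, mask, region)
        except DetectionError:
            spectrum = None
        traits.append(
            PlantTraits(
                plant_id=region.plant_id,
                height_px=h_px,
                height_m=h_m,
                density=plant_density(mask, region),
                mean_spectrum=spectrum,
            )
        )
    return traits
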