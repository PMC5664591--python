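"""Dark-current removal and row-end cropping — the first steps applied to a raw cube.

Push-broom scanners have a dark-current signature that is unique to each
vertical detector pixel, so the dark reference is a per-row spectrum
(``dark[y, b]``) rather than a single vector.  Subtraction is clamped at zero:
negative intensities are unphysical and destabilise normalised-difference
indices downstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .hypercube import HyperCube, read_cube

__all__ = ["subtract_dark_current", "crop_row_ends", "load_dark_spectrum"]


def subtract_dark_current(cube: HyperCube, dark: np.ndarray) -> HyperCube:
    """Subtract a per-row dark spectrum, clamping at zero.

    Parameters
    ----------
    dark
        Array of shape ``(height, n_bands)``: one dark spectrum per vertical
        pixel of the scanner.
    """
    dark = np.asarray(dark, dtype=float)
    if dark.shape != (cube.height, cube.n_bands):
        raise ValueError(
            f"dark spectrum shape {dark.shape} does not match cube "
            f"(rows, bands) = {(cube.height, cube.n_bands)}"
        )
    out = cube.data.astype(float) - dark[:, None, :]
    np.clip(out, 0.0, None, out=out)
    return cube.with_data(out, kind="dark_corrected")


def crop_row_ends(cube: HyperCube, start_x: int, end_x: int) -> HyperCube:
    """Restrict the cube to columns ``[start_x, end_x)``.

    Replaces the field protocol's manual click-based cropping of non-target
    material at either end of a row with explicit, reproducible indices.
    """
    if not (0 <= start_x < end_x <= cube.width):
        raise ValueError(
            f"invalid crop interval [{start_x}, {end_x}) for width {cube.width}"
        )
    return cube.with_data(cube.data[:, start_x:end_x, :].copy())


def load_dark_spectrum(path, n_rows: int, n_bands: int) -> np.ndarray:
    """Load a dark reference from an ENVI raster (rows x 1 x bands) or CSV.

    The CSV layout is ``row,band,value`` with a header line.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table = np.loadtxt(path, delimiter=",", skiprows=1)
        dark = np.zeros((n_rows, n_bands))
        rows = table[:, 0].astype(int)
        bands = table[:, 1].astype(int)
        if rows.max() >= n_rows or bands.max() >= n_bands:
            raise FormatError(f"{path}: dark CSV indexes outside (rows, bands)")
        dark[rows, bands] = table[:, 2]
        return dark
    cube = read_cube(path)
    if cube.width != 1 or cube.height != n_rows or cube.n_bands != n_bands:
        raise FormatError(
            f"{path}: dark raster shape {(cube.height, cube.width, cube.n_bands)} "
            f"does not match expected ({n_rows}, 1, {n_bands})"
        )
    return cube.data[:, 0, :].astype(float)
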