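"""Band-window means and normalised-difference index images.

Every segmentation stage in the pipeline works on a single-channel image
derived from a handful of bands: NDVI in the VNIR, a 1375/1411 nm
water-absorption contrast for SWIR plant detection, and a 1620/1537 nm
contrast for SWIR white-reference detection.  All index images are float,
finite everywhere (0/0 pixels are set to 0, the "no contrast" value), and lie
in [-1, 1] for non-negative inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import HyperCube

__all__ = [
    "BandWindow",
    "band_mean",
    "ndvi",
    "normalized_difference",
    "RED_WINDOW",
    "NIR_WINDOW",
    "BLUE_REF_WINDOW",
    "PLANT_SWIR_WINDOWS",
    "WHITEREF_SWIR_WINDOWS",
]


@dataclass(frozen=True)
class BandWindow:
    """A selection of bands, either a wavelength range or n bands around a centre.

    Range mode selects every band whose centre lies in ``[lo_nm, hi_nm]``
    (endpoints inclusive).  Centred mode selects the ``n_bands`` bands whose
    centres are nearest ``centre_nm`` — scanners rarely have a band at the
    exact nominal wavelength.
    """

    mode: str
    lo_nm: float = 0.0
    hi_nm: float = 0.0
    centre_nm: float = 0.0
    n_bands: int = 1

    @classmethod
    def range(cls, lo_nm: float, hi_nm: float) -> "BandWindow":
        if not lo_nm < hi_nm:
            raise ValueError(f"range window needs lo < hi, got [{lo_nm}, {hi_nm}]")
        return cls(mode="range", lo_nm=lo_nm, hi_nm=hi_nm)

    @classmethod
    def centred(cls, centre_nm: float, n_bands: int = 3) -> "BandWindow":
        if n_bands < 1 or n_bands % 2 == 0:
            raise ValueError(f"n_bands must be odd and >= 1, got {n_bands}")
        return cls(mode="centred", centre_nm=centre_nm, n_bands=n_bands)

    def select(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Indices of the selected bands (sorted ascending)."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        if self.mode == "range":
            idx = np.flatnonzero((wl >= self.lo_nm) & (wl <= self.hi_nm))
            if idx.size == 0:
                raise ValueError(
                    f"no bands inside [{self.lo_nm}, {self.hi_nm}] nm "
                    f"(cube covers {wl[0]:.1f}-{wl[-1]:.1f} nm)"
                )
            return idx
        if not (wl[0] <= self.centre_nm <= wl[-1]):
            raise ValueError(
                f"centre {self.centre_nm} nm outside cube range "
                f"{wl[0]:.1f}-{wl[-1]:.1f} nm"
            )
        order = np.argsort(np.abs(wl - self.centre_nm), kind="stable")
        return np.sort(order[: self.n_bands])


# The fixed windows used by the pipeline, in nm.
RED_WINDOW = BandWindow.range(650.0, 680.0)
NIR_WINDOW = BandWindow.range(710.0, 740.0)
BLUE_REF_WINDOW = BandWindow.range(455.0, 480.0)
PLANT_SWIR_WINDOWS = (BandWindow.centred(1375.0, 3), BandWindow.centred(1411.0, 3))
WHITEREF_SWIR_WINDOWS = (BandWindow.centred(1620.0, 3), BandWindow.centred(1537.0, 3))


def band_mean(cube: HyperCube, window: BandWindow) -> np.ndarray:
    """Per-pixel arithmetic mean over the bands selected by ``window``."""
    idx = window.select(cube.wavelengths_nm)
    return cube.data[:, :, idx].mean(axis=2, dtype=float)


def normalized_difference(cube: HyperCube, w_a: BandWindow, w_b: BandWindow) -> np.ndarray:
    """(A - B) / (A + B) of two band-window means; 0/0 pixels map to 0."""
    a = band_mean(cube, w_a)
    b = band_mean(cube, w_b)
    num = a - b
    den = a + b
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den != 0)
    return out


def ndvi(cube: HyperCube) -> np.ndarray:
    """Normalised difference vegetation index (NIR - red)/(NIR + red).

    Red is the 650-680 nm band mean and NIR the 710-740 nm band mean; green
    vegetation scores high through the red-edge reflectance rise.
    """
    return normalized_difference(cube, NIR_WINDOW, RED_WINDOW)
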