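"""Splitting a row image into individual plant regions.

Plants in the trial rows are evenly pitched, so the per-column count of plant
pixels has one peak per plant and minima in the gaps.  Boundaries start at
midpoints between detected peaks, oversized gaps are subdivided to cover
plants the peak finder missed, the region count is reconciled with the known
number of plants per row, and every internal boundary is finally nudged to a
local minimum of the profile.  Each region also carries an analysis span with
10 % of the width shaved from each side, excluding canopy overlap between
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = ["PlantRegion", "column_profile", "find_plant_peaks", "split_row"]


@dataclass
class PlantRegion:
    """A half-open column interval assigned to one plant."""

    plant_id: int
    full_span: tuple[int, int]
    analysis_span: tuple[int, int]

    @property
    def width(self) -> int:
        return self.full_span[1] - self.full_span[0]


def column_profile(mask: np.ndarray) -> np.ndarray:
    """Number of plant pixels in each column."""
    return np.count_nonzero(np.asarray(mask, dtype=bool), axis=0)


def find_plant_peaks(profile: np.ndarray, expected_spacing_px: float) -> np.ndarray:
    """Peak columns of the smoothed profile, at least 0.8 x spacing apart.

    The profile is smoothed with a moving average of width 0.1 x spacing to
    stabilise peaks against cane-level texture; peaks are kept greedily in
    decreasing height order subject to the minimum distance (scipy's
    ``distance`` rule).  Returned sorted ascending.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty profile")
    if expected_spacing_px < 2:
        raise ValueError(f"expected_spacing_px must be >= 2, got {expected_spacing_px}")
    win = max(1, int(round(0.1 * expected_spacing_px)))
    smoothed = uniform_filter1d(profile, size=win, mode="nearest")
    distance = max(1, int(np.ceil(0.8 * expected_spacing_px)))
    peaks, _ = find_peaks(smoothed, distance=distance)
    return peaks


def _argmin_tie_median(values: np.ndarray, offset: int) -> int:
    """Index of the minimum; ties resolved to the median minimising index."""
    mins = np.flatnonzero(values == values.min())
    return int(mins[mins.size // 2]) + offset


def _region_totals(profile: np.ndarray, bounds: list[int]) -> np.ndarray:
    return np.array([profile[a:b].sum() for a, b in zip(bounds[:-1], bounds[1:])])


def split_row(
    profile: np.ndarray,
    n_expected: int,
    expected_spacing_px: float | None = None,
) -> list[PlantRegion]:
    """Partition ``[0, width)`` into exactly ``n_expected`` plant regions.

    Steps: peak finding; midpoint boundaries; subdivision of peak gaps larger
    than 1.5 x spacing into ``round(gap / spacing)`` equal parts; merge/split
    until the region count matches; local-minimum refinement of every internal
    boundary within +-0.25 x spacing; 10 % analysis-span crop per side.
    """
    profile = np.asarray(profile)
    width = profile.size
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    if width < n_expected:
        raise ValueError(f"image width {width} is narrower than {n_expected} plants")
    spacing = float(expected_spacing_px) if expected_spacing_px else width / n_expected
    spacing = max(spacing, 2.0)

    # 1-3: peaks, midpoints, gap subdivision.
    peaks = find_plant_peaks(profile, spacing)
    bounds: list[int] = [0]
    for p, q in zip(peaks[:-1], peaks[1:]):
        gap = q - p
        if gap > 1.5 * spacing:
            k = max(2, int(round(gap / spacing)))
            bounds.extend(int(round(p + gap * j / k)) for j in range(1, k))
        else:
            bounds.append(int(round((p + q) / 2)))
    bounds.append(width)
    bounds = sorted(set(b for b in bounds if 0 <= b <= width))

    # 4: reconcile the region count with the known plants-per-row.
    while len(bounds) - 1 > n_expected:
        totals = _region_totals(profile, bounds)
        i = int(np.argmin(totals))
        if i == 0:
            j = 1
        elif i == len(totals) - 1:
            j = i - 1
        else:
            j = i - 1 if totals[i - 1] <= totals[i + 1] else i + 1
        del bounds[max(i, j)]  # drop the boundary between regions i and j
    while len(bounds) - 1 < n_expected:
        widths = np.diff(bounds)
        i = int(np.argmax(widths))
        a, b = bounds[i], bounds[i + 1]
        if b - a < 2:
            raise ValueError("cannot split a single-column region further")
        cut = _argmin_tie_median(profile[a + 1 : b], a + 1)
        bounds.insert(i + 1, cut)

    # 5: nudge internal boundaries to a nearby profile minimum.
    search = max(1, int(round(0.25 * spacing)))
    for i in range(1, len(bounds) - 1):
        b = bounds[i]
        lo = max(bounds[i - 1] + 1, b - search)
        hi = min(bounds[i + 1] - 1, b + search)
        if lo > hi:
            continue
        window = profile[lo : hi + 1]
        # ties resolved toward the provisional boundary
        candidates = np.flatnonzero(window == window.min()) + lo
        bounds[i] = int(candidates[np.argmin(np.abs(candidates - b))])

    # 6: analysis span shaves 10 % of the region width per side.
    regions = []
    for pid, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        shave = int(round(0.1 * (b - a)))
        regions.append(
            PlantRegion(plant_id=pid, full_span=(a, b), analysis_span=(a + shave, b - shave))
        )
    return regions
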