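"""Minimum-cost seam finding across an image by dynamic programming.

A seam is one vertical position per column, continuous in the sense that
neighbouring columns differ by at most one row.  Seams are used to locate the
grass/background boundary below the plants and the two horizontal edges of the
white-reference tile.

Cost construction
-----------------
``vertical_gradient`` returns a signed finite-difference gradient along y,
*downward-positive* (an image brightening with increasing row index has a
positive gradient), rescaled so the maximum absolute gradient of the image is
1.  ``1 - g_y`` is therefore near zero along dark-above/bright-below edges.
Callers that need the opposite polarity (a bright-above/dark-below edge, such
as the lower edge of a bright tile) negate their image first.

Given a cost matrix ``C`` the minimiser solves the recurrence

    t(x, y) = C(x, y)                                         for x = 0
    t(x, y) = C(x, y) + min( t(x-1, y-1) + lambda_ver,
                             t(x-1, y),
                             t(x-1, y+1) + lambda_ver )       otherwise

with off-image rows at infinite cost; ``lambda_ver`` penalises vertical moves
so the seam stays close to horizontal where the evidence is weak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundaryPath",
    "vertical_gradient",
    "cost_grass_boundary",
    "cost_edge",
    "cost_edge_with_shape",
    "shape_function_from_edge",
    "min_cost_path",
    "DEFAULT_LAMBDA_VER",
    "DEFAULT_LAMBDA_DIST",
]

# Chosen so a full-strength gradient edge (cost drop of 1) always dominates a
# one-pixel vertical move; overridable through the pipeline config.
DEFAULT_LAMBDA_VER = 0.05
DEFAULT_LAMBDA_DIST = 0.01


@dataclass
class BoundaryPath:
    """A continuous left-to-right seam: one row index per column."""

    y_at: np.ndarray
    total_cost: float

    def __post_init__(self) -> None:
        self.y_at = np.asarray(self.y_at, dtype=int)
        if self.y_at.ndim != 1 or self.y_at.size == 0:
            raise ValueError("y_at must be a non-empty 1-D array")
        if self.y_at.size > 1 and np.abs(np.diff(self.y_at)).max() > 1:
            raise ValueError("path violates continuity |dy| <= 1")

    @property
    def width(self) -> int:
        return self.y_at.size


def vertical_gradient(img: np.ndarray) -> np.ndarray:
    """Signed downward-positive vertical gradient, rescaled to [-1, 1].

    Central differences in the interior, one-sided at the top/bottom rows.
    A constant image maps to all zeros.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2:
        raise ValueError(f"need a 2-D image with height >= 2, got shape {img.shape}")
    g = np.gradient(img, axis=0)
    peak = np.abs(g).max()
    if peak > 0:
        g = g / peak
    return g


def cost_grass_boundary(ndvi_img: np.ndarray) -> np.ndarray:
    """Cost ``exp(-I(x)) * (1 - g_y)`` for the grass/background boundary.

    ``I(x)`` is the column mean of the NDVI image; the exponential damping
    keeps the seam cheap to traverse where dense plants hide the boundary.
    """
    ndvi_img = np.asarray(ndvi_img, dtype=float)
    g = vertical_gradient(ndvi_img)
    col_mean = ndvi_img.mean(axis=0)
    return np.exp(-col_mean)[None, :] * (1.0 - g)


def cost_edge(img: np.ndarray) -> np.ndarray:
    """Plain edge cost ``1 - g_y`` (no brightness damping)."""
    return 1.0 - vertical_gradient(img)


def cost_edge_with_shape(img: np.ndarray, d: np.ndarray, lambda_dist: float) -> np.ndarray:
    """Edge cost with a distance penalty: ``1 - g_y + lambda_dist * d``."""
    if lambda_dist < 0:
        raise ValueError("lambda_dist must be >= 0")
    d = np.asarray(d, dtype=float)
    img = np.asarray(img, dtype=float)
    if d.shape != img.shape:
        raise ValueError(f"shape function {d.shape} does not match image {img.shape}")
    return cost_edge(img) + lambda_dist * d


def shape_function_from_edge(
    bottom: BoundaryPath, expected_width: int, height: int
) -> np.ndarray:
    """Distance penalty favouring an edge ``expected_width`` rows above ``bottom``.

    ``d[y, x] = |(bottom.y_at[x] - expected_width) - y|`` — a per-column V with
    its vertex at the expected location of the opposite edge.
    """
    if expected_width < 1:
        raise ValueError("expected_width must be >= 1")
    expected = bottom.y_at - expected_width
    if np.all(expected < 0):
        raise ValueError(
            f"expected edge (bottom - {expected_width}) lies above the image "
            "in every column"
        )
    rows = np.arange(height)[:, None]
    return np.abs(expected[None, :] - rows).astype(float)


def min_cost_path(C: np.ndarray, lambda_ver: float) -> BoundaryPath:
    """Minimum-cost continuous seam across ``C`` (shape ``(height, width)``).

    Ties are broken deterministically: a straight move beats moving up from
    below, which beats moving down from above; the final column picks the
    smallest row among minima.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or min(C.shape) < 1:
        raise ValueError(f"cost matrix must be 2-D and non-empty, got shape {C.shape}")
    if lambda_ver < 0:
        raise ValueError("lambda_ver must be >= 0")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix must be finite")
    height, width = C.shape

    t = C[:, 0].astype(float).copy()
    back = np.zeros((height, width), dtype=np.int8)  # offset to previous row
    inf = np.inf
    for x in range(1, width):
        from_same = t
        from_below = np.concatenate([t[1:], [inf]]) + lambda_ver  # prev row y+1
        from_above = np.concatenate([[inf], t[:-1]]) + lambda_ver  # prev row y-1
        stacked = np.stack([from_same, from_below, from_above])
        choice = np.argmin(stacked, axis=0)  # first minimum = preference order
        t = stacked[choice, np.arange(height)] + C[:, x]
        back[:, x] = np.where(choice == 0, 0, np.where(choice == 1, 1, -1))

    y = int(np.argmin(t))  # first occurrence = smallest row on ties
    total = float(t[y])
    path = np.empty(width, dtype=int)
    path[-1] = y
    for x in range(width - 1, 0, -1):
        y = y + int(back[y, x])
        path[x - 1] = y
    return BoundaryPath(y_at=path, total_cost=total)
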