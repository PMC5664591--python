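"""Seeded synthetic hyperspectral row scenes with full ground truth.

The simulator renders the lateral-view field geometry the pipeline was built
for: a row of plant canopies in front of a cardboard background, a grass
strip along the bottom, a horizontal white-reference tile strip, occluding
vertical posts, smooth column-wise illumination drift, per-row dark current,
and additive Gaussian sensor noise.  Both scanner cubes (VNIR and SWIR) are
rendered from the same scene description on their own spatial/spectral grids.

Endmember reflectances are hand-built piecewise-linear curves: a leaf with a
red edge in the VNIR and a depressed 1411 nm water-absorption band in the
SWIR, grass resembling the leaf, a spectrally flat cardboard and tile, and a
dull post.  They carry exactly the contrasts every index in the pipeline
relies on, with no external spectral library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError
from .hypercube import HyperCube

__all__ = [
    "SceneConfig",
    "Endmembers",
    "ScannerTruth",
    "PlantTruth",
    "GroundTruth",
    "default_endmembers",
    "generate_scene",
    "LABELS",
]

#: Label codes in the ground-truth label maps.
LABELS = {"cardboard": 0, "grass": 1, "tile": 2, "post": 3, "plant": 4}
_ORDER = ("cardboard", "grass", "tile", "post", "plant")

# Piecewise-linear reflectance control points (wavelength nm, reflectance).
_CONTROL: dict[str, list[tuple[float, float]]] = {
    "leaf": [
        (400, 0.05), (500, 0.06), (550, 0.12), (620, 0.07), (650, 0.05),
        (680, 0.05), (700, 0.20), (710, 0.35), (740, 0.52), (780, 0.55),
        (900, 0.55), (1100, 0.54), (1300, 0.45), (1375, 0.38), (1411, 0.16),
        (1450, 0.10), (1537, 0.27), (1620, 0.37), (1700, 0.40), (1850, 0.15),
        (1940, 0.07), (2100, 0.22), (2200, 0.24), (2506, 0.12),
    ],
    "cardboard": [
        (400, 0.25), (896, 0.25), (1375, 0.248), (1411, 0.248),
        (1537, 0.25), (1620, 0.27), (2506, 0.28),
    ],
    "post": [
        (400, 0.12), (650, 0.15), (680, 0.16), (710, 0.17), (740, 0.18),
        (896, 0.20), (1537, 0.19), (1620, 0.20), (2506, 0.21),
    ],
}
_GRASS_SCALE = 0.85  # grass resembles the leaf, slightly darker


@dataclass
class SceneConfig:
    """Scene parameters; defaults follow the scanner and trial geometry.

    Heights and band counts default to the two scanners (402 rows / 178 bands
    over 400-896 nm; 378 rows / 278 bands over 895-2506 nm); a frame holds 12
    plants by default at a pitch of 100 columns per plant.
    """

    n_plants: int = 12
    plant_spacing_px: int = 100
    width: int | None = None
    vnir_height: int = 402
    swir_height: int = 378
    vnir_bands: int = 178
    swir_bands: int = 278

    plant_height_frac: tuple[float, float] = (0.55, 0.95)  # of available band
    plant_width_frac: tuple[float, float] = (0.5, 0.8)  # of plant pitch
    missing_plant_probability: float = 0.0
    force_missing: tuple[int, ...] = ()

    grass_frac: float = 0.15
    grass_wobble_frac: float = 0.01
    tile_top_frac: float = 0.08
    tile_bottom_frac: float = 0.22
    tile_reflectance: float = 0.95
    n_posts: int = 3
    post_width_px: int = 4

    illumination_drift_amplitude: float = 0.1
    drift_profile: str = "random"  # or "linear"
    noise_sd: float = 0.005
    swir_dark_amplitude: float = 0.02
    vnir_dark_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_plants", "plant_spacing_px", "vnir_height", "swir_height",
                     "vnir_bands", "swir_bands"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_plant_probability <= 1.0:
            raise ConfigError("missing_plant_probability must be in [0, 1]")
        if not 0.0 < self.tile_top_frac < self.tile_bottom_frac:
            raise ConfigError("tile span must satisfy 0 < top < bottom")
        if self.tile_bottom_frac >= 1.0 - self.grass_frac:
            raise ConfigError("tile span overlaps the grass strip")
        if self.drift_profile not in ("random", "linear"):
            raise ConfigError(f"unknown drift_profile {self.drift_profile!r}")
        if self.noise_sd < 0 or self.illumination_drift_amplitude < 0:
            raise ConfigError("noise_sd and drift amplitude must be >= 0")

    @property
    def effective_width(self) -> int:
        return self.width if self.width else self.n_plants * self.plant_spacing_px


@dataclass
class Endmembers:
    """Reflectance of the five scene materials on both scanner grids."""

    names: tuple[str, ...]
    vnir_wavelengths: np.ndarray
    swir_wavelengths: np.ndarray
    vnir: np.ndarray  # (5, vnir bands), rows ordered by LABELS
    swir: np.ndarray  # (5, swir bands)

    def vnir_of(self, name: str) -> np.ndarray:
        return self.vnir[LABELS[name]]

    def swir_of(self, name: str) -> np.ndarray:
        return self.swir[LABELS[name]]


def _curve(name: str, wl: np.ndarray, tile_reflectance: float) -> np.ndarray:
    if name == "tile":
        return np.full_like(wl, tile_reflectance, dtype=float)
    if name == "grass":
        pts = _CONTROL["leaf"]
        return _GRASS_SCALE * np.interp(wl, [p[0] for p in pts], [p[1] for p in pts])
    key = "leaf" if name == "plant" else name
    pts = _CONTROL[key]
    return np.interp(wl, [p[0] for p in pts], [p[1] for p in pts])


def default_endmembers(
    vnir_wavelengths: np.ndarray | None = None,
    swir_wavelengths: np.ndarray | None = None,
    tile_reflectance: float = 0.95,
) -> Endmembers:
    """The five named reflectance curves on both scanners' wavelength grids."""
    vw = (np.linspace(400.0, 896.0, 178) if vnir_wavelengths is None
          else np.asarray(vnir_wavelengths, dtype=float))
    sw = (np.linspace(895.0, 2506.0, 278) if swir_wavelengths is None
          else np.asarray(swir_wavelengths, dtype=float))
    vnir = np.stack([_curve(n, vw, tile_reflectance) for n in _ORDER])
    swir = np.stack([_curve(n, sw, tile_reflectance) for n in _ORDER])
    return Endmembers(names=_ORDER, vnir_wavelengths=vw, swir_wavelengths=sw,
                      vnir=vnir, swir=swir)


@dataclass
class PlantTruth:
    index: int
    centre_x: float
    span: tuple[int, int]  # rendered column extent, half-open
    missing: bool


@dataclass
class ScannerTruth:
    labels: np.ndarray  # (H, W) int8 label map
    plant_ids: np.ndarray  # (H, W) int32, -1 where not plant
    boundary_row: np.ndarray  # (W,) last background row above the grass
    dark: np.ndarray  # (H, bands) injected dark current

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    @property
    def plant_mask(self) -> np.ndarray:
        return self.mask("plant")

    @property
    def tile_mask(self) -> np.ndarray:
        return self.mask("tile")

    @property
    def grass_mask(self) -> np.ndarray:
        return self.mask("grass")

    @property
    def post_mask(self) -> np.ndarray:
        return self.mask("post")


@dataclass
class GroundTruth:
    vnir: ScannerTruth
    swir: ScannerTruth
    plants: list[PlantTruth]
    illumination: np.ndarray  # (W,) shared column drift
    endmembers: Endmembers
    config: SceneConfig = field(repr=False)


def _plant_blobs(rng, centre: float, width: float, top_frac: float,
                 base_frac: float) -> list[tuple[float, float, float, float]]:
    """Ellipses (cx, cy_frac, rx, ry_frac) for one plant: a cane plus canopy blobs."""
    h = base_frac - top_frac
    blobs = [(centre, base_frac - h / 2, max(1.2, 0.02 * width), h / 2)]  # cane
    for level, rx_scale in ((0.35, 0.50), (0.60, 0.45), (0.85, 0.35)):
        cy = base_frac - level * h
        cx = centre + rng.normal(0.0, 0.04 * width)
        blobs.append((cx, cy, rx_scale * width / 2 * rng.uniform(0.8, 1.1),
                      max(0.35 * h / 2, 0.08 * h) * rng.uniform(0.8, 1.2)))
    return blobs


def _rasterize(cfg: SceneConfig, height: int, geometry: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label map, plant-id map and boundary row for one scanner grid."""
    width = cfg.effective_width
    labels = np.full((height, width), LABELS["cardboard"], dtype=np.int8)
    plant_ids = np.full((height, width), -1, dtype=np.int32)

    grass_top = np.clip(np.round(geometry["grass_top_frac"] * height).astype(int), 1, height - 1)
    rows = np.arange(height)[:, None]
    labels[rows >= grass_top[None, :]] = LABELS["grass"]

    t0 = int(round(cfg.tile_top_frac * height))
    t1 = int(round(cfg.tile_bottom_frac * height)) - 1
    labels[t0 : t1 + 1, :] = LABELS["tile"]

    for x0 in geometry["post_x"]:
        labels[:, x0 : x0 + cfg.post_width_px] = LABELS["post"]

    yy = np.arange(height, dtype=float)
    plant_y_min = t1 + 2  # keep canopies clear of the tile strip
    for plant in geometry["plants"]:
        if plant["missing"]:
            continue
        for cx, cy_frac, rx, ry_frac in plant["blobs"]:
            cy, ry = cy_frac * height, max(ry_frac * height, 1.0)
            x_lo = max(0, int(np.floor(cx - rx)))
            x_hi = min(width, int(np.ceil(cx + rx)) + 1)
            y_lo = max(plant_y_min, int(np.floor(cy - ry)))
            y_hi = min(height, int(np.ceil(cy + ry)) + 1)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            xs = np.arange(x_lo, x_hi, dtype=float)
            inside = (((xs[None, :] - cx) / max(rx, 1e-9)) ** 2
                      + ((yy[y_lo:y_hi, None] - cy) / ry) ** 2) <= 1.0
            patch = labels[y_lo:y_hi, x_lo:x_hi]
            patch[inside] = LABELS["plant"]
            idp = plant_ids[y_lo:y_hi, x_lo:x_hi]
            idp[inside] = plant["index"]

    boundary_row = grass_top - 1
    return labels, plant_ids, boundary_row


def _dark_field(rng, amplitude: float, height: int, bands: int) -> np.ndarray:
    if amplitude <= 0:
        return np.zeros((height, bands))
    row_profile = uniform_filter1d(rng.uniform(0.0, 1.0, height), size=9, mode="nearest")
    band_profile = uniform_filter1d(rng.uniform(0.0, 1.0, bands), size=9, mode="nearest")
    return amplitude * np.outer(0.5 + 0.5 * row_profile, 0.5 + 0.5 * band_profile)


def _render_cube(rng, cfg: SceneConfig, labels: np.ndarray, refl_table: np.ndarray,
                 wavelengths: np.ndarray, illum: np.ndarray, dark: np.ndarray) -> HyperCube:
    data = refl_table.astype(np.float32)[labels]  # (H, W, B)
    data *= illum.astype(np.float32)[None, :, None]
    data += dark.astype(np.float32)[:, None, :]
    if cfg.noise_sd > 0:
        data += rng.standard_normal(data.shape, dtype=np.float32) * np.float32(cfg.noise_sd)
    np.clip(data, 0.0, None, out=data)
    return HyperCube(data, wavelengths, kind="raw")


def generate_scene(cfg: SceneConfig) -> tuple[HyperCube, HyperCube, GroundTruth]:
    """Render the VNIR cube, the SWIR cube and the full ground truth.

    Deterministic for a fixed config (including the seed): calling twice
    returns bit-identical cubes.
    """
    rng = np.random.default_rng(cfg.seed)
    width = cfg.effective_width
    spacing = width / cfg.n_plants

    # Column-wise illumination drift: a smooth low-order polynomial shared by
    # every scene element; sectioned normalisation is meant to cancel it.
    u = np.linspace(-1.0, 1.0, width)
    if cfg.drift_profile == "linear":
        p = u
    else:
        c = rng.normal(0.0, 1.0, 3)
        p = c[0] + c[1] * u + c[2] * u**2
        peak = np.abs(p).max()
        if peak > 0:
            p = p / peak
    illum = np.clip(1.0 + cfg.illumination_drift_amplitude * p, 0.2, None)

    grass_top_mean = 1.0 - cfg.grass_frac
    phase = rng.uniform(0, 2 * np.pi)
    cycles = rng.uniform(1.0, 2.5)
    grass_top_frac = grass_top_mean + cfg.grass_wobble_frac * np.sin(
        2 * np.pi * cycles * np.arange(width) / width + phase
    )

    top_limit = cfg.tile_bottom_frac + 0.03
    base_frac = grass_top_mean - cfg.grass_wobble_frac - 0.01
    max_h = base_frac - top_limit
    if max_h <= 0:
        raise ConfigError("no vertical room for plants between tile and grass")

    plants = []
    for i in range(cfg.n_plants):
        centre = (i + 0.5) * spacing + np.clip(
            rng.normal(0.0, 0.04 * spacing), -0.15 * spacing, 0.15 * spacing
        )
        w = rng.uniform(*cfg.plant_width_frac) * spacing
        h_frac = rng.uniform(*cfg.plant_height_frac) * max_h
        missing = bool(rng.uniform() < cfg.missing_plant_probability) or i in cfg.force_missing
        blobs = _plant_blobs(rng, centre, w, base_frac - h_frac, base_frac)
        plants.append({"index": i, "centre": centre, "missing": missing, "blobs": blobs})

    post_x = np.sort(rng.integers(0, max(1, width - cfg.post_width_px), cfg.n_posts))
    geometry = {"grass_top_frac": grass_top_frac, "plants": plants, "post_x": post_x}

    members = default_endmembers(
        np.linspace(400.0, 896.0, cfg.vnir_bands),
        np.linspace(895.0, 2506.0, cfg.swir_bands),
        tile_reflectance=cfg.tile_reflectance,
    )

    truth_scanners = {}
    cubes = {}
    for scanner, height, table, wl, dark_amp in (
        ("vnir", cfg.vnir_height, members.vnir, members.vnir_wavelengths,
         cfg.vnir_dark_amplitude),
        ("swir", cfg.swir_height, members.swir, members.swir_wavelengths,
         cfg.swir_dark_amplitude),
    ):
        labels, plant_ids, boundary_row = _rasterize(cfg, height, geometry)
        dark = _dark_field(rng, dark_amp, height, wl.size)
        cubes[scanner] = _render_cube(rng, cfg, labels, table, wl, illum, dark)
        truth_scanners[scanner] = ScannerTruth(
            labels=labels, plant_ids=plant_ids, boundary_row=boundary_row, dark=dark
        )

    plant_truths = []
    for plant in plants:
        cols = np.flatnonzero((truth_scanners["vnir"].plant_ids == plant["index"]).any(axis=0))
        span = (int(cols[0]), int(cols[-1]) + 1) if cols.size else (
            int(round(plant["centre"])), int(round(plant["centre"]))
        )
        plant_truths.append(
            PlantTruth(index=plant["index"], centre_x=float(plant["centre"]),
                       span=span, missing=plant["missing"])
        )

    truth = GroundTruth(
        vnir=truth_scanners["vnir"],
        swir=truth_scanners["swir"],
        plants=plant_truths,
        illumination=illum,
        endmembers=members,
        config=cfg,
    )
    return cubes["vnir"], cubes["swir"], truth
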