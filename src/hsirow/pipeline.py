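"""Full per-row workflow: preprocess -> detect -> whiteref -> normalise -> split -> extract.

The two scanners are processed independently (their images are never
registered); each produces a plant mask, a white-reference panel, a
reflectance cube, plant regions and per-plant traits/spectra.  A JSON
manifest records every effective parameter, per-stage timings and warnings,
so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .errors import DetectionError, HsirowError
from .extract import extract_traits, normalize_reflectance
from .hypercube import HyperCube, read_cube, write_cube, write_mask
from .preprocess import crop_row_ends, load_dark_spectrum, subtract_dark_current
from .segment import SegmentationParams, detect_plants_swir, detect_plants_vnir
from .split import column_profile, split_row
from .whiteref import detect_whiteref_swir, detect_whiteref_vnir

__all__ = ["run_row", "RowResult"]


@dataclass
class RowResult:
    out_dir: Path
    manifest: dict


def _write_regions_csv(path: Path, regions) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plant_id", "full_start", "full_end", "analysis_start", "analysis_end"])
        for r in regions:
            writer.writerow([r.plant_id, *r.full_span, *r.analysis_span])


def _write_traits_csv(path: Path, traits) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plant_id", "height_px", "height_m", "density"])
        for t in traits:
            writer.writerow([t.plant_id, t.height_px, f"{t.height_m:.6f}", f"{t.density:.6f}"])


def _write_spectra_csv(path: Path, traits, wavelengths: np.ndarray) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plant_id"] + [f"{w:.2f}" for w in wavelengths])
        for t in traits:
            if t.mean_spectrum is None:
                continue
            writer.writerow([t.plant_id] + [f"{v:.6g}" for v in t.mean_spectrum])


def _process_scanner(
    scanner: str,
    cube: HyperCube,
    cfg: PipelineConfig,
    out_dir: Path,
    timings: dict,
    warnings: list,
) -> dict:
    seg = SegmentationParams(
        ndvi_threshold=cfg.ndvi_threshold,
        swir_bottom_crop_fraction=cfg.swir_bottom_crop_fraction,
    )

    tic = time.perf_counter()
    if scanner == "vnir":
        mask = detect_plants_vnir(cube, seg, lambda_ver=cfg.lambda_ver)
    else:
        mask = detect_plants_swir(cube, seg)
    timings[f"{scanner}.segment"] = time.perf_counter() - tic

    tic = time.perf_counter()
    if scanner == "vnir":
        panel = detect_whiteref_vnir(
            cube,
            expected_width=cfg.expected_tile_width_px,
            lambda_ver=cfg.lambda_ver,
            lambda_dist=cfg.lambda_dist,
            darkness_fraction=cfg.whiteref_darkness_fraction,
            variance_factor=cfg.whiteref_variance_factor,
        )
    else:
        panel = detect_whiteref_swir(cube)
    timings[f"{scanner}.whiteref"] = time.perf_counter() - tic

    tic = time.perf_counter()
    refl = normalize_reflectance(cube, panel, section_width_px=cfg.section_width_px)
    timings[f"{scanner}.normalize"] = time.perf_counter() - tic

    tic = time.perf_counter()
    spacing = cfg.expected_spacing_px or cube.width / cfg.n_plants
    regions = split_row(column_profile(mask), cfg.n_plants, spacing)
    timings[f"{scanner}.split"] = time.perf_counter() - tic

    swath_px = cfg.vnir_swath_px if scanner == "vnir" else cfg.swir_swath_px
    traits = extract_traits(refl, mask, regions, swath_m=cfg.swath_m, swath_px=swath_px)
    empty = [t.plant_id for t in traits if t.mean_spectrum is None]
    if empty:
        warnings.append(f"{scanner}: no plant pixels for plant(s) {empty}")

    write_mask(mask, out_dir / f"{scanner}_plant_mask.png")
    write_mask(panel.mask, out_dir / f"{scanner}_whiteref_mask.png")
    write_cube(refl, out_dir / f"{scanner}_reflectance.bil")
    _write_regions_csv(out_dir / f"{scanner}_regions.csv", regions)
    _write_traits_csv(out_dir / f"{scanner}_traits.csv", traits)
    _write_spectra_csv(out_dir / f"{scanner}_spectra.csv", traits, cube.wavelengths_nm)

    return {
        "n_regions": len(regions),
        "n_valid_whiteref_columns": int(panel.column_valid.sum()),
        "n_plant_pixels": int(np.count_nonzero(mask)),
        "plants_without_pixels": empty,
    }


def run_row(
    vnir_path,
    swir_path,
    cfg: PipelineConfig,
    out_dir,
    swir_dark_path=None,
) -> RowResult:
    """Run the full pipeline on one row's VNIR and SWIR cubes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings: list[str] = []
    stages: dict[str, dict] = {}

    for scanner, path in (("vnir", vnir_path), ("swir", swir_path)):
        try:
            tic = time.perf_counter()
            cube = read_cube(path)
            timings[f"{scanner}.read"] = time.perf_counter() - tic
            if cfg.crop_start is not None:
                cube = crop_row_ends(cube, cfg.crop_start, cfg.crop_end)
            if scanner == "swir" and swir_dark_path is not None:
                dark = load_dark_spectrum(swir_dark_path, cube.height, cube.n_bands)
                cube = subtract_dark_current(cube, dark)
            stages[scanner] = _process_scanner(scanner, cube, cfg, out_dir, timings, warnings)
        except DetectionError as exc:
            raise DetectionError(f"[{scanner}] {exc}") from exc
        except HsirowError as exc:
            raise type(exc)(f"[{scanner}] {exc}") from exc

    manifest = {
        "hsirow_version": __version__,
        "config": cfg.to_dict(),
        "inputs": {"vnir": str(vnir_path), "swir": str(swir_path),
                   "swir_dark": str(swir_dark_path) if swir_dark_path else None},
        "stages": stages,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "warnings": warnings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return RowResult(out_dir=out_dir, manifest=manifest)
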