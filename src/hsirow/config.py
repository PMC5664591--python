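"""Pipeline configuration: every tunable of the row workflow with defaults.

Configs load from a flat YAML mapping; unknown keys are rejected by name so a
typo in a field campaign's config file fails loudly rather than silently
running with a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # plant detection
    ndvi_threshold: float = 0.3
    swir_bottom_crop_fraction: float = 0.15
    # seam finding
    lambda_ver: float = 0.05
    lambda_dist: float = 0.01
    expected_tile_width_px: int = 56  # tile height in rows, known a priori
    # white-reference occlusion filtering
    whiteref_variance_factor: float = 2.0
    whiteref_darkness_fraction: float = 0.8
    # reflectance normalisation
    section_width_px: int = 100
    # splitting
    n_plants: int = 12
    expected_spacing_px: float | None = None
    # trait calibration (swath metres over vertical pixels, per scanner)
    swath_m: float = 1.2
    vnir_swath_px: int = 402
    swir_swath_px: int = 378
    # row-end cropping (None = no crop)
    crop_start: int | None = None
    crop_end: int | None = None

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ConfigError(f"n_plants must be >= 1, got {self.n_plants}")
        if not -1.0 < self.ndvi_threshold < 1.0:
            raise ConfigError("ndvi_threshold must be in (-1, 1)")
        if not 0.0 <= self.swir_bottom_crop_fraction < 1.0:
            raise ConfigError("swir_bottom_crop_fraction must be in [0, 1)")
        if self.lambda_ver < 0 or self.lambda_dist < 0:
            raise ConfigError("lambda_ver and lambda_dist must be >= 0")
        if self.expected_tile_width_px < 1:
            raise ConfigError("expected_tile_width_px must be >= 1")
        if self.section_width_px < 1:
            raise ConfigError("section_width_px must be >= 1")
        if self.expected_spacing_px is not None and self.expected_spacing_px < 2:
            raise ConfigError("expected_spacing_px must be >= 2")
        if (self.crop_start is None) != (self.crop_end is None):
            raise ConfigError("crop_start and crop_end must be given together")
        for name in ("swath_m", "vnir_swath_px", "swir_swath_px"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        return cls.from_mapping(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
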