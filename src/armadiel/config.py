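"""YAML-backed run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError
from .models import DEFAULT_FIXED_TERMS, DEFAULT_TIMING_TERMS
from .solar import GeoPoint

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs: paths, parameters and model spec."""

    photos: Path
    deployments: Path
    landcover_raster: Path
    sound_raster: Path
    output_dir: Path
    species_filter: str = "Dasypus novemcinctus"
    gap_minutes: float = 5.0
    buffer_radius_m: float = 500.0
    anchor_latitude: float = 36.066166
    anchor_longitude: float = -94.157889
    utc_offset_minutes: int = -360
    forest_codes: tuple[float, ...] = (1.0,)
    developed_codes: tuple[float, ...] = (2.0, 3.0)
    fixed_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    timing_terms: tuple[str, ...] = DEFAULT_TIMING_TERMS
    quad_points: int = 15
    per_date_classification: bool = False
    nocturnality_threshold_pct: float = 95.0
    seed: int = 0
    force: bool = False

    def __post_init__(self) -> None:
        for name in ("photos", "deployments", "landcover_raster", "sound_raster", "output_dir"):
            setattr(self, name, Path(getattr(self, name)))
        for name in ("forest_codes", "developed_codes", "fixed_terms", "timing_terms"):
            setattr(self, name, tuple(getattr(self, name)))
        if self.gap_minutes <= 0:
            raise ValidationError("gap_minutes must be positive")
        if self.buffer_radius_m <= 0:
            raise ValidationError("buffer_radius_m must be positive")
        if self.quad_points < 1:
            raise ValidationError("quad_points must be >= 1")

    @property
    def anchor(self) -> GeoPoint:
        return GeoPoint(self.anchor_latitude, self.anchor_longitude)

    def require_inputs(self) -> None:
        missing = [
            str(p)
            for p in (self.photos, self.deployments, self.landcover_raster, self.sound_raster)
            if not Path(p).exists()
        ]
        if missing:
            raise ValidationError(f"missing input files: {missing}")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML run config; keyword overrides win over file values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
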