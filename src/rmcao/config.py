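"""Pipeline configuration: YAML-addressable, schema-validated before compute."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Schema violation, reported with field paths before any compute starts."""


class GridBlock(BaseModel):
    n: int = 64
    pitch_um: float = 0.08
    wavelength_um: float = 0.515
    na: float = 0.8
    n_medium: float = 1.33


class SceneBlock(BaseModel):
    preset: Literal["single_point", "point_grid", "filaments", "speckle_object"] = (
        "filaments"
    )


class AberrationBlock(BaseModel):
    kind: Literal["random", "zernike", "none"] = "random"
    rms_rad: float = Field(1.5, ge=0.0)
    corr_length: float = Field(0.25, gt=0.0)
    zernike: Optional[dict[int, float]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "zernike" and not self.zernike:
            raise ValueError("zernike aberration requires a 'zernike' coefficient map")
        return self


class IlluminationBlock(BaseModel):
    n_target: int = Field(100, ge=1)
    pattern: Literal["spiral", "grid"] = "spiral"


class InterferogramBlock(BaseModel):
    """Optional raw-acquisition emulation (synthesize + demodulate frames)."""

    k_dg_over_kna: float = Field(5.0, gt=2.0)  # |k_DG| in units of k0*NA
    e_r0: float = Field(1.0, gt=0.0)
    camera_noise_var: float = Field(0.0, ge=0.0)


class NoiseBlock(BaseModel):
    gamma: float = Field(0.0, ge=0.0)


class CorrectionBlock(BaseModel):
    tol: float = Field(1e-3, gt=0.0)
    max_iter: int = Field(30, ge=1)
    tile_rows: int = Field(1, ge=1)
    tile_cols: int = Field(1, ge=1)
    overlap: float = Field(0.25, ge=0.0, lt=0.5)


class VolumeBlock(BaseModel):
    enabled: bool = False
    z_min_um: float = -2.0
    z_max_um: float = 2.0
    fine_step_um: float = Field(0.5, gt=0.0)


class PipelineConfig(BaseModel):
    grid: GridBlock = GridBlock()
    scene: SceneBlock = SceneBlock()
    aberration_in: AberrationBlock = AberrationBlock()
    aberration_out: AberrationBlock = AberrationBlock()
    illumination: IlluminationBlock = IlluminationBlock()
    interferogram: Optional[InterferogramBlock] = None
    noise: NoiseBlock = NoiseBlock()
    correction: CorrectionBlock = CorrectionBlock()
    volume: VolumeBlock = VolumeBlock()
    seed: int = 0
    out_dir: str = "runs"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path: str | Path | None = None, data: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; schema errors name the field paths."""
    if (path is None) == (data is None):
        raise ConfigError("provide exactly one of path or data")
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as e:
        paths = "; ".join(
            "/".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in e.errors()
        )
        raise ConfigError(f"invalid pipeline config: {paths}") from e
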