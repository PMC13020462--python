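"""Validated run configuration (YAML) for the simulation pipeline.

A :class:`RunConfig` collects thorax geometry parameters, electrode layout,
fluid condition, electrical solve settings and the protocol grid.  Unknown
keys are rejected, defaults reproduce the headline study conditions (10 kHz,
1 mA, 8 cm separation, right side, normal refinement), and a write-then-read
round trip is the identity.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .fem import SolveSpec
from .thorax import DEFAULT_CORNERS, ThoraxParams

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThoraxConfig(_Strict):
    torso_semi_axis_x: float = Field(ThoraxParams.torso_semi_axis_x, gt=0)
    torso_semi_axis_y: float = Field(ThoraxParams.torso_semi_axis_y, gt=0)
    torso_height: float = Field(ThoraxParams.torso_height, gt=0)
    lung_semi_axes: tuple[float, float, float] = ThoraxParams.lung_semi_axes
    lung_center_abs_x: float = ThoraxParams.lung_center_abs_x
    lung_center_y: float = ThoraxParams.lung_center_y
    lung_center_z: float = ThoraxParams.lung_center_z
    lung_base_height: float = Field(ThoraxParams.lung_base_height, gt=0)
    lung_volume_fraction_right: float = Field(
        ThoraxParams.lung_volume_fraction_right, gt=0, lt=1)
    heart_center: tuple[float, float, float] = ThoraxParams.heart_center
    heart_semi_axes: tuple[float, float, float] = ThoraxParams.heart_semi_axes
    ribs_enabled: bool = ThoraxParams.ribs_enabled
    rib_count_pairs: int = Field(ThoraxParams.rib_count_pairs, ge=0)
    rib_cross_section_radius: float = Field(
        ThoraxParams.rib_cross_section_radius, gt=0)
    airways_enabled: bool = ThoraxParams.airways_enabled
    target_thorax_volume: float = Field(
        ThoraxParams.target_thorax_volume, gt=0)
    target_lung_volume_total: float = Field(
        ThoraxParams.target_lung_volume_total, gt=0)

    def to_params(self) -> ThoraxParams:
        return ThoraxParams(**{k: (tuple(v) if isinstance(v, (list, tuple))
                                   else v)
                               for k, v in self.model_dump().items()})


class ElectrodeConfig(_Strict):
    side: Literal["left", "right"] = "right"
    separation: float = Field(0.08, gt=0)
    diameter: float = Field(0.01, gt=0)
    vertical_offset: float = 0.0
    corner_assignment: dict[str, str] = dict(DEFAULT_CORNERS)


class FluidConfig(_Strict):
    side: Literal["left", "right"] = "right"
    target_volume_m3: float = Field(0.0, ge=0)


class SolveConfig(_Strict):
    frequency_Hz: float = Field(10e3, gt=0)
    current_A: float = Field(1e-3, gt=0)
    mode: Literal["real", "complex"] = "real"
    solver: Literal["auto", "direct", "iterative"] = "auto"
    rel_tolerance: float = Field(1e-10, gt=0, le=1e-2)

    def to_spec(self) -> SolveSpec:
        return SolveSpec(frequency=self.frequency_Hz, I0=self.current_A,
                         mode=self.mode, solver=self.solver,
                         rel_tolerance=self.rel_tolerance)


class ProtocolConfig(_Strict):
    refinement: Literal["coarser", "coarse", "normal", "fine"] = "normal"
    offsets_m: list[float] = Field(
        default_factory=lambda: [0.0, 0.02, 0.04, 0.06, 0.08, 0.10])
    volumes_m3: list[float] = Field(
        default_factory=lambda: [0.0, 0.134e-3, 0.268e-3, 0.402e-3,
                                 0.536e-3, 0.670e-3])
    frequencies_Hz: list[float] = Field(
        default_factory=lambda: [5e3, 10e3, 50e3, 100e3, 200e3, 500e3, 1e6])
    levels: list[Literal["coarser", "coarse", "normal", "fine"]] = Field(
        default_factory=lambda: ["coarser", "coarse", "normal", "fine"])


class RunConfig(_Strict):
    thorax: ThoraxConfig = Field(default_factory=ThoraxConfig)
    electrodes: ElectrodeConfig = Field(default_factory=ElectrodeConfig)
    fluid: FluidConfig | None = None
    solve: SolveConfig = Field(default_factory=SolveConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    output_dir: str = "results"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing file is all
    defaults.  Unknown keys and out-of-range values raise ConfigError with
    the offending keys named."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(lines)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True))
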