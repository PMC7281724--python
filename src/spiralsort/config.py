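"""Structured run configuration: one YAML document per device.

Keys carry explicit units in their names (``width_inlet_um``,
``radius_inlet_mm``, ``flow_rate_ml_per_min``) and unknown keys are rejected,
so a configuration file pins down a run bit-exactly.  A bundled fixture
(:func:`reference_device`) encodes the reference blood-sorter device; its
four collection-channel lengths were never published and are *reconstructed*
by tuning the hydraulic network to the published size-routing windows.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .assay import ParticleClass
from .geometry import ChannelGeometry, OutletChannel, OutletManifold
from .hydrodynamics import FluidProperties, ForceModel
from .migration import MigrationModel

__all__ = ["RunConfig", "ConfigError", "load_config", "reference_device", "config_digest"]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DeviceConfig(_Strict):
    n_turns: int = Field(7, ge=1)
    height_um: float = Field(100.0, gt=0)
    width_inlet_um: float = Field(200.0, gt=0)
    width_outlet_um: float = Field(600.0, gt=0)
    radius_inlet_mm: float = Field(2.0, gt=0)
    radius_outlet_mm: float = Field(6.2, gt=0)
    width_table_um: Optional[list[float]] = None
    radius_table_mm: Optional[list[float]] = None

    def to_geometry(self) -> ChannelGeometry:
        return ChannelGeometry(
            n_turns=self.n_turns,
            height_um=self.height_um,
            width_inlet_um=self.width_inlet_um,
            width_outlet_um=self.width_outlet_um,
            radius_inlet_mm=self.radius_inlet_mm,
            radius_outlet_mm=self.radius_outlet_mm,
            width_table_um=tuple(self.width_table_um) if self.width_table_um else None,
            radius_table_mm=tuple(self.radius_table_mm) if self.radius_table_mm else None,
        )


class OutletConfig(_Strict):
    index: int = Field(ge=1)
    width_um: float = Field(gt=0)
    height_um: float = Field(gt=0)
    length_mm: float = Field(gt=0)


class ManifoldConfig(_Strict):
    outlets: list[OutletConfig]

    def to_manifold(self) -> OutletManifold:
        return OutletManifold(
            tuple(
                OutletChannel(o.index, o.width_um, o.height_um, o.length_mm)
                for o in self.outlets
            )
        )


class FluidConfig(_Strict):
    density_kg_per_m3: float = Field(1000.0, gt=0)
    viscosity_pa_s: float = Field(1.0e-3, gt=0)

    def to_fluid(self) -> FluidProperties:
        return FluidProperties(self.density_kg_per_m3, self.viscosity_pa_s)


class OperatingConfig(_Strict):
    flow_rate_ml_per_min: float = Field(1.9, gt=0)
    scan_grid_ml_per_min: list[float] = Field(default_factory=list)
    carrier_volume_ml: Optional[float] = Field(None, gt=0)


class PopulationConfig(_Strict):
    label: str
    low_um: float
    high_um: float
    count: int = Field(ge=0)
    mean_um: Optional[float] = None
    sd_um: Optional[float] = None
    viable_fraction: float = Field(0.9, ge=0, le=1)

    def to_class(self) -> ParticleClass:
        return ParticleClass(
            self.label, self.low_um, self.high_um, self.count,
            self.mean_um, self.sd_um, self.viable_fraction,
        )


class ModelConfig(_Strict):
    """Calibrated migration/force constants; defaults reproduce the reference
    device's operating window and stream spacing (see docs/methods.md)."""

    lift_coefficient: float = Field(10.0, gt=0)
    dean_velocity_coeff: float = Field(1.8e-4, gt=0)
    dean_velocity_exponent: float = Field(1.63, gt=0)
    regime_band: float = Field(10.0, gt=1)
    eq_shift_gain: float = Field(0.015, gt=0)
    restoring_arm: float = Field(1.05, gt=0)
    wall_offset_coeff: float = Field(0.2, gt=0)
    focusing_tol: float = Field(0.01, gt=0)
    mixing_threshold: float = Field(16.0, gt=0)
    min_spacing_um: float = Field(5.0, gt=0)

    def to_model(self) -> MigrationModel:
        return MigrationModel(
            force=ForceModel(
                self.lift_coefficient,
                self.dean_velocity_coeff,
                self.dean_velocity_exponent,
                self.regime_band,
            ),
            eq_shift_gain=self.eq_shift_gain,
            restoring_arm=self.restoring_arm,
            wall_offset_coeff=self.wall_offset_coeff,
            focusing_tol=self.focusing_tol,
            mixing_threshold=self.mixing_threshold,
            min_spacing_um=self.min_spacing_um,
        )


class TuneConfig(_Strict):
    target_fractions: list[float]


class RunConfig(_Strict):
    """Full description of a reproducible run."""

    device: DeviceConfig = Field(default_factory=DeviceConfig)
    manifold: Optional[ManifoldConfig] = None
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    operating: OperatingConfig = Field(default_factory=OperatingConfig)
    populations: list[PopulationConfig] = Field(default_factory=list)
    model: ModelConfig = Field(default_factory=ModelConfig)
    tune: Optional[TuneConfig] = None
    seed: Optional[int] = None
    out_dir: Optional[str] = None

    def to_classes(self) -> tuple[ParticleClass, ...]:
        return tuple(p.to_class() for p in self.populations)


def load_config(path: str | Path) -> RunConfig:
    """Load and strictly validate a YAML run configuration."""
    try:
        raw = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config: {exc}") from exc
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"invalid config ({paths})") from exc


def config_digest(path: str | Path) -> str:
    """SHA-256 digest of the config file, for run provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def reference_device() -> RunConfig:
    """The bundled reference blood-sorter device configuration."""
    text = resources.files("spiralsort").joinpath("data/reference_device.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))
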