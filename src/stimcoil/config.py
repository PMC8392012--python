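"""Device configuration files: schema, validation, and the fixture registry.

One YAML file describes one device.  The boundary convention is millimetres
and amperes (matching the printed design tables); conversion to SI happens
here, once, when the config is turned into geometry objects.  Unknown keys
are rejected with an error listing them.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import geometry as geo
from .errors import ConfigError

MM = geo.MM


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CoilSection(_Strict):
    """A circular winding given by its envelope and turn count (mm)."""

    wire_awg: int = Field(ge=0, le=40)
    turns: float = Field(ge=1)
    inner_diameter_mm: float = Field(gt=0)
    outer_diameter_mm: float = Field(gt=0)
    height_mm: float = Field(gt=0)
    axial_center_mm: Optional[float] = None
    insulated_pitch_mm: Optional[float] = Field(default=None, gt=0)

    def wire(self) -> geo.WireGauge:
        pitch = None if self.insulated_pitch_mm is None else self.insulated_pitch_mm * MM
        return geo.awg_properties(self.wire_awg, insulated_pitch=pitch)


class AirCoreConfig(_Strict):
    kind: Literal["air_core"]
    current_A: float = Field(ge=0)
    mode: Literal["active", "sham", "off"] = "active"
    wire_awg: int = Field(ge=0, le=40)
    turns: float = Field(ge=1)
    inner_diameter_mm: float = Field(gt=0)
    outer_diameter_mm: float = Field(gt=0)
    height_mm: float = Field(gt=0)
    strand_offset_mm: Optional[float] = Field(default=None, ge=0)
    insulated_pitch_mm: Optional[float] = Field(default=None, gt=0)


class Merritt3Config(_Strict):
    kind: Literal["merritt3"]
    current_A: float = Field(ge=0)
    mode: Literal["active", "sham", "off"] = "active"
    wire_awg: int = Field(ge=0, le=40)
    turns_per_coil: float = Field(ge=1)
    inner_side_mm: float = Field(gt=0)
    outer_side_mm: float = Field(gt=0)
    coil_height_mm: float = Field(gt=0)
    total_height_mm: Optional[float] = Field(default=None, gt=0)
    ampere_turn_ratio: float = 1.0
    strand_offset_mm: Optional[float] = Field(default=None, ge=0)


class RodCoreConfig(_Strict):
    kind: Literal["rod_core"]
    current_A: float = Field(ge=0)
    mode: Literal["active", "sham", "off"] = "active"
    core_diameter_mm: float = Field(gt=0)
    core_length_mm: float = Field(gt=0)
    relative_permeability: float = Field(ge=1)
    taper_length_mm: float = Field(default=15.0, gt=0)
    tip_radius_mm: float = Field(default=0.2, gt=0)
    coil: CoilSection
    strand_offset_mm: Optional[float] = Field(default=None, ge=0)


class PotCoreConfig(_Strict):
    kind: Literal["pot_core"]
    current_A: float = Field(ge=0)
    mode: Literal["active", "sham", "off"] = "active"
    outer_diameter_mm: float = Field(gt=0)
    height_mm: float = Field(gt=0)
    channel_depth_mm: float = Field(gt=0)
    channel_width_mm: float = Field(gt=0)
    relative_permeability: float = Field(ge=1)
    permeability_tolerance: float = Field(default=0.0, ge=0, lt=1)
    center_post_radius_mm: Optional[float] = Field(default=None, gt=0)
    shield_thickness_mm: Optional[float] = Field(default=None, gt=0)
    coil: CoilSection
    strand_offset_mm: Optional[float] = Field(default=None, ge=0)


DeviceConfig = Union[AirCoreConfig, Merritt3Config, RodCoreConfig, PotCoreConfig]

_KIND_MODELS = {
    "air_core": AirCoreConfig,
    "merritt3": Merritt3Config,
    "rod_core": RodCoreConfig,
    "pot_core": PotCoreConfig,
}


def parse_config(data: dict) -> DeviceConfig:
    """Validate a raw mapping against the device schema."""
    if not isinstance(data, dict) or "kind" not in data:
        raise ConfigError("config must be a mapping with a 'kind' key")
    kind = data["kind"]
    model = _KIND_MODELS.get(kind)
    if model is None:
        raise ConfigError(f"unknown device kind {kind!r}; expected one of "
                          f"{sorted(_KIND_MODELS)}")
    try:
        return model.model_validate(data)
    except ValidationError as exc:
        unknown = [".".join(str(p) for p in e["loc"])
                   for e in exc.errors() if e["type"] == "extra_forbidden"]
        msg = f"invalid {kind} config: {exc}"
        if unknown:
            msg = f"unknown keys {unknown} in {kind} config\n{msg}"
        raise ConfigError(msg) from exc


def load_config(path) -> DeviceConfig:
    """Read and validate a YAML device config file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return parse_config(data)


def config_hash(path) -> str:
    """sha256 of the config file bytes (recorded in run manifests)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# config -> geometry
# ---------------------------------------------------------------------------

def build_device(cfg: DeviceConfig):
    """Turn a validated config into a device object (SI units)."""
    if isinstance(cfg, AirCoreConfig):
        pitch = None if cfg.insulated_pitch_mm is None else cfg.insulated_pitch_mm * MM
        gauge = geo.awg_properties(cfg.wire_awg, insulated_pitch=pitch)
        return geo.CircularCoilSpec.from_mm(cfg.inner_diameter_mm,
                                            cfg.outer_diameter_mm,
                                            cfg.height_mm, cfg.turns, gauge)
    if isinstance(cfg, Merritt3Config):
        gauge = geo.awg_properties(cfg.wire_awg)
        return geo.merritt_stack(cfg.inner_side_mm, cfg.outer_side_mm,
                                 cfg.coil_height_mm, cfg.turns_per_coil, gauge,
                                 total_height_mm=cfg.total_height_mm,
                                 ampere_turn_ratio=cfg.ampere_turn_ratio)
    if isinstance(cfg, RodCoreConfig):
        coil = _circular_from_section(cfg.coil, default_center_mm=0.0)
        return geo.RodCoreSpec(core_diameter=cfg.core_diameter_mm * MM,
                               core_length=cfg.core_length_mm * MM,
                               relative_permeability=cfg.relative_permeability,
                               coil=coil,
                               taper_length=cfg.taper_length_mm * MM,
                               tip_radius=cfg.tip_radius_mm * MM)
    if isinstance(cfg, PotCoreConfig):
        r_out = cfg.outer_diameter_mm / 2
        post = cfg.center_post_radius_mm
        shield = cfg.shield_thickness_mm
        if post is None and shield is None:
            # fill the envelope with the channel between post and shield,
            # splitting the material so post and shield flux areas match:
            # pi p^2 = pi (R^2 - (p + w)^2)
            w = cfg.channel_width_mm
            post = (-w + (w * w + 2 * (r_out ** 2 - w * w)) ** 0.5) / 2
            shield = r_out - post - w
        elif post is None:
            post = r_out - shield - cfg.channel_width_mm
        elif shield is None:
            shield = r_out - post - cfg.channel_width_mm
        # coil rests on the channel floor unless explicitly positioned
        channel_bottom_mm = cfg.height_mm / 2 - cfg.channel_depth_mm
        default_center = channel_bottom_mm + cfg.coil.height_mm / 2
        coil = _circular_from_section(cfg.coil, default_center_mm=default_center)
        return geo.PotCoreSpec(outer_diameter=cfg.outer_diameter_mm * MM,
                               height=cfg.height_mm * MM,
                               channel_depth=cfg.channel_depth_mm * MM,
                               channel_width=cfg.channel_width_mm * MM,
                               relative_permeability=cfg.relative_permeability,
                               permeability_tolerance=cfg.permeability_tolerance,
                               center_post_radius=post * MM,
                               shield_thickness=shield * MM,
                               coil=coil)
    raise ConfigError(f"unhandled config type {type(cfg).__name__}")


def _circular_from_section(section: CoilSection, default_center_mm: float):
    center = section.axial_center_mm
    if center is None:
        center = default_center_mm
    return geo.CircularCoilSpec.from_mm(section.inner_diameter_mm,
                                        section.outer_diameter_mm,
                                        section.height_mm, section.turns,
                                        section.wire(),
                                        axial_center_mm=center)


def drive_for(cfg: DeviceConfig) -> geo.DriveCondition:
    return geo.DriveCondition(current=cfg.current_A, mode=cfg.mode)


def strand_offset_for(cfg: DeviceConfig) -> float:
    """Strand-to-strand displacement (m): configured, else one wire pitch."""
    if cfg.strand_offset_mm is not None:
        return cfg.strand_offset_mm * MM
    if isinstance(cfg, (AirCoreConfig, Merritt3Config)):
        return geo.awg_properties(cfg.wire_awg).insulated_pitch
    return cfg.coil.wire().insulated_pitch


# ---------------------------------------------------------------------------
# bundled fixtures (the platform's four as-simulated devices)
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("air_core", "three_coil", "rod_core", "pot_core")


def fixture_path(name: str) -> Path:
    """Path to a bundled device config (one per as-simulated design)."""
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Path(str(resources.files("stimcoil").joinpath("configs", f"{name}.yaml")))


def load_fixture(name: str) -> DeviceConfig:
    return load_config(fixture_path(name))
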