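"""Coil geometry: wire gauges, winding specs for the four device families,
and the winding design rules (Merritt spacing, resistance budget, turn packing).

All stored lengths are SI metres; configuration files use millimetres and are
converted at the I/O boundary (see :mod:`stimcoil.config`).  Wire resistance is
annealed copper at 20 degC with no temperature coefficient — heating is handled
separately by :mod:`stimcoil.transient`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidGaugeError

MM = 1e-3  # metres per millimetre

#: resistivity of annealed copper at 20 degC, ohm * m
COPPER_RESISTIVITY = 1.7241e-8

#: Merritt three-coil spacing ratio h/d (top-to-bottom coil-centre distance
#: over square side length) for a uniform central field.
MERRITT_HD_RATIO = 0.821116


# ---------------------------------------------------------------------------
# wire
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WireGauge:
    """A magnet-wire size: bare conductor plus effective wound pitch.

    Attributes
    ----------
    awg_number : int
        American Wire Gauge number (0-40).
    bare_diameter : float
        Bare copper diameter, m.
    resistance_per_length : float
        DC resistance per unit length at 20 degC, ohm/m.
    insulated_pitch : float
        Effective centre-to-centre spacing of adjacent turns when wound, m.
        Accounts for the insulation build; >= bare_diameter.
    """

    awg_number: int
    bare_diameter: float
    resistance_per_length: float
    insulated_pitch: float

    def __post_init__(self) -> None:
        if self.bare_diameter <= 0:
            raise ValueError("bare_diameter must be positive")
        if self.insulated_pitch < self.bare_diameter:
            raise ValueError("insulated_pitch must be >= bare_diameter")
        if self.resistance_per_length <= 0:
            raise ValueError("resistance_per_length must be positive")


def awg_properties(awg_number: int, insulated_pitch: float | None = None) -> WireGauge:
    """Standard AWG wire properties.

    Bare diameter follows the AWG closed form d = 0.127 mm * 92**((36-g)/39);
    resistance per length is copper resistivity over the bare cross-section.
    The default insulated pitch is the bare diameter times 1.11 rounded to
    0.01 mm (which gives exactly 0.90 mm for 20 AWG, the pitch that packs the
    air-core channel to its nominal turn count).

    Parameters
    ----------
    awg_number : int
        Gauge, 0-40.
    insulated_pitch : float, optional
        Override the default wound pitch, m.
    """
    if not (0 <= awg_number <= 40):
        raise InvalidGaugeError(f"AWG number {awg_number} outside supported range 0-40")
    d = 0.127 * MM * 92.0 ** ((36 - awg_number) / 39.0)
    area = math.pi * d * d / 4.0
    r_per_len = COPPER_RESISTIVITY / area
    if insulated_pitch is None:
        insulated_pitch = round(d * 1.11 / (0.01 * MM)) * 0.01 * MM
    return WireGauge(awg_number, d, r_per_len, insulated_pitch)


# ---------------------------------------------------------------------------
# coil cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularCoilSpec:
    """A circular pancake/solenoid winding with rectangular cross-section.

    The winding occupies inner_radius <= r <= outer_radius,
    |z - axial_center| <= height/2.  All lengths in metres.
    """

    inner_radius: float
    outer_radius: float
    height: float
    turns: float
    gauge: WireGauge
    axial_center: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError("require 0 < inner_radius < outer_radius")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.turns < 1:
            raise ValueError("turns must be >= 1")

    @classmethod
    def from_mm(cls, inner_diameter_mm: float, outer_diameter_mm: float,
                height_mm: float, turns: float, gauge: WireGauge,
                axial_center_mm: float = 0.0) -> "CircularCoilSpec":
        return cls(inner_radius=inner_diameter_mm / 2 * MM,
                   outer_radius=outer_diameter_mm / 2 * MM,
                   height=height_mm * MM, turns=turns, gauge=gauge,
                   axial_center=axial_center_mm * MM)

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.inner_radius + self.outer_radius)


@dataclass(frozen=True)
class SquareCoilSpec:
    """A square winding; sides are full side lengths (metres)."""

    inner_side: float
    outer_side: float
    height: float
    turns: float
    gauge: WireGauge
    axial_center: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_side < self.outer_side):
            raise ValueError("require 0 < inner_side < outer_side")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.turns < 1:
            raise ValueError("turns must be >= 1")

    @classmethod
    def from_mm(cls, inner_side_mm: float, outer_side_mm: float, height_mm: float,
                turns: float, gauge: WireGauge,
                axial_center_mm: float = 0.0) -> "SquareCoilSpec":
        return cls(inner_side=inner_side_mm * MM, outer_side=outer_side_mm * MM,
                   height=height_mm * MM, turns=turns, gauge=gauge,
                   axial_center=axial_center_mm * MM)

    @property
    def mean_side(self) -> float:
        return 0.5 * (self.inner_side + self.outer_side)


#: admissible centre-to-outer ampere-turn ratios for the three-coil stack:
#: equal ampere-turns (as built) or the 20:39 volume-uniformity variant.
MERRITT_RATIOS = (1.0, 20.0 / 39.0)


@dataclass(frozen=True)
class MerrittStack:
    """Three coaxial square coils spaced by the Merritt h/d ratio.

    ``total_height`` is the top-coil-centre to bottom-coil-centre distance
    (coil centres sit at 0 and +-total_height/2); the physical envelope is
    taller by one coil height.  ``ampere_turn_ratio`` scales the centre coil's
    ampere-turns relative to the outer pair.
    """

    coils: tuple[SquareCoilSpec, SquareCoilSpec, SquareCoilSpec]
    total_height: float
    ampere_turn_ratio: float = 1.0

    def __post_init__(self) -> None:
        if len(self.coils) != 3:
            raise ValueError("MerrittStack requires exactly three coils")
        ref = self.coils[0]
        for c in self.coils:
            if not (math.isclose(c.inner_side, ref.inner_side)
                    and math.isclose(c.outer_side, ref.outer_side)):
                raise ValueError("stack coils must share side lengths")
        centers = sorted(c.axial_center for c in self.coils)
        expect = [-self.total_height / 2, 0.0, self.total_height / 2]
        for got, want in zip(centers, expect):
            if not math.isclose(got, want, abs_tol=1e-9):
                raise ValueError("coil centres must sit at 0 and +-total_height/2")
        if not any(math.isclose(self.ampere_turn_ratio, r) for r in MERRITT_RATIOS):
            raise ValueError("ampere_turn_ratio must be 1.0 or 20/39")


def merritt_stack(inner_side_mm: float, outer_side_mm: float, coil_height_mm: float,
                  turns_per_coil: float, gauge: WireGauge,
                  total_height_mm: float | None = None,
                  ampere_turn_ratio: float = 1.0) -> MerrittStack:
    """Build a three-coil Merritt stack from millimetre dimensions.

    If ``total_height_mm`` is omitted it follows the Merritt ratio applied to
    the inner side length.
    """
    if total_height_mm is None:
        total_height_mm = merritt_height(inner_side_mm)
    h = total_height_mm * MM
    coils = tuple(
        SquareCoilSpec.from_mm(inner_side_mm, outer_side_mm, coil_height_mm,
                               turns_per_coil, gauge, axial_center_mm=zc / MM)
        for zc in (-h / 2, 0.0, h / 2)
    )
    return MerrittStack(coils=coils, total_height=h,
                        ampere_turn_ratio=ampere_turn_ratio)


# ---------------------------------------------------------------------------
# permeable-core devices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RodCoreSpec:
    """A high-permeability rod (tapered to points at both ends) with a coil
    wound around its middle.

    The rod occupies |z| <= core_length/2 on the axis; ``taper_profile`` is a
    sequence of (axial position from the tip-ward end, radius) pairs for one
    tip, mirrored to the other.  Default taper: straight cone from the full
    radius down to ``tip_radius`` over the last ``taper_length`` of each end.
    """

    core_diameter: float
    core_length: float
    relative_permeability: float
    coil: CircularCoilSpec
    coil_axial_position: float = 0.0
    taper_length: float = 15e-3
    tip_radius: float = 0.2e-3

    def __post_init__(self) -> None:
        if self.relative_permeability < 1:
            raise ValueError("relative_permeability must be >= 1")
        if self.tip_radius > self.core_diameter / 2:
            raise ValueError("tip radius exceeds core radius")
        if self.coil.inner_radius * 2 < self.core_diameter:
            raise ValueError("coil inner diameter must clear the core")
        if self.taper_length <= 0 or self.taper_length > self.core_length / 2:
            raise ValueError("taper_length must lie in (0, core_length/2]")

    def core_radius_at(self, z: float) -> float:
        """Rod radius at axial position z (0 outside the rod)."""
        half = self.core_length / 2
        az = abs(z)
        if az > half:
            return 0.0
        r0 = self.core_diameter / 2
        if az < half - self.taper_length:
            return r0
        frac = (half - az) / self.taper_length  # 0 at apex, 1 at taper start
        return self.tip_radius + (r0 - self.tip_radius) * frac


@dataclass(frozen=True)
class PotCoreSpec:
    """Half pot core: a ferrite cup with a centre post, annular winding
    channel, outer shield wall, and one open face (at +z).

    The cup occupies |z| <= height/2; the base plate sits at the -z end and
    the channel opens through the +z face.  Internal dimensions not printed on
    the published envelope are inferred to fill it symmetrically and recorded
    in output metadata.
    """

    outer_diameter: float
    height: float
    channel_depth: float
    channel_width: float
    relative_permeability: float
    coil: CircularCoilSpec
    center_post_radius: float = 7.1e-3
    shield_thickness: float = 1.85e-3
    permeability_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.relative_permeability < 1:
            raise ValueError("relative_permeability must be >= 1")
        if not (0 <= self.permeability_tolerance < 1):
            raise ValueError("permeability tolerance fraction must be in [0, 1)")
        r_out = self.outer_diameter / 2
        if self.center_post_radius + self.channel_width + self.shield_thickness > r_out + 1e-12:
            raise ValueError("channel + shield do not fit inside the core envelope")
        if self.channel_depth >= self.height:
            raise ValueError("channel depth must be smaller than core height")

    @property
    def channel_inner_radius(self) -> float:
        return self.center_post_radius

    @property
    def channel_outer_radius(self) -> float:
        return self.center_post_radius + self.channel_width


# ---------------------------------------------------------------------------
# drive
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriveCondition:
    """Excitation: current in amperes and operating mode.

    ``off`` mode forces an effective current of zero regardless of the
    nominal current (mirrors the controller's no-stimulation condition).
    """

    current: float
    mode: str = "active"

    def __post_init__(self) -> None:
        if self.current < 0:
            raise ValueError("current must be >= 0")
        if self.mode not in ("active", "sham", "off"):
            raise ValueError(f"unknown drive mode {self.mode!r}")

    @property
    def effective_current(self) -> float:
        return 0.0 if self.mode == "off" else self.current

    def with_current(self, current: float) -> "DriveCondition":
        return replace(self, current=current)


# ---------------------------------------------------------------------------
# design rules
# ---------------------------------------------------------------------------

def pack_turns(radial_depth: float, axial_height: float, pitch: float) -> int:
    """Square-packing turn estimate for a rectangular winding channel.

    floor(radial_depth/pitch) * floor(axial_height/pitch); returns 0 when the
    wire does not fit at all.
    """
    if radial_depth <= 0 or axial_height <= 0 or pitch <= 0:
        raise ValueError("all arguments must be positive")
    return int(math.floor(radial_depth / pitch + 1e-12)
               * math.floor(axial_height / pitch + 1e-12))


def merritt_height(side_length: float) -> float:
    """Total stack height h = 0.821116 * d for a three-coil Merritt system.

    Works in any length unit (the ratio is dimensionless).
    """
    if side_length <= 0:
        raise ValueError("side_length must be positive")
    return MERRITT_HD_RATIO * side_length


def resistance_budget(supply_voltage: float, supply_current: float) -> float:
    """Maximum total winding resistance V/I for a given supply."""
    if supply_voltage <= 0:
        raise ValueError("supply_voltage must be positive")
    if supply_current <= 0:
        raise ZeroDivisionError("supply_current must be positive")
    return supply_voltage / supply_current


def max_wire_length(resistance_limit: float, gauge: WireGauge) -> float:
    """Longest wire (m) of the given gauge that stays within a resistance budget."""
    if resistance_limit <= 0:
        raise ValueError("resistance_limit must be positive")
    return resistance_limit / gauge.resistance_per_length


def coil_dc_resistance(spec: CircularCoilSpec | SquareCoilSpec) -> float:
    """Predicted DC resistance: turns x mean turn perimeter x ohm/m.

    Uses the cross-section centroid radius/side; leads and temperature rise
    are not modelled, so expect agreement with bench measurements only to a
    few tens of percent.
    """
    if isinstance(spec, CircularCoilSpec):
        perimeter = 2 * math.pi * spec.mean_radius
    elif isinstance(spec, SquareCoilSpec):
        perimeter = 4 * spec.mean_side
    else:
        raise TypeError(f"unsupported spec type {type(spec).__name__}")
    return spec.turns * perimeter * spec.gauge.resistance_per_length
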