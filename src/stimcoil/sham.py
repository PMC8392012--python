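"""Bifilar (double-wrapped) winding model and sham-mode residual fields.

Every coil in the platform is wound with two adjacent wires.  Driving the two
strands in parallel is the active condition; reversing one strand (sham)
nearly cancels the field, leaving only a residual set by the geometric offset
between the strands.  The two strands are modelled as two complete filament
coils displaced along the axis by one wire pitch (side-by-side bifilar lay);
a radial-offset variant is available through ``offset_direction``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import biot_savart as bs
from .errors import GridMismatchError
from .fieldmaps import FieldMap, LineScan
from .geometry import CircularCoilSpec, DriveCondition, SquareCoilSpec


@dataclass(frozen=True)
class DoubleWrapSpec:
    """A double-wrapped coil: base winding + strand-to-strand displacement.

    ``strand_offset`` is the centre-to-centre displacement (m) between the
    two strands; it cannot exceed two wire pitches.  ``mode`` selects the
    drive polarity of the second strand.
    """

    base: CircularCoilSpec | SquareCoilSpec
    strand_offset: float
    mode: str = "active"
    offset_direction: str = "axial"  # or "radial"

    def __post_init__(self) -> None:
        if self.strand_offset < 0:
            raise ValueError("strand_offset must be >= 0")
        if self.strand_offset > 2 * self.base.gauge.insulated_pitch:
            raise ValueError("strand_offset exceeds twice the wire pitch")
        if self.mode not in ("active", "sham"):
            raise ValueError(f"unknown double-wrap mode {self.mode!r}")
        if self.offset_direction not in ("axial", "radial"):
            raise ValueError("offset_direction must be 'axial' or 'radial'")


def _displaced(base, delta: float, direction: str):
    """A copy of the base spec displaced along the axis or radially."""
    if direction == "axial":
        return replace(base, axial_center=base.axial_center + delta)
    if isinstance(base, CircularCoilSpec):
        return replace(base, inner_radius=base.inner_radius + delta,
                       outer_radius=base.outer_radius + delta)
    return replace(base, inner_side=base.inner_side + 2 * delta,
                   outer_side=base.outer_side + 2 * delta)


def expand(spec: DoubleWrapSpec, current: float):
    """Resolve a double wrap into its two strands with signed currents.

    Each strand carries half the base turns.  Active mode drives both strands
    with +I (total ampere-turns equal the single-wrap base exactly); sham mode
    drives them with +I and -I so the net ampere-turns vanish.

    Returns a list of (coil spec, signed current) pairs.
    """
    half = spec.strand_offset / 2.0
    strand_a = _displaced(spec.base, -half, spec.offset_direction)
    strand_b = _displaced(spec.base, +half, spec.offset_direction)
    # half the turns per strand; FilamentLoop currents only ever see the
    # product N*I so fractional turns are fine
    strand_a = replace(strand_a, turns=spec.base.turns / 2.0)
    strand_b = replace(strand_b, turns=spec.base.turns / 2.0)
    sign_b = 1.0 if spec.mode == "active" else -1.0
    return [(strand_a, current), (strand_b, sign_b * current)]


def doublewrap_filaments(spec: DoubleWrapSpec, drive: DriveCondition,
                         subdivisions: int = bs.DEFAULT_SUBDIVISIONS):
    """Filament set for a double wrap; drive mode 'sham' overrides spec mode."""
    mode = spec.mode
    if drive.mode == "sham":
        mode = "sham"
    resolved = replace(spec, mode=mode)
    (coil_a, cur_a), (coil_b, cur_b) = expand(resolved, drive.effective_current)
    fils_a = bs.discretize(coil_a, cur_a, subdivisions, subdivisions)
    fils_b = bs.discretize(coil_b, cur_b, subdivisions, subdivisions)
    # interleave the strands so a zero-offset sham cancels exactly pairwise
    fils = []
    for fa, fb in zip(fils_a, fils_b):
        fils += [fa, fb]
    return fils


def residual_map(spec: DoubleWrapSpec, plane: str, extent, step: float,
                 current: float, origin=(0.0, 0.0, 0.0),
                 subdivisions: int = bs.DEFAULT_SUBDIVISIONS) -> FieldMap:
    """Residual field map of the sham (anti-parallel) condition."""
    sham_spec = replace(spec, mode="sham")
    drive = DriveCondition(current=current, mode="sham")
    fils = doublewrap_filaments(sham_spec, drive, subdivisions)
    return bs.field_map_from_filaments(fils, plane, extent, step, drive, origin)


def residual_line_scan(spec: DoubleWrapSpec, start, direction, positions,
                       current: float,
                       subdivisions: int = bs.DEFAULT_SUBDIVISIONS) -> LineScan:
    """Residual |B| along a line in sham mode."""
    sham_spec = replace(spec, mode="sham")
    drive = DriveCondition(current=current, mode="sham")
    fils = doublewrap_filaments(sham_spec, drive, subdivisions)
    return bs.line_scan_from_filaments(fils, start, direction, positions, drive)


def attenuation_ratio(active: FieldMap | LineScan, sham: FieldMap | LineScan,
                      location) -> float:
    """|B|_active / |B|_sham at a location; math.inf when the sham field is 0.

    ``location`` is a 3-vector point for maps or a signed offset for line
    scans.  Both inputs must share grid geometry.
    """
    if type(active) is not type(sham):
        raise GridMismatchError("active and sham payloads have different kinds")
    if isinstance(active, FieldMap):
        if not math.isclose(active.step, sham.step) or active.shape != sham.shape:
            raise GridMismatchError("maps do not share step/shape")
        a = active.value_at(location)
        s = sham.value_at(location)
    else:
        if active.positions.shape != sham.positions.shape or \
                not np.allclose(active.positions, sham.positions):
            raise GridMismatchError("line scans do not share positions")
        a = active.value_at(location)
        s = sham.value_at(location)
    if s == 0.0:
        return math.inf
    return a / s
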