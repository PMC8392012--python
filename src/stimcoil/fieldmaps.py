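"""Gridded field containers shared by every solver and the measurement rig.

``FieldMap`` is a planar grid of B vectors; ``LineScan`` a 1-D sampling of
|B| along a straight line; ``ScanRecord`` wraps either payload with the
measurement condition metadata (active / sham / control, excitation current,
read averaging).  All coordinates and fields are SI (m, T); serialization to
the delimited-text scan format lives in :mod:`stimcoil.scanio`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ScalingError
from .geometry import DriveCondition

#: in-plane axis indices for each named plane (first axis, second axis)
PLANE_AXES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}


@dataclass
class FieldMap:
    """B sampled on a regular planar grid.

    ``points`` has shape (n1, n2, 3): full 3-D coordinates of each grid node
    (m).  ``values`` has the same shape and holds (Bx, By, Bz) in tesla.
    Nodes where evaluation was impossible (inside a winding filament) are
    flagged in ``mask`` and carry NaN values.
    """

    plane: str
    origin: np.ndarray
    step: float
    points: np.ndarray
    values: np.ndarray
    excitation: DriveCondition
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.plane not in PLANE_AXES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.points.shape != self.values.shape or self.points.ndim != 3:
            raise ValueError("points and values must share shape (n1, n2, 3)")
        if self.points.shape[0] < 2 or self.points.shape[1] < 2:
            raise ValueError("grid must be at least 2x2")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def magnitude(self) -> np.ndarray:
        """|B| grid (n1, n2), tesla."""
        return np.linalg.norm(self.values, axis=-1)

    def scaled(self, factor: float) -> "FieldMap":
        out = replace(self, values=self.values * factor)
        return out

    def nearest_index(self, point) -> tuple[int, int]:
        """Grid index of the node closest to a 3-D point (m)."""
        p = np.asarray(point, dtype=float)
        d2 = np.sum((self.points - p) ** 2, axis=-1)
        return tuple(np.unravel_index(np.argmin(d2), d2.shape))  # type: ignore[return-value]

    def value_at(self, point) -> float:
        """|B| at the grid node nearest to ``point``."""
        i, j = self.nearest_index(point)
        return float(self.magnitude[i, j])


@dataclass
class LineScan:
    """|B| along a straight line.

    ``positions`` are signed offsets (m) along ``direction`` from ``start``,
    strictly increasing.  ``b_vectors`` is optional (FEM scans report only
    the axial component pair it derives the magnitude from).
    """

    start: np.ndarray
    direction: np.ndarray
    positions: np.ndarray
    magnitude: np.ndarray
    excitation: DriveCondition
    b_vectors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.direction = self.direction / n
        self.positions = np.asarray(self.positions, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.magnitude.shape:
            raise ValueError("positions and magnitude must be matching 1-D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def scaled(self, factor: float) -> "LineScan":
        out = replace(self, magnitude=self.magnitude * abs(factor))
        if self.b_vectors is not None:
            out.b_vectors = self.b_vectors * factor
        return out

    def value_at(self, position: float) -> float:
        """Linearly interpolated |B| at a signed offset (m)."""
        if position < self.positions[0] or position > self.positions[-1]:
            raise ValueError(f"position {position} outside scan range")
        return float(np.interp(position, self.positions, self.magnitude))


@dataclass
class ScanRecord:
    """A measured-style scan: payload plus acquisition metadata.

    ``condition`` mirrors the experiment's trial types: ``active`` (drive on),
    ``sham`` (anti-parallel double wrap), ``control`` (no current — implies
    zero excitation current).  ``n_averages`` is the number of sensor reads
    averaged per grid point.
    """

    payload: FieldMap | LineScan
    condition: str
    current: float
    n_averages: int = 1
    provenance: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.condition not in ("active", "sham", "control"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "control" and self.current != 0:
            raise ValueError("control condition implies zero current")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")

    def scaled_to_current(self, target_current: float) -> "ScanRecord":
        """Linearly rescale the payload to a different excitation current."""
        if self.current <= 0:
            raise ScalingError("cannot scale a zero-current scan")
        factor = target_current / self.current
        return replace(self, payload=self.payload.scaled(factor),
                       current=target_current,
                       provenance=(self.provenance +
                                   f" [scaled x{factor:g} from {self.current:g} A]").strip())
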