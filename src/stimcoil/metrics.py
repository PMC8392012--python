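"""Quantitative comparison of simulated and measured field maps.

Covers the validation workflow: integer-cell cross-correlation alignment of
|B| images, linear rescaling between excitation currents, centre-relative
uniformity profiles of line scans, and a per-condition summary report
(control / sham / active / simulated) at a stated target location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (DegenerateCorrelationError, GridMismatchError,
                     ReportError)
from .fieldmaps import FieldMap, LineScan, ScanRecord


def align(map_a: FieldMap, map_b: FieldMap,
          max_shift: int | None = None) -> tuple[int, int]:
    """Integer-cell shift of map_b's content relative to map_a.

    Maximizes the zero-normalized cross-correlation of the |B| grids over
    integer displacements within +-1/4 of the grid size (ties broken toward
    the smallest displacement norm, then lexicographically).  A returned
    shift (di, dj) means map_b[i, j] matches map_a[i - di, j - dj].
    """
    if not math.isclose(map_a.step, map_b.step, rel_tol=1e-9):
        raise GridMismatchError("maps have different step sizes")
    A = np.nan_to_num(map_a.magnitude)
    B = np.nan_to_num(map_b.magnitude)
    if A.shape != B.shape:
        raise GridMismatchError("maps have different grid shapes")
    if np.ptp(A) == 0 or np.ptp(B) == 0:
        raise DegenerateCorrelationError("constant |B| grid: correlation undefined")

    n1, n2 = A.shape
    if max_shift is None:
        max_shift = max(1, min(n1, n2) // 4)

    best = None
    for di in range(-max_shift, max_shift + 1):
        for dj in range(-max_shift, max_shift + 1):
            # overlap of A[i,j] with B[i+di, j+dj]
            a_i0, a_i1 = max(0, -di), min(n1, n1 - di)
            a_j0, a_j1 = max(0, -dj), min(n2, n2 - dj)
            if a_i1 - a_i0 < 2 or a_j1 - a_j0 < 2:
                continue
            a = A[a_i0:a_i1, a_j0:a_j1]
            b = B[a_i0 + di:a_i1 + di, a_j0 + dj:a_j1 + dj]
            da = a - a.mean()
            db = b - b.mean()
            denom = np.sqrt((da * da).sum() * (db * db).sum())
            if denom == 0:
                continue
            ncc = float((da * db).sum() / denom)
            key = (-ncc, di * di + dj * dj, di, dj)
            if best is None or key < best[0]:
                best = (key, (di, dj))
    if best is None:
        raise DegenerateCorrelationError("no valid overlap for any shift")
    return best[1]


def scale_to_current(record: ScanRecord, target_current: float) -> ScanRecord:
    """Linearly rescale a scan to a different excitation current.

    Magnetostatics is linear in the drive, so a 1 A measurement times 15
    is the 15 A prediction exactly.
    """
    return record.scaled_to_current(target_current)


def uniformity_profile(scan: LineScan, offsets: Iterable[float]) -> list[float]:
    """Signed percent deviation of |B| at +-offset versus the scan centre.

    For each offset o the value is the mean over the two symmetric positions
    of 100 * (|B|(+-o) - |B|(0)) / |B|(0).  "Average" over the pair is the
    documented interpretation of centre-relative uniformity percentages.
    Scale-invariant by construction.
    """
    center = scan.value_at(0.0)
    if center == 0:
        raise ZeroDivisionError("centre |B| is zero; profile undefined")
    out = []
    for o in offsets:
        lo, hi = scan.value_at(-abs(o)), scan.value_at(abs(o))
        out.append(100.0 * (0.5 * (lo + hi) - center) / center)
    return out


@dataclass
class ComparisonReport:
    """Per-condition summary at a target location.

    ``values`` holds |B| (T) per condition at the location (maps sampled
    after alignment to the simulated grid); ``projected_15A`` is the active
    measurement linearly scaled to 15 A.
    """

    location: np.ndarray
    values: dict = field(default_factory=dict)         # condition -> |B| (T)
    simulated_value: float = float("nan")
    alignment_shifts: dict = field(default_factory=dict)
    attenuation: float = float("nan")                  # active / sham
    relative_difference: float = float("nan")          # (active - sim) / sim
    projected_15A: float = float("nan")
    uniformity: Optional[list[float]] = None


def summarize(records: Sequence[ScanRecord], simulated: FieldMap,
              location, offsets: Iterable[float] = ()) -> ComparisonReport:
    """Build the per-condition comparison at a stated location.

    Records carrying FieldMap payloads are aligned to the simulated map by
    cross-correlation before sampling; the active record is also projected
    to 15 A.  Raises :class:`ReportError` when no active record is present.
    """
    by_cond = {}
    for rec in records:
        by_cond.setdefault(rec.condition, rec)
    if "active" not in by_cond:
        raise ReportError("summary requires at least one active record")

    loc = np.asarray(location, dtype=float)
    report = ComparisonReport(location=loc)
    report.simulated_value = simulated.value_at(loc)

    # the scanner-to-device offset is estimated once, from the active record
    # (sham/control patterns are residual/noise and carry no alignment
    # information), and applied to every map of the session
    shift = (0, 0)
    active_payload = by_cond["active"].payload
    if isinstance(active_payload, FieldMap):
        try:
            shift = align(simulated, active_payload)
        except DegenerateCorrelationError:
            shift = (0, 0)

    for cond, rec in by_cond.items():
        payload = rec.payload
        if isinstance(payload, FieldMap):
            report.alignment_shifts[cond] = shift
            i, j = simulated.nearest_index(loc)
            di, dj = shift
            n1, n2 = payload.shape
            ii = min(max(i + di, 0), n1 - 1)
            jj = min(max(j + dj, 0), n2 - 1)
            report.values[cond] = float(np.nan_to_num(payload.magnitude[ii, jj]))
        else:
            # line scans are sampled at the location's offset along the line
            offset = float(np.dot(loc - payload.start, payload.direction))
            report.values[cond] = payload.value_at(offset)

    active = by_cond["active"]
    if "sham" in report.values:
        s = report.values["sham"]
        report.attenuation = math.inf if s == 0 else report.values["active"] / s
    if report.simulated_value != 0:
        sim_at_meas_current = report.simulated_value * (
            active.current / max(simulated.excitation.current, 1e-300))
        report.relative_difference = ((report.values["active"] - sim_at_meas_current)
                                      / sim_at_meas_current)
    if active.current > 0:
        report.projected_15A = report.values["active"] * 15.0 / active.current

    offsets = list(offsets)
    if offsets and isinstance(active.payload, LineScan):
        report.uniformity = uniformity_profile(active.payload, offsets)
    return report
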