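"""Synthetic measurement rig: emulates the three-axis Hall-probe XYZ scanner
and the 1 Hz thermal logger so every downstream comparison stage can be
exercised without hardware.

The sensor model is per-axis Gaussian read noise plus a constant offset field
(ambient/Earth field and probe bias), with several reads averaged per grid
point (default 5, matching the bench procedure).  Grid misalignment between
scanner and device is an integer-cell shift.  All generators are
deterministic given (configuration, seed); seeds are explicit arguments and
recorded on the output records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import biot_savart as bs
from .fieldmaps import FieldMap, ScanRecord
from .geometry import DriveCondition
from .transient import ThermalParams, temperature_trajectory

#: default per-axis read noise, T (order of a consumer 3-axis Hall sensor's
#: noise class; a fixture choice, configurable)
DEFAULT_SIGMA_T = 0.13e-3

#: default constant offset field, T (|offset| = 0.05 mT)
DEFAULT_OFFSET_T = (3e-5, 0.0, 4e-5)


@dataclass(frozen=True)
class SensorModel:
    """Per-axis noise sigma (T), constant offset vector (T), reads per point."""

    noise_sigma: float = DEFAULT_SIGMA_T
    offset: tuple[float, float, float] = DEFAULT_OFFSET_T
    n_averages: int = 5

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")


def _shift_with_edge_clamp(values: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Displace grid content by (di, dj) cells, replicating edge values.

    Models a scanner origin offset: out[i, j] = truth[i - di, j - dj].
    """
    if di == 0 and dj == 0:
        return values.copy()
    n1, n2 = values.shape[:2]
    ii = np.clip(np.arange(n1) - di, 0, n1 - 1)
    jj = np.clip(np.arange(n2) - dj, 0, n2 - 1)
    return values[np.ix_(ii, jj)]


def generate_scan(truth: FieldMap, sensor: SensorModel,
                  misalignment: tuple[int, int] = (0, 0),
                  seed: int = 0, condition: str = "active") -> ScanRecord:
    """One synthetic scan: shifted truth + offset + averaged read noise.

    Each grid point is the mean of ``sensor.n_averages`` independent vector
    reads; the output is fully reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    di, dj = misalignment
    base = _shift_with_edge_clamp(truth.values, di, dj)
    base = np.nan_to_num(base) + np.asarray(sensor.offset, dtype=float)
    if sensor.noise_sigma > 0:
        noise = rng.normal(0.0, sensor.noise_sigma,
                           size=(sensor.n_averages,) + base.shape)
        values = base + noise.mean(axis=0)
    else:
        values = base
    payload = replace(truth, values=values, mask=None)
    current = 0.0 if condition == "control" else truth.excitation.current
    return ScanRecord(payload=payload, condition=condition, current=current,
                      n_averages=sensor.n_averages, seed=seed,
                      provenance=f"synthetic rig (shift {di},{dj})")


def _sham_filaments(device, current: float, strand_offset: float,
                    subdivisions: int) -> list:
    """Bifilar sham model for any filament device: the full winding split
    into two half-strength strands displaced axially by the strand offset,
    driven anti-parallel."""
    drive = DriveCondition(current=current, mode="active")
    fils = bs.device_filaments(device, drive, subdivisions, subdivisions)
    half = strand_offset / 2.0
    out = []
    for f in fils:
        out.append(replace(f, axial_position=f.axial_position - half,
                           current=0.5 * f.current))
        out.append(replace(f, axial_position=f.axial_position + half,
                           current=-0.5 * f.current))
    return out


def generate_condition_set(device, sensor: SensorModel, seed: int,
                           current: float = 1.0, plane: str = "XZ",
                           extent=(0.06, 0.06), step: float = 0.5e-3,
                           origin=(0.0, 0.0, 0.0),
                           strand_offset: float = 0.9e-3,
                           misalignment: tuple[int, int] = (0, 0),
                           subdivisions: int = 8) -> dict[str, ScanRecord]:
    """Active / sham / control scans of a device on a shared grid at 1 A.

    Active truth comes from the filament forward model, sham truth from the
    bifilar anti-parallel residual at the given strand offset, control truth
    is identically zero (offset + noise only).  Sub-seeds are derived from
    ``seed`` so the three conditions have independent noise.
    """
    drive = DriveCondition(current=current, mode="active")
    fils_active = bs.device_filaments(device, drive, subdivisions, subdivisions)
    truth_active = bs.field_map_from_filaments(fils_active, plane, extent,
                                               step, drive, origin)
    fils_sham = _sham_filaments(device, current, strand_offset, subdivisions)
    truth_sham = bs.field_map_from_filaments(
        fils_sham, plane, extent, step,
        DriveCondition(current=current, mode="sham"), origin)
    truth_control = replace(truth_active,
                            values=np.zeros_like(truth_active.values),
                            excitation=DriveCondition(current=0.0, mode="off"),
                            mask=None)

    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    return {
        "active": generate_scan(truth_active, sensor, misalignment, sub[0], "active"),
        "sham": generate_scan(truth_sham, sensor, misalignment, sub[1], "sham"),
        "control": generate_scan(truth_control, sensor, misalignment, sub[2], "control"),
    }


def generate_thermal_series(params: ThermalParams, current: float,
                            resistance: float, noise_sigma: float = 0.0,
                            seed: int = 0, duration_cap: float = 3600.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """1 Hz synthetic coil-temperature log, truncated at the safety limit.

    Samples the lumped-model trajectory plus Gaussian noise until the first
    sample at or above the temperature limit (inclusive) or the duration cap.
    """
    t, T = temperature_trajectory(current, resistance, params, duration_cap,
                                  step=1.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        T = T + rng.normal(0.0, noise_sigma, size=T.shape)
    over = np.nonzero(T >= params.temperature_limit)[0]
    if len(over):
        end = over[0] + 1
        t, T = t[:end], T[:end]
    return t, T
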