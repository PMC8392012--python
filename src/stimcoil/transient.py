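"""Switching transients and Joule-heating operating limits.

The stimulation is DC, but switching it on or off ramps the current through
the series RL circuit, giving a 10%-90% rise/fall time t_r = (L/R) ln 9 and a
transient induced electric field estimated from Faraday's law over that
transition (delta B = 0.8 * B_steady).  Coil heating follows a first-order
lumped thermal model T(t) = T_amb + I^2 R R_th (1 - exp(-t / (R_th C_th))),
which yields the exponential maximum-operating-time versus current behaviour
observed on the bench; R_th and C_th are per-device fixture parameters, not
measured constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError

LN9 = math.log(9.0)


@dataclass(frozen=True)
class CircuitParams:
    """Series resistance (ohm) and inductance (H) of a wound coil."""

    resistance: float
    inductance: float

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ValueError("resistance must be positive")
        if self.inductance < 0:
            raise ValueError("inductance must be >= 0")


@dataclass(frozen=True)
class TransientEstimate:
    """Rise/fall time and the induced E-field during the transition."""

    rise_time: float
    fall_time: float
    induced_efield: float
    geometry_factor: float

    def __post_init__(self) -> None:
        if self.induced_efield < 0:
            raise ValueError("induced E-field must be >= 0")
        if self.rise_time != self.fall_time:
            raise ValueError("RL rise and fall times are equal by construction")


@dataclass(frozen=True)
class ThermalParams:
    """Lumped thermal model parameters.

    thermal_resistance : K/W, winding-to-ambient.
    thermal_capacitance : J/K, lumped heat capacity of the winding.
    ambient : degC.  temperature_limit : degC (safety cutoff, default 75).
    """

    thermal_resistance: float
    thermal_capacitance: float
    ambient: float = 22.0
    temperature_limit: float = 75.0

    def __post_init__(self) -> None:
        if self.thermal_resistance <= 0 or self.thermal_capacitance <= 0:
            raise ValueError("thermal resistance and capacitance must be positive")
        if self.temperature_limit <= self.ambient:
            raise ValueError("temperature limit must exceed ambient")

    @property
    def time_constant(self) -> float:
        return self.thermal_resistance * self.thermal_capacitance


def rise_time(params: CircuitParams) -> float:
    """10%-90% rise (= fall) time of a step through a series RL circuit."""
    if params.resistance == 0:
        raise ZeroDivisionError("rise time undefined for zero resistance")
    return params.inductance / params.resistance * LN9


def induced_efield(b_steady: float, rise_time_s: float,
                   geometry_factor: float = 1.0) -> float:
    """Faraday-law estimate of the transient E-field at the target.

    E = geometry_factor * (0.8 * B_steady) / t_r, where 0.8*B spans the
    10%-90% transition.  The default geometry factor of 1 m reproduces the
    platform's reporting convention of quoting dB/dt directly in V/m; the
    factor is exposed so a physical loop radius (E = (a/2) dB/dt for a loop
    of radius a) can be substituted.
    """
    if b_steady < 0 or geometry_factor < 0:
        raise ValueError("b_steady and geometry_factor must be >= 0")
    if rise_time_s <= 0:
        raise ZeroDivisionError("rise time must be positive")
    return geometry_factor * 0.8 * b_steady / rise_time_s


def transient_estimate(params: CircuitParams, b_steady: float,
                       geometry_factor: float = 1.0) -> TransientEstimate:
    """Bundle rise/fall time and induced E-field for one coil."""
    tr = rise_time(params)
    return TransientEstimate(rise_time=tr, fall_time=tr,
                             induced_efield=induced_efield(b_steady, tr,
                                                           geometry_factor),
                             geometry_factor=geometry_factor)


def temperature_trajectory(current: float, resistance: float,
                           params: ThermalParams, duration: float,
                           step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """First-order lumped heating response sampled on a time grid.

    Returns (times, temperatures in degC); T(0) = ambient and the asymptote
    is ambient + I^2 R R_th.
    """
    if current < 0 or resistance <= 0 or duration <= 0 or step <= 0:
        raise ValueError("inputs must be positive (current >= 0)")
    t = np.arange(0.0, duration + step / 2, step)
    rise = current ** 2 * resistance * params.thermal_resistance
    T = params.ambient + rise * (1.0 - np.exp(-t / params.time_constant))
    return t, T


def time_to_limit(current: float, resistance: float,
                  params: ThermalParams) -> float:
    """Time (s) until the winding reaches the temperature limit.

    Closed form t* = -tau ln(1 - dT_lim / (I^2 R R_th)); returns math.inf
    when the steady-state rise stays below the limit (unbounded operation).
    """
    if current < 0 or resistance <= 0:
        raise ValueError("current must be >= 0 and resistance positive")
    dT_lim = params.temperature_limit - params.ambient
    rise = current ** 2 * resistance * params.thermal_resistance
    if rise <= dT_lim:
        return math.inf
    return -params.time_constant * math.log(1.0 - dT_lim / rise)


def fit_operating_time_curve(currents, times) -> tuple[float, float, np.ndarray]:
    """Least-squares fit of t = a * exp(-b * I) to operating-time data.

    The fit is linear in log space with unit weights.  Returns
    (amplitude a, decay rate b, residuals of log t).  Requires at least three
    bounded, positive times.
    """
    I = np.asarray(currents, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(t)
    I, t = I[ok], t[ok]
    if len(t) < 3:
        raise DataError("need at least three bounded operating-time points")
    if np.any(t <= 0):
        raise DataError("operating times must be positive")
    logt = np.log(t)
    slope, intercept = np.polyfit(I, logt, 1)
    resid = logt - (slope * I + intercept)
    return float(np.exp(intercept)), float(-slope), resid
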