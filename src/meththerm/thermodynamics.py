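"""Body-temperature dynamics driven by the SPN output.

The core ODE is first-order and linear,

    tau_T dT/dt = P_SPN(t) - (T - T0),

so temperature relaxes toward T0 + P_SPN with time constant tau_T
(~89 min): the steady state under a constant drive A is simply T0 + A.

Integration uses classical RK4 with a fixed step (default 0.1 min).  Because
the ODE is linear in T, each RK4 step is an affine map
T_{k+1} = A*T_k + c_k whose coefficients depend only on the precomputed
drive samples; the recursion is evaluated at C speed with
``scipy.signal.lfilter``, which makes MCMC over the full model cheap.  The
stress input jumps at the injection times; those instants are kept on step
boundaries and the drive is sampled one-sidedly (right-limit at the left
node of a step, left-limit at the right node) so RK4 never integrates
across a discontinuity and retains its accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .circuit import CircuitParams, spn_drive
from .pharmacokinetics import (
    InjectionSchedule,
    PKParams,
    meth_concentration,
    stress_input,
)

__all__ = [
    "ThermoParams",
    "TemperatureTrajectory",
    "simulate_temperature",
    "steady_state_temperature",
    "integrate_linear_drive",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class ThermoParams:
    """Temperature time constant (min) and baseline body temperature (degC)."""

    tau_T: float = 89.2
    T0: float = 37.0

    def __post_init__(self) -> None:
        if not self.tau_T > 0:
            raise ValueError("tau_T must be strictly positive")
        if not 30.0 <= self.T0 <= 42.0:
            raise ValueError("T0 outside the physiological window [30, 42] degC")


@dataclass(frozen=True)
class TemperatureTrajectory:
    times: np.ndarray   # minutes
    temp: np.ndarray    # degC

    def __post_init__(self) -> None:
        if len(self.times) != len(self.temp):
            raise ValueError("times and temp must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def steady_state_temperature(drive: float, thermo: ThermoParams) -> float:
    """Equilibrium temperature under a constant SPN drive (degC)."""
    return thermo.T0 + drive


def integrate_linear_drive(p_left, p_mid, p_right, thermo: ThermoParams,
                           dt: float, x0: float = 0.0) -> np.ndarray:
    """Integrate tau_T x' = P(t) - x by fixed-step RK4, vectorized.

    ``p_left``/``p_right`` are the drive at the step nodes sampled as
    right/left limits (length N); ``p_mid`` at step midpoints (length N-1).
    Returns the deviation x = T - T0 at the N nodes, starting from ``x0``.
    """
    p_left = np.asarray(p_left, float)
    p_right = np.asarray(p_right, float)
    p_mid = np.asarray(p_mid, float)
    n = p_left.size
    if p_right.size != n or p_mid.size != n - 1:
        raise ValueError("drive arrays have inconsistent lengths")
    if not (np.all(np.isfinite(p_left)) and np.all(np.isfinite(p_mid))
            and np.all(np.isfinite(p_right))):
        raise ValueError("non-finite drive")
    tau = thermo.tau_T

    def rk4(x, p0, pm, p1):
        k1 = (p0 - x) / tau
        k2 = (pm - (x + 0.5 * dt * k1)) / tau
        k3 = (pm - (x + 0.5 * dt * k2)) / tau
        k4 = (p1 - (x + dt * k3)) / tau
        return x + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0

    # homogeneous multiplier and per-step forcing of the affine step map
    a_coef = rk4(1.0, 0.0, 0.0, 0.0)
    c = rk4(0.0, p_left[:-1], p_mid, p_right[1:])
    x = np.empty(n)
    x[0] = x0
    if n > 1:
        y = lfilter([1.0], [1.0, -a_coef], c)  # y_k = c_k + a*y_{k-1}
        x[1:] = y
        if x0 != 0.0:
            x[1:] += x0 * a_coef ** np.arange(1, n)
    return x


def _drive_arrays(schedule: InjectionSchedule, circuit_params: CircuitParams,
                  pk: PKParams, t_nodes: np.ndarray):
    """Drive at step nodes (right- and left-limit) and midpoints."""
    t_mid = 0.5 * (t_nodes[:-1] + t_nodes[1:])
    conc_nodes = meth_concentration(t_nodes - schedule.meth_time,
                                    schedule.meth_dose, pk)
    conc_mid = meth_concentration(t_mid - schedule.meth_time,
                                  schedule.meth_dose, pk)
    s_right = sum(stress_input(t_nodes, t0, pk.tau_s, include_onset=True)
                  for t0 in schedule.stress_times)
    s_left = sum(stress_input(t_nodes, t0, pk.tau_s, include_onset=False)
                 for t0 in schedule.stress_times)
    s_mid = sum(stress_input(t_mid, t0, pk.tau_s) for t0 in schedule.stress_times)
    p_left = spn_drive(conc_nodes, s_right, circuit_params)
    p_right = spn_drive(conc_nodes, s_left, circuit_params)
    p_mid = spn_drive(conc_mid, s_mid, circuit_params)
    return p_left, p_mid, p_right


def simulate_temperature(schedule: InjectionSchedule,
                         circuit_params: CircuitParams,
                         pk: PKParams,
                         thermo: ThermoParams,
                         t_grid,
                         dt: float = 0.1) -> TemperatureTrajectory:
    """Temperature trajectory on ``t_grid`` starting from T0 at t_grid[0].

    The internal integration grid runs from t_grid[0] with step ``dt``;
    injection times are snapped onto it by construction of the experimental
    protocol (integer injection times, dt dividing their offsets).  Output
    is linearly interpolated onto the requested grid.  Deterministic.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if not dt > 0:
        raise ValueError("dt must be positive")
    n_steps = int(np.ceil((t_grid[-1] - t_grid[0]) / dt - 1e-9))
    t_nodes = t_grid[0] + dt * np.arange(n_steps + 1)
    p_left, p_mid, p_right = _drive_arrays(schedule, circuit_params, pk, t_nodes)
    x = integrate_linear_drive(p_left, p_mid, p_right, thermo, dt)
    if not np.all(np.isfinite(x)):
        raise RuntimeError("temperature integration produced non-finite values")
    temp = thermo.T0 + np.interp(t_grid, t_nodes, x)
    return TemperatureTrajectory(times=t_grid, temp=temp)


def write_trajectory(path, traj: TemperatureTrajectory) -> None:
    """Write a trajectory as delimited text with columns time_min, temp_c."""
    pd.DataFrame({"time_min": traj.times, "temp_c": traj.temp}).to_csv(
        path, index=False
    )


def read_trajectory(path) -> TemperatureTrajectory:
    df = pd.read_csv(path)
    return TemperatureTrajectory(
        times=df["time_min"].to_numpy(float), temp=df["temp_c"].to_numpy(float)
    )
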