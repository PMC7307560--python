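"""Predator-prey ODE model for ciliate microcosm boom-bust cycles.

The system couples logistic-form prey growth to a type-II functional
response with mutual interference among predators, and a predator
mortality rate that relaxes exponentially as prey become abundant:

    dR/dt = (r - r_slope * R) * R - f(R, C) * C
    dC/dt = e * f(R, C) * C - C * d * exp(-R * C_d)

with the per-predator consumption rate

    f(R, C) = a * R / (1 + a * h * R + m * max(C - c_offset, 0)).

``R`` is prey density and ``C`` predator density, both in individuals
per mL; time is in days.  ``c_offset`` is the density of a single
predator in the dish (1/6 per mL for a 6-mL dish), so interference
vanishes when only one predator is present.  The interference term is
clamped at zero below ``c_offset`` so that the denominator never drops
below ``1 + a*h*R``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "ModelParams",
    "SystemState",
    "Trajectory",
    "functional_response",
    "predator_mortality_rate",
    "carrying_capacity",
    "derivatives",
    "solve_trajectory",
]

#: The eight rate parameters, in canonical order.  ``c_offset`` is a
#: geometric constant of the dish, not a rate, and is kept separate.
PARAM_NAMES = ("r", "r_slope", "a", "h", "m", "e", "d", "C_d")

#: One predator in a 6-mL dish, expressed per mL.
DEFAULT_C_OFFSET = 1.0 / 6.0


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of the predator-prey system.

    Attributes
    ----------
    r : float
        Prey maximum per-capita growth rate (day^-1).
    r_slope : float
        Decline of prey per-capita growth per unit prey density
        (mL individual^-1 day^-1); equals ``r / K`` for carrying
        capacity ``K``.
    a : float
        Space clearance rate (mL predator^-1 day^-1).
    h : float
        Handling time (days per prey item); sets the saturation
        ceiling ``1/h`` of the functional response.
    m : float
        Mutual interference coefficient (mL predator^-1).
    e : float
        Conversion efficiency (predators produced per prey consumed).
    d : float
        Predator maximum per-capita mortality (day^-1).
    C_d : float
        Prey-density scale of the mortality decline (mL individual^-1).
    c_offset : float
        Density of one predator in the dish (individuals mL^-1);
        1/6 (displayed 0.167) for the 6-mL dish.
    """

    r: float
    r_slope: float
    a: float
    h: float
    m: float
    e: float
    d: float
    C_d: float
    c_offset: float = DEFAULT_C_OFFSET

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name!r} must be >= 0, got {v!r}")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: time (days) and densities (per mL)."""

    t: float
    R: float
    C: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and math.isfinite(self.R) and math.isfinite(self.C)):
            raise ValueError("state components must be finite")
        if self.R < 0 or self.C < 0:
            raise ValueError(f"densities must be >= 0, got R={self.R}, C={self.C}")


@dataclass
class Trajectory:
    """Densities along a time grid, with solver diagnostics.

    ``success`` is False when the integrator stopped before reaching the
    end of the grid; ``failure_time`` then holds the last time reached
    and the arrays are truncated to the solved portion.
    """

    times: np.ndarray
    R_values: np.ndarray
    C_values: np.ndarray
    success: bool = True
    failure_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.R_values = np.asarray(self.R_values, dtype=float)
        self.C_values = np.asarray(self.C_values, dtype=float)
        if not (len(self.times) == len(self.R_values) == len(self.C_values)):
            raise ValueError("times, R_values and C_values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def _check_densities(R: float, C: float) -> None:
    if not (np.isfinite(R) and np.isfinite(C)):
        raise ValueError("densities must be finite")
    if R < 0 or C < 0:
        raise ValueError(f"densities must be >= 0, got R={R}, C={C}")


def functional_response(params: ModelParams, R: float, C: float) -> float:
    """Per-predator consumption rate (prey predator^-1 day^-1).

    Type-II response with mutual interference; the interference term
    ``m * (C - c_offset)`` is clamped at zero when fewer predators than
    one per dish are present.  Zero at ``R = 0``; bounded by ``1/h``.
    """
    _check_densities(R, C)
    interference = params.m * max(C - params.c_offset, 0.0)
    return params.a * R / (1.0 + params.a * params.h * R + interference)


def predator_mortality_rate(params: ModelParams, R: float) -> float:
    """Per-capita predator mortality ``d * exp(-R * C_d)`` (day^-1).

    Equals ``d`` when prey are absent and declines exponentially with
    prey density.
    """
    if not np.isfinite(R):
        raise ValueError("prey density must be finite")
    if R < 0:
        raise ValueError(f"prey density must be >= 0, got {R}")
    return params.d * math.exp(-R * params.C_d)


def carrying_capacity(params: ModelParams) -> float:
    """Prey carrying capacity ``K = r / r_slope`` (individuals mL^-1).

    Returns ``inf`` when ``r_slope`` is zero and ``r > 0`` (no finite
    carrying capacity), and 0 when ``r`` is zero.
    """
    if params.r == 0:
        return 0.0
    if params.r_slope == 0:
        return math.inf
    return params.r / params.r_slope


def derivatives(params: ModelParams, state: SystemState) -> tuple[float, float]:
    """Right-hand side (dR/dt, dC/dt) at the given state."""
    R, C = state.R, state.C
    f = functional_response(params, R, C)
    dR = (params.r - params.r_slope * R) * R - f * C
    dC = params.e * f * C - C * predator_mortality_rate(params, R)
    return dR, dC


def _rhs(params: ModelParams):
    """Vectorised RHS closure for the integrator.

    Sub-individual and transiently negative densities are tolerated
    here (the solver may overshoot); negatives are treated as zero for
    the rate evaluation so the vector field stays well defined.
    """
    r, r_slope, a, h, m = params.r, params.r_slope, params.a, params.h, params.m
    e, d, C_d, c_off = params.e, params.d, params.C_d, params.c_offset

    def rhs(t: float, y: np.ndarray) -> list[float]:
        R = max(y[0], 0.0)
        C = max(y[1], 0.0)
        f = a * R / (1.0 + a * h * R + m * max(C - c_off, 0.0))
        dR = (r - r_slope * R) * R - f * C
        dC = e * f * C - C * d * math.exp(-min(R * C_d, 700.0))
        return [dR, dC]

    return rhs


def solve_trajectory(
    params: ModelParams,
    initial: SystemState,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the system over ``t_grid`` starting from ``initial``.

    The default solver is stiff-capable (LSODA) with tight tolerances:
    the boom-bust dynamics have sharp transitions once prey collapse
    and the mortality term switches on.  Densities are clipped to >= 0
    at each output time.  Integrator failure is reported through the
    ``Trajectory`` diagnostics (partial solution returned) rather than
    raised, because profile-likelihood scans must survive it.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if abs(t_grid[0] - initial.t) > 1e-12:
        raise ValueError(f"t_grid must start at initial.t={initial.t}, got {t_grid[0]}")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")

    if len(t_grid) == 1:
        return Trajectory(t_grid, [initial.R], [initial.C])

    sol = solve_ivp(
        _rhs(params),
        (t_grid[0], t_grid[-1]),
        [initial.R, initial.C],
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    R = np.clip(sol.y[0], 0.0, None)
    C = np.clip(sol.y[1], 0.0, None)
    if sol.success and len(sol.t) == len(t_grid):
        return Trajectory(t_grid, R, C)
    failure_time = float(sol.t[-1]) if len(sol.t) else float(t_grid[0])
    return Trajectory(sol.t, R, C, success=False, failure_time=failure_time)


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV (time, prey_density, pred_density)."""
    import pandas as pd

    pd.DataFrame(
        {
            "time": traj.times,
            "prey_density": traj.R_values,
            "pred_density": traj.C_values,
        }
    ).to_csv(path, index=False)
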