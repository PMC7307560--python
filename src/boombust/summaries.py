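"""Cycle-shape metrics and single-parameter sensitivity contrasts.

The microcosm dynamics are a single boom-bust cycle: prey boom first,
the predator peak follows, and the predator then declines to
functional extinction (below one individual per dish).  The metrics
here operationalize amplitude (peak density), phase (peak times and
lag) and time to extinction; "period" is reported via the cycle
duration since only one cycle exists before deterministic extinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DEFAULT_C_OFFSET, ModelParams, PARAM_NAMES, SystemState, Trajectory, solve_trajectory

__all__ = ["CycleSummary", "SensitivityContrast", "cycle_metrics", "parameter_contrast", "generation_counts"]


@dataclass(frozen=True)
class CycleSummary:
    """Shape descriptors of one boom-bust cycle.

    Extinction times are None when the species never falls below the
    functional-zero threshold after its peak; ``cycle_duration`` is the
    predator extinction time (single-cycle proxy for the period).
    """

    prey_peak_density: float
    pred_peak_density: float
    prey_peak_time: float
    pred_peak_time: float
    peak_lag: float
    prey_extinction_time: float | None
    pred_extinction_time: float | None
    cycle_duration: float | None


@dataclass
class SensitivityContrast:
    """Min/mean/max contrast for one focal parameter.

    ``mean_set`` carries the across-temperature mean of every
    parameter and is identical across focal parameters within one
    analysis; ``min_set`` / ``max_set`` replace only the focal
    parameter by its across-temperature extreme.
    """

    focal: str
    min_set: ModelParams
    mean_set: ModelParams
    max_set: ModelParams
    min_traj: Trajectory
    mean_traj: Trajectory
    max_traj: Trajectory

    @property
    def trajectories(self) -> dict[str, Trajectory]:
        return {"min": self.min_traj, "mean": self.mean_traj, "max": self.max_traj}


def _extinction_time(times: np.ndarray, values: np.ndarray, peak_idx: int, threshold: float):
    """First time after the peak at which the density is below the
    threshold and never rises to it again."""
    below = values < threshold
    for i in range(peak_idx + 1, len(values)):
        if below[i] and not np.any(values[i:] >= threshold):
            return float(times[i])
    return None


def cycle_metrics(traj: Trajectory, extinction_threshold: float = DEFAULT_C_OFFSET) -> CycleSummary:
    """Summarize amplitude, peak timing and extinction of a trajectory.

    Peak time is the earliest time attaining the species maximum;
    extinction is crossing below ``extinction_threshold`` (default one
    individual per dish) for good.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    ip = int(np.argmax(traj.R_values))
    ic = int(np.argmax(traj.C_values))
    prey_ext = _extinction_time(traj.times, traj.R_values, ip, extinction_threshold)
    pred_ext = _extinction_time(traj.times, traj.C_values, ic, extinction_threshold)
    return CycleSummary(
        prey_peak_density=float(traj.R_values[ip]),
        pred_peak_density=float(traj.C_values[ic]),
        prey_peak_time=float(traj.times[ip]),
        pred_peak_time=float(traj.times[ic]),
        peak_lag=float(traj.times[ic] - traj.times[ip]),
        prey_extinction_time=prey_ext,
        pred_extinction_time=pred_ext,
        cycle_duration=pred_ext,
    )


def _mean_params(sets: list[ModelParams]) -> ModelParams:
    vals = {n: float(np.mean([getattr(p, n) for p in sets])) for n in PARAM_NAMES}
    vals["c_offset"] = sets[0].c_offset
    return ModelParams(**vals)


def parameter_contrast(
    fitted_sets: dict[str, ModelParams] | list[ModelParams],
    focal: str,
    initial: SystemState,
    horizon: float = 18.0,
    n_points: int = 721,
) -> SensitivityContrast:
    """Solve the model under min/mean/max values of one parameter.

    The mean set takes the across-temperature mean of every parameter;
    the min and max sets swap in the focal parameter's extreme fitted
    value while keeping all other parameters at their means.  Note the
    extremes are extremes across fitted sets, which need not coincide
    with the extremes of temperature.
    """
    sets = list(fitted_sets.values()) if isinstance(fitted_sets, dict) else list(fitted_sets)
    if len(sets) < 2:
        raise ValueError("need at least two fitted parameter sets")
    if focal not in PARAM_NAMES:
        raise ValueError(f"unknown focal parameter {focal!r}")
    mean_set = _mean_params(sets)
    focal_vals = [getattr(p, focal) for p in sets]
    min_set = mean_set.replace(**{focal: min(focal_vals)})
    max_set = mean_set.replace(**{focal: max(focal_vals)})
    grid = np.linspace(initial.t, initial.t + horizon, n_points)
    return SensitivityContrast(
        focal=focal,
        min_set=min_set,
        mean_set=mean_set,
        max_set=max_set,
        min_traj=solve_trajectory(min_set, initial, grid),
        mean_traj=solve_trajectory(mean_set, initial, grid),
        max_traj=solve_trajectory(max_set, initial, grid),
    )


def generation_counts(
    params: ModelParams, duration: float, literal_e_over_h: bool = False
) -> tuple[float, float]:
    """Approximate (predator, prey) generation counts over a duration.

    Prey generation time is 1/r, so prey generations = duration * r.
    The predator generation time is taken as h/e days by default
    (handling time per prey over predators produced per prey, which
    has units of time); ``literal_e_over_h=True`` instead uses e/h as
    the generation time, the alternative convention in which the ratio
    is read as a rate.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0:
        return (0.0, 0.0)
    if params.r <= 0 or params.h <= 0 or params.e <= 0:
        raise ValueError("generation counts need r, h and e > 0")
    prey = duration * params.r
    gen_time = (params.e / params.h) if literal_e_over_h else (params.h / params.e)
    pred = duration / gen_time
    return (pred, prey)
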