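"""Synthetic microcosm datasets with the structure of the experiment.

Emulates six temperature treatments (17-31 degC) of 6-mL Petri-dish
microcosms inoculated with ~30 prey/mL and 2 predators per dish,
sampled daily for five days and then every couple of days to day 18,
with replicate-level multiplicative observation noise and
across-replicate averaging.  Everything downstream (fitting,
uncertainty, recovery, summaries) is testable against these datasets
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import TimeSeries
from .model import DEFAULT_C_OFFSET, ModelParams, SystemState, Trajectory, solve_trajectory

__all__ = [
    "ExperimentDesign",
    "observation_schedule",
    "sample_trajectory",
    "add_observation_noise",
    "generate_dataset",
    "fixture_parameter_sets",
    "simulate_design",
]

#: Temperatures of the experiment, in degC.
DEFAULT_TEMPERATURES = (17.0, 20.0, 23.0, 25.0, 27.0, 31.0)

#: Half of one individual per dish, used as the zero-offset delta in
#: log transforms of densities that can be exactly zero.
ZERO_OFFSET = DEFAULT_C_OFFSET / 2.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Structure of one microcosm experiment.

    Defaults reproduce the study conditions: 6-mL dishes, initial prey
    density 30/mL, two predators added per dish (C0 = 0.333/mL), daily
    sampling on days 1-5 then every second day plus the terminal day
    18, six replicates per temperature, and log-scale observation
    noise with SD ``noise_sigma``.
    """

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    dish_volume: float = 6.0
    prey_initial_density: float = 30.0
    predator_initial_count: float = 2.0
    observation_days: tuple[float, ...] | None = None
    horizon: float = 18.0
    n_replicates: int = 6
    noise_sigma: float = 0.1
    seed: int = 0
    truncate: bool = True

    def __post_init__(self) -> None:
        if self.dish_volume <= 0:
            raise ValueError("dish_volume must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.observation_days is not None:
            days = np.asarray(self.observation_days, dtype=float)
            if len(days) and not np.all(np.diff(days) > 0):
                raise ValueError("observation_days must be strictly increasing")
            if len(days) and days[-1] > self.horizon:
                raise ValueError("observation_days exceed the horizon")

    @property
    def c_offset(self) -> float:
        """Density of one predator in the dish (per mL)."""
        return 1.0 / self.dish_volume

    @property
    def initial_state(self) -> SystemState:
        return SystemState(
            t=0.0,
            R=self.prey_initial_density,
            C=self.predator_initial_count / self.dish_volume,
        )


def observation_schedule(design: ExperimentDesign) -> np.ndarray:
    """Observation days: daily on days 1-5, then every 2 days plus the
    terminal day, capped at the design horizon."""
    if design.observation_days is not None:
        return np.asarray(design.observation_days, dtype=float)
    horizon = design.horizon
    if horizon < 1:
        return np.array([], dtype=float)
    days = [float(d) for d in range(1, 6) if d <= horizon]
    d = 7.0
    while d < horizon:
        days.append(d)
        d += 2.0
    if horizon > days[-1]:
        days.append(float(horizon))
    return np.array(days, dtype=float)


def _truncate_species(times: np.ndarray, values: np.ndarray, zero_level: float) -> np.ndarray:
    """Blank (NaN) observations after the third consecutive functionally
    zero time point following the species' last positive observation."""
    out = values.copy()
    positive = np.flatnonzero(values >= zero_level)
    if len(positive) == 0:
        cut_from = 3  # keep only the first three (all-zero) observations
    else:
        cut_from = positive[-1] + 4  # last positive + three zero points
    if cut_from < len(out):
        out[cut_from:] = np.nan
    return out


def sample_trajectory(
    traj: Trajectory,
    times,
    truncate: bool = False,
    zero_level: float = DEFAULT_C_OFFSET,
) -> TimeSeries:
    """Evaluate a trajectory at observation times.

    Values are linearly interpolated from the trajectory grid.  With
    ``truncate=True`` each species' series is cut (set to NaN) after
    the third consecutive functionally-zero observation following its
    last positive one, mirroring the timespan used for fitting.
    """
    times = np.asarray(times, dtype=float)
    if len(times) and (times.min() < traj.times.min() - 1e-9 or times.max() > traj.times.max() + 1e-9):
        raise ValueError(
            f"requested times [{times.min()}, {times.max()}] outside trajectory "
            f"range [{traj.times.min()}, {traj.times.max()}]"
        )
    R = np.interp(times, traj.times, traj.R_values)
    C = np.interp(times, traj.times, traj.C_values)
    if truncate:
        R = _truncate_species(times, R, zero_level)
        C = _truncate_species(times, C, zero_level)
    return TimeSeries(times=times, R_obs=R, C_obs=C)


def add_observation_noise(
    series: TimeSeries,
    sigma: float,
    seed: int,
    scale: str = "log",
    delta: float = ZERO_OFFSET,
) -> TimeSeries:
    """Perturb each observed density with seeded Normal(0, sigma) noise.

    On the default ``log`` scale each density x becomes
    ``exp(ln(x + delta) + eps) - delta`` (about ``sigma``-proportional
    multiplicative noise), with ``delta`` a half-individual-per-dish
    offset so zeros stay finite; results are clipped at 0.  On the
    ``raw`` scale the draw is added to the density directly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if scale not in ("log", "raw"):
        raise ValueError(f"scale must be 'log' or 'raw', got {scale!r}")
    out = series.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for name in ("R_obs", "C_obs"):
        x = getattr(out, name)
        eps = rng.normal(0.0, sigma, size=len(x))
        mask = np.isfinite(x)
        if scale == "log":
            noisy = np.exp(np.log(x[mask] + delta) + eps[mask]) - delta
        else:
            noisy = x[mask] + eps[mask]
        x[mask] = np.clip(noisy, 0.0, None)
    return out


def simulate_design(
    params: ModelParams,
    design: ExperimentDesign,
    dense: bool = False,
) -> TimeSeries:
    """Noiseless sampled series for one parameter set under a design.

    ``dense=False`` samples at the observation schedule (with the
    design's truncation setting); the returned series records the day-0
    initial state.
    """
    schedule = observation_schedule(design)
    if len(schedule) == 0:
        raise ValueError("design has an empty observation schedule")
    init = design.initial_state
    grid = np.union1d(np.linspace(0.0, design.horizon, 721), schedule)
    traj = solve_trajectory(params, init, grid)
    if not traj.success:
        raise RuntimeError(f"integration failed at t={traj.failure_time} for {params}")
    series = sample_trajectory(
        traj, schedule, truncate=design.truncate, zero_level=design.c_offset
    )
    series.t0, series.R0, series.C0 = 0.0, init.R, init.C
    return series


def generate_dataset(
    params_by_temperature: dict[str, ModelParams],
    design: ExperimentDesign,
) -> list[TimeSeries]:
    """Full synthetic experiment: per temperature, ``n_replicates``
    noisy replicate series plus one across-replicate mean series with
    per-time SE = SD/sqrt(n).

    Pure function of (params, design, design.seed): replicate noise
    streams are sub-seeded deterministically.
    """
    from .io import average_replicates

    if not params_by_temperature:
        raise ValueError("params_by_temperature must not be empty")
    out: list[TimeSeries] = []
    ss = np.random.SeedSequence(design.seed)
    labels = list(params_by_temperature)
    child_seeds = ss.generate_state(len(labels) * design.n_replicates)
    k = 0
    for label in labels:
        base = simulate_design(params_by_temperature[label], design)
        base.temperature = str(label)
        reps: list[TimeSeries] = []
        for i in range(design.n_replicates):
            rep = add_observation_noise(base, design.noise_sigma, int(child_seeds[k]))
            rep.temperature = str(label)
            rep.replicate = str(i + 1)
            reps.append(rep)
            k += 1
        mean = average_replicates(reps)
        mean.temperature = str(label)
        out.extend(reps)
        out.append(mean)
    return out


# Synthetic stand-in parameter sets, one per temperature label.  These
# are NOT the study's fitted values (those are deposited externally);
# they are hand-tuned so that each set produces the qualitative
# dynamics of the experiment -- a single prey boom, a delayed predator
# peak, and predator functional extinction (below one individual per
# dish) by day 18 -- with time-to-extinction decreasing from the
# coldest to the warmest label.  e = 0.055 and C_d = 40 throughout,
# matching the fixed values of the final fitting protocol.
_FIXTURES: dict[str, dict[str, float]] = {
    "17": dict(r=0.90, r_slope=0.00145, a=0.18, h=0.052, m=0.020, e=0.055, d=0.80, C_d=40.0),
    "20": dict(r=1.10, r_slope=0.00180, a=0.20, h=0.049, m=0.025, e=0.055, d=0.85, C_d=40.0),
    "23": dict(r=1.30, r_slope=0.00215, a=0.24, h=0.046, m=0.030, e=0.055, d=0.95, C_d=40.0),
    "25": dict(r=1.45, r_slope=0.00242, a=0.28, h=0.044, m=0.030, e=0.055, d=1.10, C_d=40.0),
    "27": dict(r=1.60, r_slope=0.00267, a=0.33, h=0.042, m=0.035, e=0.055, d=1.25, C_d=40.0),
    "31": dict(r=1.50, r_slope=0.00250, a=0.40, h=0.040, m=0.030, e=0.055, d=1.50, C_d=40.0),
}


def fixture_parameter_sets(path=None) -> dict[str, ModelParams]:
    """Six synthetic stand-in parameter sets keyed by temperature label.

    Optionally load overrides from a JSON file mapping label ->
    {parameter: value}.
    """
    if path is not None:
        import json

        with open(path) as fh:
            raw = json.load(fh)
        return {str(k): ModelParams.from_dict(v) for k, v in raw.items()}
    return {label: ModelParams(**vals) for label, vals in _FIXTURES.items()}
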