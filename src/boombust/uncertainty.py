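"""Parameter uncertainty: profile-likelihood CIs with Hessian fallback.

The profile for a parameter steps its value away from the estimate on
a multiplicative (log-increment) grid — which keeps every candidate
bound positive — re-optimizing all other free parameters at each
step.  A confidence bound sits where the re-optimized chi2 exceeds
the base chi2 by a threshold; the default threshold of 1.0
corresponds to the ~68.5% (one standard deviation) interval for a
single parameter.  When the integrator fails before the threshold is
crossed the bound is reported at the last feasible grid value and
flagged, mirroring the practical limit of pushing parameters far from
the optimum in stiff boom-bust dynamics.  Where profiles are
unattainable, symmetric CIs from the finite-difference Hessian of the
deviance at the optimum are available as a fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import TimeSeries
from .fitting import FitResult, chi_squared, fit_model

__all__ = [
    "ProfileResult",
    "profile_likelihood",
    "profile_objective",
    "hessian_ci",
    "hessian_ci_objective",
    "DEFAULT_THRESHOLD",
    "DEFAULT_STEP_RATIO",
]

#: Delta-chi2 for the ~68.5% (one-SD) confidence interval.
DEFAULT_THRESHOLD = 1.0
#: Multiplicative grid step between profile points.
DEFAULT_STEP_RATIO = 1.05
#: Maximum profile steps per side.
DEFAULT_MAX_STEPS = 200

THRESHOLD_CROSSED = "threshold-crossed"
INTEGRATION_FAILURE = "integration-failure"
GRID_EXHAUSTED = "grid-exhausted"


@dataclass
class ProfileResult:
    """Chi-square profile of one parameter and the derived CI.

    ``grid`` and ``chi2_profile`` cover both directions, sorted by
    parameter value, and include the estimate itself.  ``bound_status``
    per side is one of ``threshold-crossed`` (CI bound interpolated at
    the crossing), ``integration-failure`` (bound clamped at the last
    feasible value) or ``grid-exhausted`` (profile stayed flat to the
    end of the grid).
    """

    name: str
    estimate: float
    base_chi2: float
    threshold: float
    grid: np.ndarray
    chi2_profile: np.ndarray
    ci_low: float
    ci_high: float
    low_status: str
    high_status: str

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "base_chi2": self.base_chi2,
            "threshold": self.threshold,
            "grid": list(map(float, self.grid)),
            "chi2_profile": list(map(float, self.chi2_profile)),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "low_status": self.low_status,
            "high_status": self.high_status,
        }


def _scan_direction(
    profile_chi2: Callable[[float], float],
    estimate: float,
    base_chi2: float,
    threshold: float,
    step_ratio: float,
    max_steps: int,
    up: bool,
):
    """Walk one direction until the chi2 excess crosses the threshold.

    Returns (grid values, chi2 values, bound, status).  The bound is
    log-linearly interpolated between the bracketing grid points at
    the crossing.
    """
    factor = step_ratio if up else 1.0 / step_ratio
    values: list[float] = []
    chi2s: list[float] = []
    prev_v, prev_chi2 = estimate, base_chi2
    v = estimate
    for _ in range(max_steps):
        v = v * factor
        chi2 = profile_chi2(v)
        if not math.isfinite(chi2):
            return values, chi2s, prev_v, INTEGRATION_FAILURE
        values.append(v)
        chi2s.append(chi2)
        if chi2 > base_chi2 + threshold:
            # interpolate the crossing on the log-parameter axis
            t = (base_chi2 + threshold - prev_chi2) / (chi2 - prev_chi2)
            bound = prev_v * (v / prev_v) ** t
            return values, chi2s, bound, THRESHOLD_CROSSED
        prev_v, prev_chi2 = v, chi2
    return values, chi2s, v, GRID_EXHAUSTED


def profile_objective(
    profile_chi2: Callable[[float], float],
    name: str,
    estimate: float,
    base_chi2: float,
    threshold: float = DEFAULT_THRESHOLD,
    step_ratio: float = DEFAULT_STEP_RATIO,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> ProfileResult:
    """Profile an arbitrary re-optimized deviance function.

    ``profile_chi2(value)`` must return the chi2 minimised over all
    nuisance parameters with the focal parameter pinned at ``value``
    (or +inf / NaN where the model cannot be evaluated).  This is the
    engine under :func:`profile_likelihood`; exposing it keeps the
    scanning logic testable against closed-form deviances.
    """
    if estimate <= 0:
        raise ValueError("profiling requires a positive estimate (log increments)")
    if step_ratio <= 1:
        raise ValueError("step_ratio must be > 1")
    up = _scan_direction(profile_chi2, estimate, base_chi2, threshold, step_ratio, max_steps, up=True)
    down = _scan_direction(profile_chi2, estimate, base_chi2, threshold, step_ratio, max_steps, up=False)
    grid = np.array(list(reversed(down[0])) + [estimate] + up[0])
    chi2s = np.array(list(reversed(down[1])) + [base_chi2] + up[1])
    return ProfileResult(
        name=name,
        estimate=estimate,
        base_chi2=base_chi2,
        threshold=threshold,
        grid=grid,
        chi2_profile=chi2s,
        ci_low=down[2],
        ci_high=up[2],
        low_status=down[3],
        high_status=up[3],
    )


def profile_likelihood(
    series: TimeSeries,
    base: FitResult,
    name: str,
    threshold: float = DEFAULT_THRESHOLD,
    step_ratio: float = DEFAULT_STEP_RATIO,
    max_steps: int = DEFAULT_MAX_STEPS,
    max_nfev: int = 200,
) -> ProfileResult:
    """Profile-likelihood CI for one free parameter of a fitted model.

    Each grid point refits all remaining free parameters, warm-started
    from the previous point's optimum (the profile is continuous, so
    warm starts track the ridge cheaply).
    """
    if name not in base.free:
        raise ValueError(f"parameter {name!r} is not free in the base fit")
    nuisance = tuple(n for n in base.free if n != name)
    estimate = getattr(base.params, name)
    warm = {True: base.params, False: base.params}  # per-direction warm start

    def make_profile_chi2(direction_up: bool):
        def profile_chi2(value: float) -> float:
            try:
                fit = fit_model(
                    series,
                    free=nuisance,
                    fixed_values={
                        **{n: getattr(base.params, n) for n in set(base.params.to_dict()) - set(nuisance) - {"c_offset"}},
                        name: value,
                    },
                    starts=0,
                    include_start=warm[direction_up].replace(**{name: value}),
                    c_offset=base.params.c_offset,
                    max_nfev=max_nfev,
                )
            except RuntimeError:
                return math.inf
            warm[direction_up] = fit.params
            return fit.chi2

        return profile_chi2

    up_fn = make_profile_chi2(True)
    down_fn = make_profile_chi2(False)

    up = _scan_direction(up_fn, estimate, base.chi2, threshold, step_ratio, max_steps, up=True)
    down = _scan_direction(down_fn, estimate, base.chi2, threshold, step_ratio, max_steps, up=False)
    grid = np.array(list(reversed(down[0])) + [estimate] + up[0])
    chi2s = np.array(list(reversed(down[1])) + [base.chi2] + up[1])
    return ProfileResult(
        name=name,
        estimate=estimate,
        base_chi2=base.chi2,
        threshold=threshold,
        grid=grid,
        chi2_profile=chi2s,
        ci_low=down[2],
        ci_high=up[2],
        low_status=down[3],
        high_status=up[3],
    )


def hessian_ci_objective(
    chi2_fn: Callable[[np.ndarray], float],
    estimates: np.ndarray,
    names: tuple[str, ...],
    threshold: float = DEFAULT_THRESHOLD,
    rel_step: float = 1e-4,
) -> dict[str, dict]:
    """Symmetric CIs from the Hessian of chi2/2 in log-parameter space.

    ``chi2_fn`` maps a natural-scale parameter vector to the deviance.
    Half-widths on the log scale are sqrt(threshold * diag(H^-1)) for
    H the Hessian of chi2/2 with respect to ln(parameters); bounds map
    back multiplicatively.  Parameters whose curvature row makes the
    Hessian non-invertible (or non-positive on the diagonal of the
    inverse) are flagged unavailable.
    """
    x = np.log(np.asarray(estimates, dtype=float))
    k = len(x)
    step = np.maximum(np.abs(x) * rel_step, rel_step)

    def f(z: np.ndarray) -> float:
        return 0.5 * chi2_fn(np.exp(z))

    f0 = f(x)
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step[i]
            ej[j] = step[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step[i] * step[j])

    out: dict[str, dict] = {}
    try:
        Hinv = np.linalg.inv(H)
        diag = np.diag(Hinv)
    except np.linalg.LinAlgError:
        diag = np.full(k, np.nan)
    for i, name in enumerate(names):
        var = diag[i]
        if not np.isfinite(var) or var <= 0:
            out[name] = {"available": False, "estimate": float(np.exp(x[i]))}
            continue
        half = math.sqrt(threshold * var)
        est = float(np.exp(x[i]))
        out[name] = {
            "available": True,
            "estimate": est,
            "ci_low": est * math.exp(-half),
            "ci_high": est * math.exp(half),
        }
    return out


def hessian_ci(
    series: TimeSeries,
    base: FitResult,
    threshold: float = DEFAULT_THRESHOLD,
    rel_step: float = 1e-4,
) -> dict[str, dict]:
    """Hessian-based symmetric CIs for every free parameter of a fit."""
    names = base.free
    if not names:
        raise ValueError("base fit has no free parameters")

    def chi2_fn(values: np.ndarray) -> float:
        params = base.params.replace(**dict(zip(names, values)))
        return chi_squared(params, series)

    estimates = np.array([getattr(base.params, n) for n in names])
    return hessian_ci_objective(chi2_fn, estimates, names, threshold, rel_step)
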