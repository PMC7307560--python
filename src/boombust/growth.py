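"""Predator-free exponential growth-rate estimation.

Prey growth in the control dishes is summarized by the two-point
exponential estimator r = ln(N4/N2)/2 between days 2 and 4 (the first
day is skipped because densities decline from inoculation to day 2),
computed per replicate so the across-replicate spread estimates the
error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthObservation", "exponential_growth_rate", "summarize_growth"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthObservation:
    """Densities of one control replicate at days 2 and 4 (per mL)."""

    N2: float
    N4: float
    replicate: str | None = None
    temperature: str | None = None

    def __post_init__(self) -> None:
        if not (self.N2 > 0 and self.N4 > 0):
            raise ValueError(
                f"N2 and N4 must be > 0 (got N2={self.N2}, N4={self.N4}); "
                "zero-density observations are excluded upstream"
            )


def exponential_growth_rate(obs: GrowthObservation) -> float:
    """Per-day growth rate r = ln(N4/N2)/2; exact for exponential
    growth over the two-day window, negative when the population
    declined."""
    return math.log(obs.N4 / obs.N2) / 2.0


def summarize_growth(
    observations: list[GrowthObservation],
) -> dict[str, dict[str, float | int | None]]:
    """Per-temperature mean and SE of replicate-level growth rates.

    SE is SD/sqrt(n) with the n-1 denominator in the SD; with a single
    replicate the SE is None (undefined) and the mean is that value.
    """
    if not observations:
        raise ValueError("no growth observations")
    groups: dict[str, list[float]] = {}
    for obs in observations:
        groups.setdefault(str(obs.temperature), []).append(exponential_growth_rate(obs))
    out: dict[str, dict[str, float | int | None]] = {}
    for label, rates in groups.items():
        n = len(rates)
        mean = float(np.mean(rates))
        se = float(np.std(rates, ddof=1) / math.sqrt(n)) if n > 1 else None
        out[label] = {"mean": mean, "se": se, "n": n}
    return out


def growth_observations_from_series(series_list) -> list[GrowthObservation]:
    """Extract day-2/day-4 prey observations from control time series.

    Series missing either day, or with a zero density at one of them,
    are skipped with a warning (the estimator is undefined there).
    """
    out = []
    for s in series_list:
        vals = {}
        for day in (2.0, 4.0):
            idx = np.flatnonzero(np.isclose(s.times, day))
            if len(idx) and np.isfinite(s.R_obs[idx[0]]):
                vals[day] = float(s.R_obs[idx[0]])
        if set(vals) != {2.0, 4.0}:
            log.warning("series %s/%s lacks day-2/4 prey densities; skipped", s.temperature, s.replicate)
            continue
        if vals[2.0] <= 0 or vals[4.0] <= 0:
            log.warning("series %s/%s has zero density at day 2 or 4; skipped", s.temperature, s.replicate)
            continue
        out.append(
            GrowthObservation(N2=vals[2.0], N4=vals[4.0], replicate=s.replicate, temperature=s.temperature)
        )
    return out
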