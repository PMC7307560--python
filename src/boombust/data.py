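"""Observed / sampled time-series container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """Densities of one prey/predator pair over observation days.

    Entries may be NaN where a species was not observed at a time
    point (e.g. after truncation of the fitted timespan); all arrays
    share one time grid.  ``replicate`` is a replicate id or the
    string ``"mean"`` for an across-replicate average, in which case
    ``R_se`` / ``C_se`` hold the standard error of the mean.

    ``R0`` / ``C0`` record the known initial densities at time ``t0``
    (day 0 inoculation); when absent, consumers fall back to the first
    observation as the initial state.
    """

    times: np.ndarray
    R_obs: np.ndarray
    C_obs: np.ndarray
    R_se: np.ndarray | None = None
    C_se: np.ndarray | None = None
    temperature: str | None = None
    replicate: str | None = None
    t0: float | None = None
    R0: float | None = None
    C0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.R_obs = np.asarray(self.R_obs, dtype=float)
        self.C_obs = np.asarray(self.C_obs, dtype=float)
        if self.R_se is not None:
            self.R_se = np.asarray(self.R_se, dtype=float)
        if self.C_se is not None:
            self.C_se = np.asarray(self.C_se, dtype=float)
        n = len(self.times)
        for name in ("R_obs", "C_obs", "R_se", "C_se"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != times length {n}")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("R_obs", "C_obs"):
            arr = getattr(self, name)
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"{name} contains negative densities")
        for name in ("R_se", "C_se"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"{name} contains negative standard errors")

    def __len__(self) -> int:
        return len(self.times)

    def initial_state(self):
        """Initial (t, R, C) for simulation: the recorded inoculation
        state when available, else the first observation."""
        from .model import SystemState

        if self.t0 is not None and self.R0 is not None and self.C0 is not None:
            return SystemState(t=self.t0, R=self.R0, C=self.C0)
        if len(self.times) == 0:
            raise ValueError("empty series has no initial state")
        R = self.R_obs[0] if np.isfinite(self.R_obs[0]) else 0.0
        C = self.C_obs[0] if np.isfinite(self.C_obs[0]) else 0.0
        return SystemState(t=float(self.times[0]), R=float(R), C=float(C))

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            times=self.times.copy(),
            R_obs=self.R_obs.copy(),
            C_obs=self.C_obs.copy(),
            R_se=None if self.R_se is None else self.R_se.copy(),
            C_se=None if self.C_se is None else self.C_se.copy(),
            temperature=self.temperature,
            replicate=self.replicate,
            t0=self.t0,
            R0=self.R0,
            C0=self.C0,
        )
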