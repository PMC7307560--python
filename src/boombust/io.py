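"""Readers, writers and configuration for the analysis pipeline.

The interchange format is a long-format CSV with columns
``day, temperature_C, replicate, species, density_per_ml`` and an
optional ``se`` column (blank for individual replicates); species is
``prey`` or ``predator`` and the across-replicate average carries the
replicate label ``mean``.  Parameter sets and fit results travel as
flat JSON keyed by symbol name; run configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import TimeSeries
from .model import ModelParams
from .synthetic import ExperimentDesign

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "average_replicates",
    "AnalysisConfig",
    "read_params_json",
    "write_params_json",
]

REQUIRED_COLUMNS = ("day", "temperature_C", "replicate", "species", "density_per_ml")
SPECIES = ("prey", "predator")


class SchemaError(ValueError):
    pass


class ValidationError(ValueError):
    pass


def _series_from_group(g: pd.DataFrame, temperature: str, replicate: str) -> TimeSeries:
    days = np.array(sorted(g["day"].unique()), dtype=float)
    n = len(days)
    arrays = {
        "R_obs": np.full(n, np.nan),
        "C_obs": np.full(n, np.nan),
        "R_se": np.full(n, np.nan),
        "C_se": np.full(n, np.nan),
    }
    idx = {d: i for i, d in enumerate(days)}
    for _, row in g.iterrows():
        i = idx[float(row["day"])]
        prefix = "R" if row["species"] == "prey" else "C"
        arrays[f"{prefix}_obs"][i] = row["density_per_ml"]
        if "se" in g.columns and pd.notna(row.get("se")):
            arrays[f"{prefix}_se"][i] = row["se"]
    has_se = np.any(np.isfinite(arrays["R_se"])) or np.any(np.isfinite(arrays["C_se"]))
    return TimeSeries(
        times=days,
        R_obs=arrays["R_obs"],
        C_obs=arrays["C_obs"],
        R_se=arrays["R_se"] if has_se else None,
        C_se=arrays["C_se"] if has_se else None,
        temperature=str(temperature),
        replicate=str(replicate),
    )


def read_timeseries_csv(
    path,
    column_map: dict[str, str] | None = None,
    exclude_replicates: list[tuple[str, str]] | None = None,
) -> list[TimeSeries]:
    """Read a long-format CSV into per-(temperature, replicate) series.

    ``column_map`` renames source columns to the canonical schema
    (e.g. ``{"Day": "day"}``); ``exclude_replicates`` drops listed
    (temperature, replicate) pairs, mirroring the exclusion of
    aberrant dishes from analysis.  Malformed rows are reported with
    their line numbers (header = line 1).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    # data rows start at line 2 (after the header)
    lines = df.index.to_numpy() + 2
    bad_species = ~df["species"].isin(SPECIES)
    if bad_species.any():
        raise ValidationError(
            f"unknown species on line(s) {lines[bad_species].tolist()}: "
            f"{sorted(df.loc[bad_species, 'species'].unique())}"
        )
    dens = pd.to_numeric(df["density_per_ml"], errors="coerce")
    non_numeric = dens.isna() & df["density_per_ml"].notna()
    if non_numeric.any():
        raise ValidationError(f"non-numeric density on line(s) {lines[non_numeric].tolist()}")
    negative = dens < 0
    if negative.any():
        raise ValidationError(f"negative density on line(s) {lines[negative.to_numpy()].tolist()}")
    df["density_per_ml"] = dens

    excl = {(str(t), str(r)) for t, r in (exclude_replicates or [])}
    out: list[TimeSeries] = []
    for (temp, rep), g in df.groupby(["temperature_C", "replicate"], sort=True):
        if (str(temp), str(rep)) in excl:
            continue
        out.append(_series_from_group(g, temp, rep))
    return out


def write_timeseries_csv(series_list: list[TimeSeries], path) -> None:
    """Write series to the long-format CSV (inverse of the reader)."""
    rows = []
    for s in series_list:
        for sp, obs, se in (("prey", s.R_obs, s.R_se), ("predator", s.C_obs, s.C_se)):
            for i, t in enumerate(s.times):
                if not np.isfinite(obs[i]):
                    continue
                rows.append(
                    {
                        "day": t,
                        "temperature_C": s.temperature,
                        "replicate": s.replicate,
                        "species": sp,
                        "density_per_ml": obs[i],
                        "se": se[i] if se is not None and np.isfinite(se[i]) else "",
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def average_replicates(replicates: list[TimeSeries]) -> TimeSeries:
    """Across-replicate mean series with per-time SE = SD/sqrt(n).

    The time grid is the union of replicate grids; a replicate
    contributes only where it was observed, so extinct or truncated
    dishes drop out of n at later days.  SE uses the n-1 SD
    denominator; identical replicates give SE exactly 0, and a time
    point observed by a single replicate gets SE 0 (no spread
    information, and downstream weighting floors the sigma anyway).
    """
    if not replicates:
        raise ValueError("no replicates to average")
    times = replicates[0].times
    for s in replicates[1:]:
        times = np.union1d(times, s.times)
    n = len(times)
    acc = {"R": [[] for _ in range(n)], "C": [[] for _ in range(n)]}
    for s in replicates:
        pos = np.searchsorted(times, s.times)
        for key, obs in (("R", s.R_obs), ("C", s.C_obs)):
            for j, i in enumerate(pos):
                if np.isfinite(obs[j]):
                    acc[key][i].append(obs[j])
    mean = {}
    se = {}
    for key in ("R", "C"):
        mean[key] = np.array([np.mean(v) if v else np.nan for v in acc[key]])
        se[key] = np.array(
            [
                (np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else (0.0 if v else np.nan)
                for v in acc[key]
            ]
        )
    first = replicates[0]
    return TimeSeries(
        times=times,
        R_obs=mean["R"],
        C_obs=mean["C"],
        R_se=se["R"],
        C_se=se["C"],
        temperature=first.temperature,
        replicate="mean",
        t0=first.t0,
        R0=first.R0,
        C0=first.C0,
    )


def write_params_json(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        fh.write(params.to_json())


def read_params_json(path) -> ModelParams:
    with open(path) as fh:
        return ModelParams.from_json(fh.read())


@dataclass
class AnalysisConfig:
    """Whole-pipeline configuration; round-trips through YAML."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    starts: int = 20
    fit_seed: int = 0
    fixed: dict[str, float] = field(default_factory=lambda: {"C_d": 40.0})
    profile_threshold: float = 1.0
    profile_step_ratio: float = 1.05
    extinction_threshold: float = 1.0 / 6.0
    exclude_replicates: list[list[str]] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["design"] = asdict(self.design)
        for key in ("temperatures", "observation_days"):
            if d["design"][key] is not None:
                d["design"][key] = list(d["design"][key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        design = d.pop("design", {})
        for key in ("temperatures", "observation_days"):
            if design.get(key) is not None:
                design[key] = tuple(design[key])
        return cls(design=ExperimentDesign(**design), **d)

    def content_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=list).encode()).hexdigest()[:12]


def provenance(config: AnalysisConfig | None = None, seed: int | None = None) -> dict:
    """Provenance block stamped into result JSON files."""
    from . import __version__

    return {
        "software": "boombust",
        "version": __version__,
        "seed": seed,
        "config_hash": config.content_hash() if config is not None else None,
    }
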