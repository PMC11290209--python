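"""Delimited-text readers/writers and run configuration.

Time series are CSV, UTF-8, header row. Two layouts are accepted: wide
(first column ``time_h``, one column per observable, units declared by a
column suffix such as ``fructose_mM`` or via an explicit unit map) and long
(``time_h,observable,value[,unit]``). Values are normalized to the internal
unit system on read (g L^-1 for analytes, mole fractions for gases, hours).

Run configurations are YAML with strict validation: unknown keys are
rejected, bounds must be ordered, and enabling a structure flag without its
parameter is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .estimate import OBSERVABLE_TO_STATE, Dataset, FitConfig
from .model_auto import AutoParams, GasEnv
from .model_het import ConfigurationError, HetParams, ModelStructure
from .units import MOLAR_MASS

__all__ = ["RunConfig", "read_timeseries", "write_timeseries", "load_config"]

log = logging.getLogger(__name__)

_UNIT_COMPOUND = {"fructose": "fructose", "acetoin": "acetoin", "bdo": "bdo"}

#: unit label -> (conversion to internal units, applicable observables)
_UNIT_SUFFIXES = ("mM", "gL", "g_L", "pct", "frac")


def _normalize(observable: str, value, unit: str):
    value = np.asarray(value, dtype=float)
    unit = (unit or "").strip()
    if unit in ("", "g/L", "gL", "g_L", "frac", "h", "od"):
        return value
    if unit == "mM":
        if observable not in _UNIT_COMPOUND:
            raise ValueError(f"unit mM not applicable to observable {observable!r}")
        return value * MOLAR_MASS[_UNIT_COMPOUND[observable]] / 1000.0
    if unit in ("pct", "%"):
        return value / 100.0
    raise ValueError(f"unknown unit {unit!r} for observable {observable!r}")


def _split_suffix(column: str):
    for suffix in _UNIT_SUFFIXES:
        if column.endswith("_" + suffix):
            return column[: -(len(suffix) + 1)], suffix
    return column, ""


def read_timeseries(path, unit_map: Optional[dict] = None) -> Dataset:
    """Read a wide or long CSV time series into a long-form Dataset with
    internal units. Missing cells are skipped; unknown observable columns and
    non-monotone times are rejected."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if not cols or cols[0] != "time_h":
        raise ValueError("first column must be 'time_h'")
    unit_map = unit_map or {}

    if set(cols) >= {"time_h", "observable", "value"}:  # long layout
        long = df.copy()
        if "unit" not in long.columns:
            long["unit"] = ""
        long["unit"] = long["unit"].fillna("")
    else:  # wide layout
        records = []
        for col in cols[1:]:
            name, suffix = _split_suffix(col)
            unit = unit_map.get(name, suffix)
            for t, v in zip(df["time_h"], df[col]):
                if pd.isna(v):
                    continue
                records.append((t, name, v, unit))
        long = pd.DataFrame(records,
                            columns=["time_h", "observable", "value", "unit"])

    unknown = set(long["observable"]) - set(OBSERVABLE_TO_STATE)
    if unknown:
        raise ValueError(
            f"unknown observable column(s) {sorted(unknown)}; allowed names: "
            f"{sorted(OBSERVABLE_TO_STATE)}")
    per_obs_times = long.groupby("observable")["time_h"]
    if (per_obs_times.apply(lambda s: np.any(np.diff(s.to_numpy()) < 0))).any():
        raise ValueError("time_h must be non-decreasing within each observable")

    long = long.dropna(subset=["value"]).reset_index(drop=True)
    long["value"] = [
        float(_normalize(o, v, u))
        for o, v, u in zip(long["observable"], long["value"], long["unit"])
    ]
    long["unit"] = [
        "frac" if o.endswith("_frac") else ("" if o == "OD600" else "g/L")
        for o in long["observable"]
    ]
    return Dataset(observations=long[["time_h", "observable", "value", "unit"]],
                   label=str(path))


def write_timeseries(dataset: Dataset, path) -> None:
    """Write a Dataset as a long CSV (time_h,observable,value,unit)."""
    df = dataset.observations.copy()
    if "unit" not in df.columns:
        df["unit"] = ""
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Fully resolved configuration for a simulate/fit run."""

    mode: str
    params: object
    structure: ModelStructure
    env: Optional[GasEnv]
    state0: dict
    solver: dict = field(default_factory=dict)
    fit: Optional[FitConfig] = None
    seed: int = 0
    paths: dict = field(default_factory=dict)


_TOP_KEYS = {"mode", "structure", "params", "env", "state0", "solver", "fit",
             "seed", "paths"}
_SOLVER_KEYS = {"rtol", "atol", "method", "t_span", "n_points"}
_FIT_KEYS = {"max_nfev", "max_iter", "n_starts", "weights"}


def _build_params(mode: str, raw: dict):
    cls = HetParams if mode == "het" else AutoParams
    values, free = {}, {}
    for name, spec in raw.items():
        if isinstance(spec, dict):
            extra = set(spec) - {"value", "min", "max", "free"}
            if extra:
                raise ConfigurationError(
                    f"unknown keys {sorted(extra)} in parameter {name!r}")
            v = spec["value"]
            values[name] = v
            if spec.get("free"):
                lo, hi = spec.get("min"), spec.get("max")
                if lo is None or hi is None:
                    raise ConfigurationError(
                        f"free parameter {name!r} needs min and max bounds")
                if not lo < hi:
                    raise ConfigurationError(
                        f"bounds for parameter {name!r} are inverted: [{lo}, {hi}]")
                if not (lo <= v <= hi):
                    raise ConfigurationError(
                        f"initial value of {name!r} lies outside its bounds")
                free[name] = (float(lo), float(hi), float(v))
        else:
            values[name] = spec
    try:
        params = cls(**values)
    except TypeError as exc:
        raise ConfigurationError(f"bad parameter set for mode {mode!r}: {exc}") from exc
    return params, free


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; resolved values are
    echoed to the log."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
    mode = raw.get("mode")
    if mode not in ("het", "auto"):
        raise ConfigurationError("config must set mode: het or auto")

    structure = ModelStructure(**(raw.get("structure") or {}))
    params, free = _build_params(mode, raw.get("params") or {})
    params.validate(structure)

    env = None
    if mode == "auto":
        env = GasEnv(**(raw.get("env") or {}))
        env.validate()

    solver = dict(raw.get("solver") or {})
    bad = set(solver) - _SOLVER_KEYS
    if bad:
        raise ConfigurationError(f"unknown solver keys {sorted(bad)}")

    fit_cfg = None
    fit_raw = dict(raw.get("fit") or {})
    bad = set(fit_raw) - _FIT_KEYS
    if bad:
        raise ConfigurationError(f"unknown fit keys {sorted(bad)}")
    if free:
        fit_cfg = FitConfig(free=free,
                            weights=fit_raw.get("weights"),
                            max_nfev=int(fit_raw.get("max_nfev", 3000)),
                            max_iter=int(fit_raw.get("max_iter", 200)),
                            n_starts=int(fit_raw.get("n_starts", 1)),
                            seed=int(raw.get("seed", 0)))

    cfg = RunConfig(mode=mode, params=params, structure=structure, env=env,
                    state0=dict(raw.get("state0") or {}), solver=solver,
                    fit=fit_cfg, seed=int(raw.get("seed", 0)),
                    paths=dict(raw.get("paths") or {}))
    log.info("resolved config: mode=%s seed=%d solver=%s params=%s",
             cfg.mode, cfg.seed, cfg.solver, cfg.params)
    return cfg
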