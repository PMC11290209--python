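"""Bounded nonlinear least-squares parameter estimation and fit scoring.

The objective is the weighted sum of squared errors between sparse
observations and the model trajectory evaluated exactly at the observation
times (no interpolation error: the observation times are part of the solver
grid). Bounds, a function-evaluation cap and an iteration cap constrain the
local search; optimization uses scipy's Trust Region Reflective bounded
least-squares. Per-observable weights default to the inverse variance of each
observable's measurements so that g L^-1 analytes and mole-fraction gases
contribute commensurably. Fit quality is scored per observable with the
coefficient of determination R^2 = 1 - SS_res/SS_tot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_het import ConfigurationError, ModelStructure
from .model_auto import GasEnv
from .simulate import IntegrationError, Trajectory, integrate
from .yields import od_to_biomass

__all__ = [
    "Dataset",
    "FitConfig",
    "FitContext",
    "FitResult",
    "OBSERVABLE_TO_STATE",
    "sse_objective",
    "fit_parameters",
    "r_squared",
]

log = logging.getLogger(__name__)

#: Observation vocabulary -> model state variable. OD600 is mapped to biomass
#: through the dry-weight calibration before residuals are computed.
OBSERVABLE_TO_STATE = {
    "OD600": "X",
    "X": "X",
    "fructose": "cS_F",
    "acetoin": "cP_A",
    "bdo": "cP_B",
    "o2_frac": "cO2_g",
    "co2_frac": "cCO2_g",
    "h2_frac": "cH2_g",
    "o2_l": "cO2_l",
    "co2_l": "cCO2_l",
    "h2_l": "cH2_l",
}

#: Residual magnitude substituted when a candidate makes the solver fail.
PENALTY_RESIDUAL = 1e3


@dataclass
class Dataset:
    """Sparse noisy observations in long form.

    ``observations`` columns: ``time_h``, ``observable``, ``value`` (internal
    units: g L^-1 for analytes and biomass, dimensionless OD600 and mole
    fractions), optional ``unit``. ``liquid_volume`` optionally records the
    remaining liquid volume per sampling time for yield bookkeeping.
    """

    observations: pd.DataFrame
    liquid_volume: Optional[pd.DataFrame] = None
    label: str = ""

    def __post_init__(self) -> None:
        required = {"time_h", "observable", "value"}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations lack columns {sorted(missing)}")
        unknown = set(self.observations["observable"]) - set(OBSERVABLE_TO_STATE)
        if unknown:
            raise ValueError(
                f"unknown observables {sorted(unknown)}; allowed: "
                f"{sorted(OBSERVABLE_TO_STATE)}"
            )

    def observables(self) -> list:
        return sorted(self.observations["observable"].unique())

    def times(self) -> np.ndarray:
        return np.sort(self.observations["time_h"].unique())

    def subset(self, observable: str) -> pd.DataFrame:
        df = self.observations
        return df[df["observable"] == observable].sort_values("time_h")


@dataclass
class FitConfig:
    """Free parameters with box bounds and start values, plus search caps.

    ``free``: parameter name -> (lower, upper, initial). ``weights``:
    observable -> weight; None selects inverse-variance weights.
    """

    free: dict
    weights: Optional[dict] = None
    max_nfev: int = 3000
    max_iter: int = 200
    n_starts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.free:
            raise ConfigurationError("FitConfig.free must name at least one parameter")
        for name, (lo, hi, x0) in self.free.items():
            if not lo < hi:
                raise ConfigurationError(
                    f"bounds for {name} are inverted: [{lo}, {hi}]")
            if not (lo <= x0 <= hi):
                raise ConfigurationError(
                    f"initial value {x0} for {name} outside bounds [{lo}, {hi}]")


@dataclass
class FitContext:
    """Everything needed to simulate a candidate: model choice, initial
    state, template parameter set (fixed values), structure, environment and
    horizon."""

    model: str
    state0: np.ndarray
    params: object  # HetParams | AutoParams template
    structure: ModelStructure
    env: Optional[GasEnv] = None
    t_span: tuple = (0.0, 120.0)
    rtol: float = 1e-6
    atol: float = 1e-9


@dataclass
class FitResult:
    params: object
    estimates: dict
    objective: float
    r2: dict
    success: bool
    message: str
    trajectory: Optional[Trajectory]
    nfev: int = 0
    condition_number: float = float("nan")
    bounds_hit: list = field(default_factory=list)

    def report(self) -> str:
        lines = ["fit report", "=" * 40,
                 f"converged: {self.success} ({self.message})",
                 f"objective (weighted SSE): {self.objective:.6g}",
                 f"function evaluations: {self.nfev}",
                 f"Jacobian condition number: {self.condition_number:.3g}",
                 "", "estimates:"]
        for name, v in self.estimates.items():
            hit = "  [at bound]" if name in self.bounds_hit else ""
            lines.append(f"  {name} = {v:.6g}{hit}")
        lines += ["", "per-observable R^2:"]
        for obs, v in self.r2.items():
            lines.append(f"  {obs}: {v:.4f}")
        return "\n".join(lines)

    def to_keyvalues(self) -> dict:
        out = {f"param.{k}": v for k, v in self.estimates.items()}
        out.update({f"r2.{k}": v for k, v in self.r2.items()})
        out["objective"] = self.objective
        out["success"] = self.success
        return out


def r_squared(observed, simulated) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative for
    fits worse than the data mean."""
    y = np.asarray(observed, dtype=float)
    ys = np.asarray(simulated, dtype=float)
    if y.shape != ys.shape or y.size < 2:
        raise ValueError("observed and simulated must be equal-length vectors of size >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed values are all identical; R^2 undefined")
    return 1.0 - float(np.sum((y - ys) ** 2) / ss_tot)


def _default_weights(dataset: Dataset) -> dict:
    w = {}
    for obs in dataset.observables():
        var = float(np.var(dataset.subset(obs)["value"].to_numpy()))
        w[obs] = 1.0 / var if var > 0 else 1.0
    return w


def _simulate_candidate(values, names, dataset: Dataset, ctx: FitContext,
                        t_eval=None) -> Trajectory:
    params = replace(ctx.params, **dict(zip(names, values)))
    if t_eval is None:
        obs_times = dataset.times()
        t_eval = np.union1d(obs_times, np.asarray(ctx.t_span, dtype=float))
    return integrate(ctx.model, ctx.state0, params, ctx.structure, ctx.env,
                     t_span=ctx.t_span, t_eval=t_eval,
                     rtol=ctx.rtol, atol=ctx.atol)


def _residuals(values, names, dataset: Dataset, ctx: FitContext,
               weights: dict) -> np.ndarray:
    df = dataset.observations
    try:
        traj = _simulate_candidate(values, names, dataset, ctx)
    except (IntegrationError, ValueError) as exc:
        log.warning("candidate %s penalized: %s", dict(zip(names, values)), exc)
        return np.full(len(df), PENALTY_RESIDUAL)
    res = np.empty(len(df))
    for i, (t, obs, val) in enumerate(
            zip(df["time_h"], df["observable"], df["value"])):
        sim = traj.interp(OBSERVABLE_TO_STATE[obs], t)
        y = od_to_biomass(val) if obs == "OD600" else val
        res[i] = np.sqrt(weights[obs]) * (y - sim)
    return res


def sse_objective(values, names, dataset: Dataset, ctx: FitContext,
                  weights: Optional[dict] = None) -> float:
    """Weighted sum of squared errors for a candidate parameter vector.

    Solver failures return a large finite penalty (and are logged) rather
    than raising, so the optimizer can step away from pathological regions.
    """
    weights = weights or _default_weights(dataset)
    r = _residuals(values, names, dataset, ctx, weights)
    return float(np.sum(r ** 2))


def fit_parameters(dataset: Dataset, config: FitConfig,
                   ctx: FitContext) -> FitResult:
    """Bounded local least-squares fit of the free parameters.

    Deterministic for identical data, start and settings. With
    ``config.n_starts > 1`` the start is perturbed within bounds from a
    seeded generator and the best converged objective is kept.
    """
    names = list(config.free)
    lo = np.array([config.free[n][0] for n in names])
    hi = np.array([config.free[n][1] for n in names])
    x0 = np.array([config.free[n][2] for n in names])
    weights = config.weights or _default_weights(dataset)

    starts = [x0]
    if config.n_starts > 1:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_starts - 1):
            starts.append(rng.uniform(lo, hi))

    best = None
    for start in starts:
        # diff_step must clear the adaptive-solver noise floor or the
        # finite-difference Jacobian is garbage and the search stalls early
        sol = least_squares(
            _residuals, start, bounds=(lo, hi), method="trf",
            args=(names, dataset, ctx, weights),
            max_nfev=config.max_nfev, diff_step=1e-3, x_scale="jac",
            xtol=1e-14, ftol=1e-14, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    estimates = dict(zip(names, best.x))
    objective = float(2.0 * best.cost)  # least_squares cost = 0.5 * SSE
    all_penalized = bool(np.all(np.abs(best.fun) >= PENALTY_RESIDUAL))
    success = bool(best.success) and not all_penalized
    message = best.message if not all_penalized else (
        "no candidate could be simulated (all penalized)")

    traj = None
    r2: dict = {}
    if not all_penalized:
        try:
            t_dense = np.linspace(ctx.t_span[0], ctx.t_span[1], 241)
            t_eval = np.union1d(t_dense, dataset.times())
            traj = _simulate_candidate(best.x, names, dataset, ctx, t_eval=t_eval)
            for obs in dataset.observables():
                sub = dataset.subset(obs)
                y = sub["value"].to_numpy()
                if obs == "OD600":
                    y = od_to_biomass(y)
                ys = traj.interp(OBSERVABLE_TO_STATE[obs],
                                 sub["time_h"].to_numpy())
                r2[obs] = r_squared(y, ys)
        except (IntegrationError, ValueError) as exc:  # pragma: no cover
            log.warning("could not score optimum: %s", exc)

    with np.errstate(divide="ignore", invalid="ignore"):
        cond = float(np.linalg.cond(best.jac)) if best.jac is not None else float("nan")
    log.info("fit finished: SSE = %.6g, cond(J) = %.3g", objective, cond)

    tol = 1e-9
    bounds_hit = [n for n, l, h, v in zip(names, lo, hi, best.x)
                  if v - l < tol * max(1.0, abs(l)) or h - v < tol * max(1.0, abs(h))]
    params_full = replace(ctx.params, **estimates)
    return FitResult(params_full, estimates, objective, r2, success,
                     str(message), traj, int(best.nfev), cond, bounds_hit)
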