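"""Stiff integration of the batch models with event-located regime switching.

The published model structures change discretely when a substrate or the
electron acceptor depletes (back-reaction onset after fructose exhaustion;
growth-kinetic switch and exchange-reaction scheduling after CO2 and O2
depletion). The integrator runs a variable-order implicit stiff method (BDF,
the NDF family) piecewise: each depletion crossing is located by the solver's
event machinery, the regime is advanced, and integration restarts from the
event state, so switches happen at the crossing time rather than at a grid
point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_auto import (
    AUTO_STATE_NAMES,
    AutoParams,
    AutoState,
    GasEnv,
    auto_rhs,
)
from .model_het import (
    HET_STATE_NAMES,
    ConfigurationError,
    HetParams,
    HetState,
    ModelStructure,
    het_rhs,
)

__all__ = [
    "Trajectory",
    "RegimeEvent",
    "IntegrationError",
    "integrate",
    "regime_schedule",
    "resolve_gas_thresholds",
]

log = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9

#: Fraction of the initial equilibrium solubility used as the dissolved-gas
#: depletion trigger when no absolute threshold is configured ("almost
#: depleted" made proportional, hence scale-free).
GAS_THRESHOLD_FRACTION = 0.01


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid time and state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(f"{message} (last valid t = {t_last:.6g})")
        self.t_last = t_last
        self.y_last = np.asarray(y_last)


@dataclass
class RegimeEvent:
    """A regime transition: which observable crossing triggers it, in which
    direction, and which regime it enters. ``time`` is filled in once the
    event is located during integration."""

    trigger: str
    threshold: float
    direction: str  # "falling" or "rising"
    regime: str
    time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError("event threshold must be >= 0")
        if self.direction not in ("falling", "rising"):
            raise ConfigurationError("event direction must be 'falling' or 'rising'")


@dataclass
class Trajectory:
    """Dense simulation output: named state columns on a strictly increasing
    time grid, with the active regime recorded per time point."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_vars)
    names: tuple
    regimes: list
    events: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    #: Reported states may dip this far below zero (stiff-solver error near
    #: a depletion switch) before being clipped; anything lower is an error.
    NEGATIVE_CLIP = 1e-4

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(~np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")
        if self.states.min(initial=0.0) < -self.NEGATIVE_CLIP:
            raise ValueError("trajectory contains grossly negative states")
        self.states = np.clip(self.states, 0.0, None)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    def interp(self, name: str, t) -> np.ndarray:
        """Linear interpolation of one state variable at arbitrary times."""
        return np.interp(np.asarray(t, dtype=float), self.times, self[name])

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self, long: bool = True) -> pd.DataFrame:
        wide = pd.DataFrame(self.states, columns=list(self.names))
        wide.insert(0, "time_h", self.times)
        wide["regime"] = self.regimes
        if not long:
            return wide
        out = wide.melt(
            id_vars=["time_h", "regime"], var_name="variable", value_name="value"
        )
        return out[["time_h", "variable", "value", "regime"]].sort_values(
            ["time_h", "variable"], ignore_index=True
        )


def resolve_gas_thresholds(structure: ModelStructure, state0: np.ndarray,
                           params: AutoParams, env: GasEnv) -> dict:
    """Absolute dissolved-gas depletion thresholds [mol L^-1]: configured
    values, else GAS_THRESHOLD_FRACTION of the initial equilibrium
    solubility of each gas."""
    y0 = np.asarray(state0, dtype=float)
    o2_star0 = y0[3] * env.P * params.H_O2
    co2_star0 = y0[4] * env.P * params.H_CO2
    return {
        "co2": structure.depletion_thresholds.get(
            "co2", GAS_THRESHOLD_FRACTION * co2_star0),
        "o2": structure.depletion_thresholds.get(
            "o2", GAS_THRESHOLD_FRACTION * o2_star0),
    }


def _het_transitions(structure: ModelStructure, thresholds: dict) -> dict:
    """regime -> list of (trigger name, state index, threshold, direction,
    next regime) for the heterotrophic model."""
    if not structure.use_het_reverse:
        return {}
    thr = thresholds["fructose"]
    table = {"growth": [("fructose", 1, thr, "falling", "depleted")]}
    if structure.switch_mode == "reversible":
        table["depleted"] = [("fructose", 1, thr, "rising", "growth")]
    return table


def _auto_transitions(structure: ModelStructure, thresholds: dict) -> dict:
    stage2 = (structure.use_gas_switch or structure.use_auto_forward1
              or structure.use_auto_reverse)
    stage3 = structure.use_auto_forward2 or structure.use_auto_reverse
    table: dict = {}
    if stage2 or stage3:
        table["growth"] = [
            ("cCO2_l", 7, thresholds["co2"], "falling", "co2_depleted")
        ]
    if stage3:
        table["co2_depleted"] = [
            ("cO2_l", 6, thresholds["o2"], "falling", "o2_depleted")
        ]
    if structure.switch_mode == "reversible":
        table.setdefault("co2_depleted", []).append(
            ("cCO2_l", 7, thresholds["co2"], "rising", "growth"))
        table.setdefault("o2_depleted", []).append(
            ("cO2_l", 6, thresholds["o2"], "rising", "co2_depleted"))
    return table


def _initial_regime(model: str, y0: np.ndarray, structure: ModelStructure,
                    thresholds: dict) -> str:
    if model == "het":
        if structure.use_het_reverse and y0[1] < thresholds["fructose"]:
            return "depleted"
        return "growth"
    # closed bottles start gas-replete; a below-threshold start skips ahead
    if (structure.use_gas_switch or structure.use_auto_forward1
            or structure.use_auto_reverse) and y0[7] < thresholds["co2"]:
        if ((structure.use_auto_forward2 or structure.use_auto_reverse)
                and y0[6] < thresholds["o2"]):
            return "o2_depleted"
        return "co2_depleted"
    return "growth"


def _prepare(model: str, state0, params, structure, env):
    if model == "het":
        y0 = state0.to_array() if isinstance(state0, HetState) else np.asarray(
            state0, dtype=float)
        names = HET_STATE_NAMES
        thresholds = {"fructose": structure.fructose_threshold}
        transitions = _het_transitions(structure, thresholds)

        def rhs(t, y, regime):
            return het_rhs(t, y, params, structure)

    elif model == "auto":
        if env is None:
            env = GasEnv()
        env.validate()
        y0 = state0.to_array() if isinstance(state0, AutoState) else np.asarray(
            state0, dtype=float)
        names = AUTO_STATE_NAMES
        thresholds = resolve_gas_thresholds(structure, y0, params, env)
        transitions = _auto_transitions(structure, thresholds)

        def rhs(t, y, regime):
            return auto_rhs(t, y, params, env, structure, regime)

    else:
        raise ValueError(f"unknown model {model!r}; expected 'het' or 'auto'")
    return y0, names, thresholds, transitions, rhs, env


def regime_schedule(trajectory: Trajectory, structure: ModelStructure,
                    model: str = "auto", params=None, env=None):
    """Replay the depletion-driven transition rules over an existing
    trajectory (grid-located, not event-located).

    Returns ``(final regime, realized RegimeEvent list)``. With no exchange
    or switch flags set the schedule has a single regime regardless of the
    gas dynamics.
    """
    y0 = trajectory.states[0]
    if model == "het":
        thresholds = {"fructose": structure.fructose_threshold}
        transitions = _het_transitions(structure, thresholds)
    else:
        if env is None:
            env = GasEnv()
        if params is None:
            raise ConfigurationError("regime_schedule for the autotrophic model needs params")
        thresholds = resolve_gas_thresholds(structure, y0, params, env)
        transitions = _auto_transitions(structure, thresholds)
    regime = _initial_regime(model, y0, structure, thresholds)
    events: list = []
    names = trajectory.names
    for k in range(1, len(trajectory.times)):
        for trig, idx, thr, direction, nxt in transitions.get(regime, []):
            prev = trajectory.states[k - 1, names.index(trig)]
            cur = trajectory.states[k, names.index(trig)]
            crossed = (prev >= thr > cur) if direction == "falling" else (prev <= thr < cur)
            if crossed:
                events.append(RegimeEvent(trig, thr, direction,
                                          nxt, float(trajectory.times[k])))
                regime = nxt
                break
    return regime, events


def integrate(model: str, state0, params, structure: Optional[ModelStructure] = None,
              env: Optional[GasEnv] = None, t_span=(0.0, 120.0), t_eval=None,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
              method: str = "BDF", max_switches: int = 20,
              dense_n: int = 241) -> Trajectory:
    """Integrate the heterotrophic ('het') or autotrophic ('auto') model.

    Parameters are validated against the structure; the solution is reported
    on ``t_eval`` (default: ``dense_n`` evenly spaced points) with located
    event times inserted. Raises :class:`IntegrationError` on solver failure,
    carrying the last valid time and state.
    """
    structure = structure or ModelStructure()
    params.validate(structure)
    t0, t_end = float(t_span[0]), float(t_span[1])
    if not t_end > t0:
        raise ValueError("t_span must be non-degenerate (t_end > t0)")
    if t_eval is None:
        t_eval = np.linspace(t0, t_end, dense_n)
    t_eval = np.asarray(t_eval, dtype=float)

    y0, names, thresholds, transitions, rhs, env = _prepare(
        model, state0, params, structure, env)
    regime = _initial_regime(model, y0, structure, thresholds)

    times: list = []
    states: list = []
    regimes: list = []
    realized: list = []
    cur_t, cur_y = t0, y0.copy()

    for _ in range(max_switches + 1):
        active = transitions.get(regime, [])
        event_fns = []
        for trig, idx, thr, direction, nxt in active:
            def make(idx=idx, thr=thr, direction=direction):
                def ev(t, y):
                    return y[idx] - thr
                ev.terminal = True
                ev.direction = -1.0 if direction == "falling" else 1.0
                return ev
            event_fns.append(make())

        seg_eval = t_eval[(t_eval >= cur_t) & (t_eval <= t_end)]
        if len(seg_eval) == 0 or seg_eval[0] > cur_t:
            seg_eval = np.concatenate(([cur_t], seg_eval))
        sol = solve_ivp(
            lambda t, y: rhs(t, y, regime),
            (cur_t, t_end), cur_y, method=method, t_eval=seg_eval,
            events=event_fns or None, rtol=rtol, atol=atol,
        )
        if sol.status == -1:
            t_last = sol.t[-1] if len(sol.t) else cur_t
            y_last = sol.y[:, -1] if len(sol.t) else cur_y
            raise IntegrationError(f"stiff solver failed: {sol.message}",
                                   t_last, y_last)

        seg_t, seg_y = sol.t, sol.y.T
        if sol.status == 1:  # terminated at an event
            fired = next(i for i, te in enumerate(sol.t_events) if len(te))
            t_ev = float(sol.t_events[fired][0])
            y_ev = sol.y_events[fired][0]
            trig, idx, thr, direction, nxt = active[fired]
            realized.append(RegimeEvent(trig, thr, direction, nxt, t_ev))
            keep = seg_t < t_ev
            seg_t = np.concatenate((seg_t[keep], [t_ev]))
            seg_y = np.vstack((seg_y[keep], y_ev))
        for tk, yk in zip(seg_t, seg_y):
            if times and tk <= times[-1]:
                continue
            times.append(float(tk))
            states.append(yk)
            regimes.append(regime)
        if sol.status == 1:
            regime = nxt
            cur_t, cur_y = t_ev, np.clip(np.asarray(y_ev, dtype=float), 0.0, None)
            if cur_t >= t_end:
                break
            continue
        break
    else:
        raise IntegrationError(
            f"exceeded max_switches = {max_switches} regime transitions",
            cur_t, cur_y)

    meta = {
        "model": model, "params": params, "structure": structure, "env": env,
        "solver": {"method": method, "rtol": rtol, "atol": atol},
        "thresholds": thresholds,
    }
    return Trajectory(np.array(times), np.array(states), tuple(names),
                      regimes, realized, meta)
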