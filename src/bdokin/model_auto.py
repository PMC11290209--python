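"""Autotrophic (knallgas) batch kinetics: H2/CO2/O2-fed growth and
acetoin/2,3-BDO exchange in closed bottles.

Nine mass balances: biomass ``X`` and the two products in the liquid, plus,
for each of O2, CO2 and H2, a headspace mole fraction ``c_i_g`` and a
dissolved concentration ``c_i_l`` [mol L^-1]. Growth is a triple Monod in the
dissolved gases; gas-liquid transfer follows a kLa driving force toward the
Henry equilibrium solubility ``c* = x * P * H``; headspace fractions deplete
through transfer scaled by the volume ratio::

    dX/dt      = (mu - mu_d) * X
    dc_i_l/dt  = kLa * (c_i* - c_i_l) - X * mu / Y_X_i
    dc_i_g/dt  = -kLa * (c_i* - c_i_l) * (V_L * R * T) / (V_G * P)

Once one gas is depleted its Monod factor would pin all rates at zero, so
the growth/lysis kinetics can be switched to drop the CO2 factor
(``use_gas_switch``). Acetoin <-> 2,3-BDO exchange reactions (two forward,
one reverse), each a Monod uptake with a coupling yield, are enabled per
strain and per regime; the regime sequence is handled by the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Optional

import numpy as np

from .model_het import (
    ConfigurationError,
    InvalidStateError,
    ModelStructure,
    _clean_state,
)
from .units import R_L_ATM, T_MODEL, henry_constant

__all__ = [
    "AUTO_STATE_NAMES",
    "GAS_SPECIES",
    "REGIMES",
    "AutoState",
    "AutoParams",
    "GasEnv",
    "equilibrium_solubility",
    "auto_growth_rate",
    "auto_death_rate",
    "exchange_rates",
    "active_exchanges",
    "growth_kinetic_for",
    "auto_rhs",
]

AUTO_STATE_NAMES = (
    "X", "cP_A", "cP_B",
    "cO2_g", "cCO2_g", "cH2_g",
    "cO2_l", "cCO2_l", "cH2_l",
)
GAS_SPECIES = ("o2", "co2", "h2")

#: Smooth availability regularization on gas-uptake terms [mol L^-1]. After
#: the growth-kinetic switch the dropped gas no longer appears in mu, so its
#: uptake term alone would drive the dissolved concentration negative; the
#: factor c_l/(c_l + eps) shuts uptake off continuously at zero while being
#: indistinguishable from 1 at physiological concentrations (>= 1e-5 mol/L).
GAS_UPTAKE_EPS = 1e-8

#: Process regimes, in the order they occur in a closed-bottle run:
#: unrestricted growth/production; CO2 depleted (growth kinetic switched,
#: first forward + reverse exchange active); O2 also depleted (reverse stops,
#: second forward exchange takes over).
REGIMES = ("growth", "co2_depleted", "o2_depleted")


@dataclass
class AutoState:
    X: float
    cP_A: float = 0.0
    cP_B: float = 0.0
    cO2_g: float = 0.15
    cCO2_g: float = 0.05
    cH2_g: float = 0.80
    cO2_l: float = 0.0
    cCO2_l: float = 0.0
    cH2_l: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.cO2_g, self.cCO2_g, self.cH2_g)
        if any(f > 1.0 + 1e-12 for f in fracs):
            raise InvalidStateError("headspace mole fractions must be <= 1")
        if sum(fracs) > 1.0 + 1e-9:
            raise InvalidStateError(
                "tracked headspace fractions sum above 1 (remainder must be inert N2)"
            )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in AUTO_STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "AutoState":
        return cls(*np.asarray(y, dtype=float))


@dataclass
class GasEnv:
    """Closed-bottle environment: litres, atm, Kelvin, R in L atm mol^-1 K^-1.

    Defaults are the 1-L bottle protocol: 50 mL liquid, 1.08 L headspace,
    1 atm, 30 degC.
    """

    V_L: float = 0.05
    V_G: float = 1.08
    P: float = 1.0
    T: float = T_MODEL
    R: float = R_L_ATM

    def validate(self) -> None:
        for name in ("V_L", "V_G", "P", "T"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"GasEnv.{name} must be > 0")
        # dimensional-consistency heuristic: an SI gas constant (8.314)
        # demands Pa-scale pressures; the L-atm constant demands atm-scale.
        if self.R > 1.0 and self.P < 100.0:
            raise ConfigurationError(
                "GasEnv looks dimensionally inconsistent: R is on the SI scale "
                f"({self.R}) but P ({self.P}) is on the atm scale; use "
                "R = 0.082057 L atm/(mol K) with P in atm"
            )
        if self.R < 1.0 and self.P > 100.0:
            raise ConfigurationError(
                "GasEnv looks dimensionally inconsistent: R is on the L-atm "
                f"scale ({self.R}) but P ({self.P}) is on the Pa scale"
            )

    @property
    def total_gas_moles(self) -> float:
        return self.P * self.V_G / (self.R * self.T)


def _default_henry(gas: str) -> float:
    return henry_constant(gas, T_MODEL)


@dataclass
class AutoParams:
    """Kinetic and physical parameters of the autotrophic model.

    Gas affinities K_* are dissolved concentrations [mol L^-1]; gas yields
    Y_X_* are g_cell per mol of gas consumed; kLa [h^-1]; Henry constants
    H_* [mol L^-1 atm^-1] default to compilation values corrected to 30 degC.
    Exchange-reaction parameters (q_*_max [g g_cell^-1 h^-1], K_* [g L^-1],
    yields [g g^-1]) are needed only when the corresponding structure flag
    is on.
    """

    mu_max: float
    K_O2: float
    K_CO2: float
    K_H2: float
    Y_X_A: float
    Y_X_B: float
    Y_X_O2: float
    Y_X_CO2: float
    Y_X_H2: float
    kLa: float
    mu_d_min: float = 0.0
    mu_d_max: float = 0.0
    H_O2: float = None  # type: ignore[assignment]
    H_CO2: float = None  # type: ignore[assignment]
    H_H2: float = None  # type: ignore[assignment]
    q_f1_A_max: Optional[float] = None
    K_f1_A: Optional[float] = None
    Y_f1_B_A: Optional[float] = None
    q_f2_A_max: Optional[float] = None
    K_f2_A: Optional[float] = None
    Y_f2_B_A: Optional[float] = None
    q_r_B_max: Optional[float] = None
    K_r_B: Optional[float] = None
    Y_r_A_B: Optional[float] = None

    def __post_init__(self) -> None:
        if self.H_O2 is None:
            self.H_O2 = _default_henry("o2")
        if self.H_CO2 is None:
            self.H_CO2 = _default_henry("co2")
        if self.H_H2 is None:
            self.H_H2 = _default_henry("h2")

    def validate(self, structure: Optional[ModelStructure] = None) -> None:
        for name in ("mu_max", "K_O2", "K_CO2", "K_H2", "Y_X_A", "Y_X_B",
                     "Y_X_O2", "Y_X_CO2", "Y_X_H2", "kLa",
                     "H_O2", "H_CO2", "H_H2"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"parameter {name} must be > 0")
        for name in ("mu_d_min", "mu_d_max"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"parameter {name} must be >= 0")
        if structure is not None:
            needed = []
            if structure.use_auto_forward1:
                needed += ["q_f1_A_max", "K_f1_A", "Y_f1_B_A"]
            if structure.use_auto_forward2:
                needed += ["q_f2_A_max", "K_f2_A", "Y_f2_B_A"]
            if structure.use_auto_reverse:
                needed += ["q_r_B_max", "K_r_B", "Y_r_A_B"]
            for name in needed:
                v = getattr(self, name)
                if v is None or not v > 0:
                    raise ConfigurationError(
                        f"active structure flag requires parameter {name} > 0"
                    )

    def with_values(self, **kw) -> "AutoParams":
        return replace(self, **kw)

    def names(self) -> tuple:
        return tuple(f.name for f in fields(self))


def equilibrium_solubility(gas_fraction: float, env: GasEnv, H: float) -> float:
    """Equilibrium dissolved concentration c* = x * P * H [mol L^-1]."""
    if gas_fraction < 0 or H < 0:
        raise ValueError("gas fraction and Henry constant must be non-negative")
    return gas_fraction * env.P * H


def _as_auto_array(state) -> np.ndarray:
    y = state.to_array() if isinstance(state, AutoState) else state
    return _clean_state(y, AUTO_STATE_NAMES)


def _monod(c: float, K: float) -> float:
    return c / (c + K)


def growth_kinetic_for(regime: str, structure: ModelStructure) -> str:
    """Map a process regime to the growth-kinetic form: the CO2 Monod factor
    is dropped ('switched') after CO2 depletion when use_gas_switch is on."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if regime != "growth" and structure.use_gas_switch:
        return "switched"
    return "full"


def auto_growth_rate(state, params: AutoParams, structure: ModelStructure,
                     regime: str = "full") -> float:
    """Specific growth rate [h^-1]: mu_max times the product of dissolved-gas
    Monod factors — all three gases in the 'full' regime, O2 and H2 only in
    the 'switched' regime."""
    y = _as_auto_array(state)
    o2, co2, h2 = y[6], y[7], y[8]
    mu = params.mu_max * _monod(o2, params.K_O2) * _monod(h2, params.K_H2)
    if regime == "full":
        mu *= _monod(co2, params.K_CO2)
    elif regime != "switched":
        raise ValueError(f"unknown growth regime {regime!r}; expected 'full' or 'switched'")
    return mu


def auto_death_rate(state, params: AutoParams, structure: ModelStructure,
                    regime: str = "full") -> float:
    """Cell lysis rate [h^-1] with the same gas factors as growth, added on
    top of the minimal death rate."""
    y = _as_auto_array(state)
    o2, co2, h2 = y[6], y[7], y[8]
    factor = _monod(o2, params.K_O2) * _monod(h2, params.K_H2)
    if regime == "full":
        factor *= _monod(co2, params.K_CO2)
    elif regime != "switched":
        raise ValueError(f"unknown lysis regime {regime!r}; expected 'full' or 'switched'")
    return params.mu_d_min + params.mu_d_max * factor


def active_exchanges(regime: str, structure: ModelStructure) -> set:
    """Which acetoin<->BDO exchange reactions run in a process regime.

    After CO2 depletion the first forward reaction and (while O2 lasts) the
    reverse reaction run; after O2 depletion the reverse stops and the second
    forward reaction takes over. Each stage only runs if its structure flag
    is set.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    active = set()
    if regime == "co2_depleted":
        if structure.use_auto_forward1:
            active.add("f1")
        if structure.use_auto_reverse:
            active.add("r")
    elif regime == "o2_depleted":
        if structure.use_auto_forward2:
            active.add("f2")
    return active


def exchange_rates(state, params: AutoParams, structure: ModelStructure,
                   regime: str = "growth") -> dict:
    """Specific exchange rates [g g_cell^-1 h^-1].

    Forward reactions consume acetoin (``q_f*_A``) and produce 2,3-BDO at the
    yield-scaled rate (``q_f*_BA = Y_f*_B_A * q_f*_A``); the reverse consumes
    2,3-BDO (``q_r_B``) and produces acetoin (``q_r_AB = Y_r_A_B * q_r_B``).
    Inactive reactions contribute zero.
    """
    y = _as_auto_array(state)
    cP_A, cP_B = y[1], y[2]
    active = active_exchanges(regime, structure)
    rates = dict.fromkeys(
        ("q_f1_A", "q_f1_BA", "q_f2_A", "q_f2_BA", "q_r_B", "q_r_AB"), 0.0
    )
    if "f1" in active:
        rates["q_f1_A"] = params.q_f1_A_max * _monod(cP_A, params.K_f1_A)
        rates["q_f1_BA"] = params.Y_f1_B_A * rates["q_f1_A"]
    if "f2" in active:
        rates["q_f2_A"] = params.q_f2_A_max * _monod(cP_A, params.K_f2_A)
        rates["q_f2_BA"] = params.Y_f2_B_A * rates["q_f2_A"]
    if "r" in active:
        rates["q_r_B"] = params.q_r_B_max * _monod(cP_B, params.K_r_B)
        rates["q_r_AB"] = params.Y_r_A_B * rates["q_r_B"]
    return rates


def auto_rhs(t: float, state, params: AutoParams, env: GasEnv,
             structure: ModelStructure, regime: str = "growth") -> np.ndarray:
    """Right-hand side of the nine autotrophic mass balances for a given
    process regime. Accepts an :class:`AutoState` or a length-9 array ordered
    as ``AUTO_STATE_NAMES``."""
    env.validate()
    y = _as_auto_array(state)
    X = y[0]
    kin = growth_kinetic_for(regime, structure)
    mu = auto_growth_rate(y, params, structure, kin)
    mu_d = auto_death_rate(y, params, structure, kin)
    ex = exchange_rates(y, params, structure, regime)

    henry = (params.H_O2, params.H_CO2, params.H_H2)
    yields_gas = (params.Y_X_O2, params.Y_X_CO2, params.Y_X_H2)
    gas_to_liq = env.V_L * env.R * env.T / (env.V_G * env.P)

    d = np.zeros(9)
    d[0] = (mu - mu_d) * X
    d[1] = (mu / params.Y_X_A) * X - (ex["q_f1_A"] + ex["q_f2_A"]) * X + ex["q_r_AB"] * X
    d[2] = (mu / params.Y_X_B) * X + (ex["q_f1_BA"] + ex["q_f2_BA"]) * X - ex["q_r_B"] * X
    for i in range(3):
        c_g, c_l = y[3 + i], y[6 + i]
        c_star = c_g * env.P * henry[i]
        transfer = params.kLa * (c_star - c_l)
        availability = c_l / (c_l + GAS_UPTAKE_EPS)
        d[6 + i] = transfer - X * mu / yields_gas[i] * availability
        d[3 + i] = -transfer * gas_to_liq
    return d
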