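"""Heterotrophic batch kinetics: fructose-fed growth and acetoin/2,3-BDO
production by *Cupriavidus necator*.

The model is four coupled mass balances — biomass ``X``, fructose ``cS_F``,
acetoin ``cP_A`` and 2,3-butanediol ``cP_B`` (all g L^-1) — driven by Monod
growth on fructose with optional lag and 2,3-BDO product-inhibition factors, a
cell-lysis rate interpolating between a minimal and a maximal death rate as
substrate depletes, growth-coupled production of both products, and an
optional back-reaction that reoxidizes 2,3-BDO to acetoin once fructose is
(nearly) exhausted::

    dX/dt    = (mu - mu_d) * X
    dcS_F/dt = -(mu / Y_X_F) * X
    dcP_A/dt = (mu / Y_X_A) * X + q_P_AB * X
    dcP_B/dt = (mu / Y_X_B) * X - (q_P_AB / Y_A_B) * X

with ``q_P_AB = Y_A_B * q_B_max * cP_B / (cP_B + K_P_B)`` active only below
the fructose depletion threshold. ``Y_A_B`` is the mass yield of acetoin from
2,3-BDO, so the back-reaction consumes BDO at ``q_P_AB / Y_A_B`` per unit
biomass and produces acetoin at ``q_P_AB``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "HET_STATE_NAMES",
    "DEFAULT_FRUCTOSE_THRESHOLD",
    "ConfigurationError",
    "InvalidStateError",
    "ModelStructure",
    "HetState",
    "HetParams",
    "het_growth_rate",
    "het_death_rate",
    "het_specific_rates",
    "het_reverse_active",
    "het_rhs",
]

HET_STATE_NAMES = ("X", "cS_F", "cP_A", "cP_B")

#: Fructose concentration [g L^-1] below which the 2,3-BDO back-reaction
#: activates when ``use_het_reverse`` is set. A small positive cutoff avoids a
#: discontinuity at exactly zero substrate.
DEFAULT_FRUCTOSE_THRESHOLD = 0.05

#: Physical ceiling on yield coefficients, to catch unit mistakes.
YIELD_CEILING = 10.0

#: States more negative than this raise; smaller excursions are clipped to 0
#: because implicit stiff solvers probe negative values during Newton
#: iterations (occasionally by ~1e-3 before step rejection).
NEGATIVE_STATE_TOL = 0.05


class ConfigurationError(ValueError):
    """Inconsistent model configuration (flag without its parameter, bad
    bounds, dimensionally inconsistent environment, ...)."""


class InvalidStateError(ValueError):
    """State vector contains NaN or a grossly negative entry."""


@dataclass
class ModelStructure:
    """Per-strain switchboard of optional kinetic terms.

    The published model structures differ between strains: lag and product
    inhibition apply to heterotrophic growth, the heterotrophic back-reaction
    and the autotrophic forward/reverse acetoin<->BDO exchanges are enabled on
    demand, and the growth kinetic can be switched to drop the CO2 Monod
    factor once CO2 is depleted.
    """

    use_lag: bool = False
    use_product_inhibition: bool = False
    use_het_reverse: bool = False
    use_auto_forward1: bool = False
    use_auto_forward2: bool = False
    use_auto_reverse: bool = False
    use_gas_switch: bool = False
    #: observable name ("fructose", "co2", "o2") -> absolute threshold.
    #: Gas thresholds are dissolved concentrations [mol L^-1]; when absent
    #: the simulator resolves them to 1% of the initial equilibrium solubility.
    depletion_thresholds: dict = field(default_factory=dict)
    switch_mode: str = "one_way"  # or "reversible"

    def __post_init__(self) -> None:
        if self.switch_mode not in ("one_way", "reversible"):
            raise ConfigurationError(
                f"switch_mode must be 'one_way' or 'reversible', got {self.switch_mode!r}"
            )
        for name, thr in self.depletion_thresholds.items():
            if thr < 0:
                raise ConfigurationError(
                    f"depletion threshold for {name!r} must be >= 0, got {thr}"
                )

    @property
    def fructose_threshold(self) -> float:
        return self.depletion_thresholds.get("fructose", DEFAULT_FRUCTOSE_THRESHOLD)


@dataclass
class HetState:
    """Heterotrophic state: biomass and liquid analytes, all g L^-1."""

    X: float
    cS_F: float
    cP_A: float = 0.0
    cP_B: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.X, self.cS_F, self.cP_A, self.cP_B], dtype=float)

    @classmethod
    def from_array(cls, y) -> "HetState":
        return cls(*np.asarray(y, dtype=float))


@dataclass
class HetParams:
    """Kinetic parameters of the heterotrophic model.

    mu_max   maximum specific growth rate [h^-1]
    K_S_F    fructose affinity constant [g L^-1]
    Y_X_F    biomass yield on fructose [g_cell g^-1]
    Y_X_A    biomass-to-acetoin coupling yield [g_cell g^-1]
    Y_X_B    biomass-to-2,3-BDO coupling yield [g_cell g^-1]
    mu_d_min, mu_d_max   minimal / maximal cell lysis rates [h^-1]
    q_B_max  maximum specific 2,3-BDO uptake of the back-reaction [g g_cell^-1 h^-1]
    K_P_B    2,3-BDO affinity constant of the back-reaction [g L^-1]
    Y_A_B    acetoin yield from 2,3-BDO [g g^-1]
    t_lag    lag time [h]; required only when use_lag
    K_I_B    2,3-BDO inhibition constant [g L^-1]; required only when
             use_product_inhibition
    """

    mu_max: float
    K_S_F: float
    Y_X_F: float
    Y_X_A: float
    Y_X_B: float
    mu_d_min: float = 0.0
    mu_d_max: float = 0.0
    q_B_max: float = 0.0
    K_P_B: float = 1.0
    Y_A_B: float = 1.0
    t_lag: Optional[float] = None
    K_I_B: Optional[float] = None

    def validate(self, structure: Optional[ModelStructure] = None,
                 yield_ceiling: float = YIELD_CEILING) -> None:
        for name in ("mu_max", "K_S_F", "Y_X_F", "Y_X_A", "Y_X_B", "K_P_B", "Y_A_B"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"parameter {name} must be > 0, got {v}")
        for name in ("mu_d_min", "mu_d_max", "q_B_max"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"parameter {name} must be >= 0, got {v}")
        for name in ("Y_X_F", "Y_X_A", "Y_X_B", "Y_A_B"):
            if getattr(self, name) > yield_ceiling:
                raise ConfigurationError(
                    f"yield {name} = {getattr(self, name)} exceeds the physical "
                    f"ceiling {yield_ceiling}; check units"
                )
        if structure is not None:
            if structure.use_lag and self.t_lag is None:
                raise ConfigurationError("use_lag requires parameter t_lag")
            if structure.use_product_inhibition and self.K_I_B is None:
                raise ConfigurationError(
                    "use_product_inhibition requires parameter K_I_B"
                )

    def with_values(self, **kw) -> "HetParams":
        return replace(self, **kw)

    def names(self) -> tuple:
        return tuple(f.name for f in fields(self))


def _clean_state(y, names) -> np.ndarray:
    """Validate and clip a raw state vector.

    NaNs and entries below -NEGATIVE_STATE_TOL raise InvalidStateError naming
    the offending field; small negative excursions from the stiff solver are
    clipped to zero.
    """
    y = np.asarray(y, dtype=float)
    for i, name in enumerate(names):
        v = y[i]
        if math.isnan(v):
            raise InvalidStateError(f"state field {name!r} is NaN")
        if v < -NEGATIVE_STATE_TOL:
            raise InvalidStateError(f"state field {name!r} is negative ({v})")
    return np.clip(y, 0.0, None)


def _as_het_array(state) -> np.ndarray:
    y = state.to_array() if isinstance(state, HetState) else state
    return _clean_state(y, HET_STATE_NAMES)


def het_growth_rate(state, params: HetParams, t: float,
                    structure: ModelStructure) -> float:
    """Specific growth rate mu [h^-1]: Monod in fructose, optionally damped
    by the exponential lag factor ``1 - exp(-t/t_lag)`` and the product
    inhibition factor ``K_I_B / (K_I_B + cP_B)``."""
    _, cS_F, _, cP_B = _as_het_array(state)
    mu = params.mu_max * cS_F / (cS_F + params.K_S_F)
    if structure.use_lag:
        if params.t_lag is None:
            raise ConfigurationError("use_lag requires parameter t_lag")
        mu *= 1.0 - math.exp(-t / params.t_lag)
    if structure.use_product_inhibition:
        if params.K_I_B is None:
            raise ConfigurationError("use_product_inhibition requires parameter K_I_B")
        mu *= params.K_I_B / (params.K_I_B + cP_B)
    return mu


def het_death_rate(state, params: HetParams,
                   structure: ModelStructure) -> float:
    """Cell lysis rate mu_d [h^-1], rising from mu_d_min toward
    mu_d_min + mu_d_max as fructose depletes (and, with product inhibition
    on, as 2,3-BDO accumulates)."""
    _, cS_F, _, cP_B = _as_het_array(state)
    mu_d = params.mu_d_min + params.mu_d_max * params.K_S_F / (params.K_S_F + cS_F)
    if structure.use_product_inhibition:
        if params.K_I_B is None:
            raise ConfigurationError("use_product_inhibition requires parameter K_I_B")
        # the inhibition factor applies to the variable part only
        mu_d = params.mu_d_min + (mu_d - params.mu_d_min) * cP_B / (cP_B + params.K_I_B)
    return mu_d


def het_reverse_active(cS_F: float, structure: ModelStructure) -> bool:
    """Whether the 2,3-BDO -> acetoin back-reaction is active: flag on and
    fructose below its depletion threshold."""
    return structure.use_het_reverse and cS_F < structure.fructose_threshold


def het_specific_rates(mu: float, state, params: HetParams,
                       structure: ModelStructure) -> dict:
    """Specific rates [g g_cell^-1 h^-1] coupled to growth plus the
    substrate-depletion back-reaction rate q_P_AB."""
    for name in ("Y_X_F", "Y_X_A", "Y_X_B"):
        if getattr(params, name) == 0:
            raise ConfigurationError(f"yield coefficient {name} must be nonzero")
    _, cS_F, _, cP_B = _as_het_array(state)
    q_P_AB = 0.0
    if het_reverse_active(cS_F, structure):
        q_P_AB = params.Y_A_B * params.q_B_max * cP_B / (cP_B + params.K_P_B)
    return {
        "q_S_F": mu / params.Y_X_F,
        "q_P_A": mu / params.Y_X_A,
        "q_P_B": mu / params.Y_X_B,
        "q_P_AB": q_P_AB,
    }


def het_rhs(t: float, state, params: HetParams,
            structure: ModelStructure) -> np.ndarray:
    """Right-hand side of the four heterotrophic mass balances.

    Accepts a :class:`HetState` or a length-4 array ordered as
    ``HET_STATE_NAMES``; returns the derivative array in the same order.
    """
    y = _as_het_array(state)
    X = y[0]
    mu = het_growth_rate(y, params, t, structure)
    mu_d = het_death_rate(y, params, structure)
    q = het_specific_rates(mu, y, params, structure)
    dX = (mu - mu_d) * X
    dS = -q["q_S_F"] * X
    dA = q["q_P_A"] * X + q["q_P_AB"] * X
    dB = q["q_P_B"] * X - (q["q_P_AB"] / params.Y_A_B) * X
    return np.array([dX, dS, dA, dB])
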