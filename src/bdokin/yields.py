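"""Biomass, carbon-yield and hydrogen-efficiency accounting for batch runs.

Implements the bookkeeping used to score production experiments: the
OD600-to-dry-biomass calibration, biomass yields on a mass and mole basis
(biomass approximated as C4H7O1.5N, 93 g mol^-1), exponential-phase specific
growth rate, ideal-gas headspace mole accounting at ambient sampling
conditions, product carbon yields with correction for the liquid and gas
volumes withdrawn at each sampling, the stoichiometric hydrogen demand of
CO2-derived products, pathway ceilings, and volumetric productivities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .units import (
    ATOMIC_WEIGHTS,
    FORMULAS,
    MOLAR_MASS,
    R_SI,
    molar_mass_of,
)

__all__ = [
    "SamplingRecord",
    "YieldReport",
    "od_to_biomass",
    "biomass_from_od",
    "biomass_yield",
    "specific_growth_rate",
    "headspace_moles",
    "carbon_yield",
    "h2_balance",
    "theoretical_h2",
    "hydrogen_efficiency",
    "theoretical_max_yield",
    "volumetric_productivity",
]

# OD600 -> dry biomass calibration [g L^-1]: slope and intercept of the
# linear dry-weight correlation.
OD_SLOPE = 0.6416
OD_INTERCEPT = 0.0632

BIOMASS_MOLAR_MASS = MOLAR_MASS["biomass"]  # 93 g/mol convention


@dataclass
class SamplingRecord:
    """Volumes withdrawn at one sampling time point."""

    time_h: float
    liquid_mL: float = 0.0
    gas_mL: float = 0.0
    n2_topup: bool = True

    def __post_init__(self) -> None:
        if self.liquid_mL < 0 or self.gas_mL < 0:
            raise ValueError("sample volumes must be >= 0")


@dataclass
class YieldReport:
    """Summary of a production run in the conventional table layout."""

    label: str = ""
    biomass_yield_g_g: float = float("nan")
    biomass_yield_pct: float = float("nan")
    acetoin_yield_pct: float = float("nan")
    bdo_yield_pct: float = float("nan")
    hydrogen_efficiency_pct: Optional[float] = None
    h2_co2_ratio: Optional[float] = None
    productivities: dict = field(default_factory=dict)  # name -> mg/L/h

    @property
    def total_product_yield_pct(self) -> float:
        return self.acetoin_yield_pct + self.bdo_yield_pct

    def to_table(self) -> pd.DataFrame:
        row = {
            "strain": self.label,
            "biomass_yield_g_g": self.biomass_yield_g_g,
            "acetoin_yield_pct": self.acetoin_yield_pct,
            "bdo_yield_pct": self.bdo_yield_pct,
            "total_product_yield_pct": self.total_product_yield_pct,
        }
        if self.hydrogen_efficiency_pct is not None:
            row["hydrogen_efficiency_pct"] = self.hydrogen_efficiency_pct
        if self.h2_co2_ratio is not None:
            row["h2_co2_ratio"] = self.h2_co2_ratio
        for name, v in self.productivities.items():
            row[f"productivity_{name}_mg_L_h"] = v
        return pd.DataFrame([row])


def od_to_biomass(od600):
    """Dry biomass [g L^-1] from OD600 via the linear calibration."""
    od600 = np.asarray(od600, dtype=float)
    if np.any(od600 < 0):
        raise ValueError("OD600 must be >= 0")
    out = OD_SLOPE * od600 + OD_INTERCEPT
    return float(out) if out.ndim == 0 else out


biomass_from_od = od_to_biomass  # alias


def biomass_od_from_dry_mass(biomass_g_L):
    """Inverse of the OD calibration (used when synthesizing OD readings)."""
    return (np.asarray(biomass_g_L, dtype=float) - OD_INTERCEPT) / OD_SLOPE


def biomass_yield(delta_cx: float, delta_cs: float,
                  substrate_molar_mass: float = MOLAR_MASS["fructose"]) -> dict:
    """Biomass yield on substrate.

    Returns the mass yield Y_bmass = dX/dS [g g^-1] and the mole-basis
    percentage, converting biomass with the 93 g mol^-1 C4H7O1.5N convention.
    """
    if delta_cs <= 0:
        raise ValueError("substrate consumption must be > 0")
    y_mass = delta_cx / delta_cs
    y_pct = 100.0 * (delta_cx / BIOMASS_MOLAR_MASS) / (delta_cs / substrate_molar_mass)
    return {"Y_bmass": y_mass, "Y_X_S_pct": y_pct}


def specific_growth_rate(od_t0: float, od_t1: float, t0: float, t1: float) -> float:
    """Exponential-phase specific growth rate mu = (ln OD1 - ln OD0)/(t1 - t0)."""
    if t1 <= t0:
        raise ValueError("t1 must be after t0")
    if od_t0 <= 0 or od_t1 <= 0:
        raise ValueError("optical densities must be > 0")
    return (math.log(od_t1) - math.log(od_t0)) / (t1 - t0)


def headspace_moles(P_pa: float, V_gas_m3: float, T_K: float,
                    fractions: Optional[dict] = None) -> dict:
    """Ideal-gas headspace mole accounting at sampling conditions.

    ``n_total = P V / (R T)`` with R = 8.314 J mol^-1 K^-1; per-gas moles are
    the mole fraction times the total. The untracked remainder is reported as
    inert N2 so that the per-gas moles always sum to the total.
    """
    if P_pa <= 0 or V_gas_m3 <= 0 or T_K <= 0:
        raise ValueError("P, V and T must be > 0")
    n_total = P_pa * V_gas_m3 / (R_SI * T_K)
    per_gas: dict = {}
    if fractions:
        s = sum(fractions.values())
        if s > 1.0 + 1e-9:
            raise ValueError("gas fractions sum above 1")
        per_gas = {g: f * n_total for g, f in fractions.items()}
        if "n2" not in {g.lower() for g in fractions}:
            per_gas["N2"] = (1.0 - s) * n_total
    return {"n_total": n_total, "per_gas": per_gas}


def _liquid_volumes(times_h, v0_L: float,
                    sampling: Optional[Sequence[SamplingRecord]]) -> np.ndarray:
    """Liquid volume [L] in place at each time point, before that point's
    own sample is withdrawn."""
    times_h = np.asarray(times_h, dtype=float)
    v = np.full(len(times_h), v0_L)
    if sampling:
        removed = 0.0
        rec = {round(s.time_h, 9): s for s in sampling}
        for k, t in enumerate(times_h):
            v[k] = v0_L - removed
            s = rec.get(round(float(t), 9))
            if s is not None:
                removed += s.liquid_mL / 1000.0
        if removed >= v0_L:
            raise ValueError("cumulative liquid sampling exceeds the initial volume")
    return v


def carbon_yield(times_h, product_mM, mode: str, *, v0_L: float,
                 substrate_mM=None, sampling: Optional[Sequence[SamplingRecord]] = None,
                 co2_moles=None, nahco3_mol: float = 0.0,
                 headspace_V_L: Optional[float] = None,
                 carbons_per_product: int = 4, basis: str = "carbon") -> float:
    """Product carbon yield [%] with sampling-volume bookkeeping.

    Heterotrophic mode: moles of product formed (including moles carried out
    in earlier liquid samples) per mole of fructose consumed, as a percentage
    of the 1 mol/mol pathway ceiling.

    Autotrophic mode: product relative to carbon consumed from headspace CO2
    (a mole series aligned with ``times_h``; gas-sample withdrawals are
    credited back using ``headspace_V_L``) plus the initial NaHCO3 loading.
    ``basis='carbon'`` counts 4 carbons per product molecule, matching the
    convention where converting every CO2 into product carbon scores 100%;
    ``basis='mole'`` reports mol product per mol CO2 (ceiling 25%).
    """
    times_h = np.asarray(times_h, dtype=float)
    c_prod = np.asarray(product_mM, dtype=float) / 1000.0  # mol L^-1
    v_liq = _liquid_volumes(times_h, v0_L, sampling)

    # product moles formed = final amount + amounts withdrawn - initial
    removed_prod = 0.0
    if sampling:
        rec = {round(s.time_h, 9): s for s in sampling}
        for k, t in enumerate(times_h[:-1]):
            s = rec.get(round(float(t), 9))
            if s is not None:
                removed_prod += c_prod[k] * s.liquid_mL / 1000.0
    v_end = v_liq[-1]
    n_prod = c_prod[-1] * v_end + removed_prod - c_prod[0] * v0_L
    if n_prod < 0:
        n_prod = 0.0

    if mode == "het":
        if substrate_mM is None:
            raise ValueError("het mode needs the fructose series")
        c_sub = np.asarray(substrate_mM, dtype=float) / 1000.0
        removed_sub = 0.0
        if sampling:
            for k, t in enumerate(times_h[:-1]):
                s = rec.get(round(float(t), 9))
                if s is not None:
                    removed_sub += c_sub[k] * s.liquid_mL / 1000.0
        n_sub = c_sub[0] * v0_L - c_sub[-1] * v_end - removed_sub
        if n_sub <= 0:
            raise ValueError("substrate consumption must be > 0")
        return 100.0 * n_prod / n_sub

    if mode == "auto":
        if co2_moles is None:
            raise ValueError("auto mode needs the headspace CO2 mole series")
        n_co2 = np.asarray(co2_moles, dtype=float)
        removed_co2 = 0.0
        if sampling:
            if headspace_V_L is None:
                raise ValueError("gas-sample crediting needs headspace_V_L")
            rec = {round(s.time_h, 9): s for s in sampling}
            for k, t in enumerate(times_h[:-1]):
                s = rec.get(round(float(t), 9))
                if s is not None and s.gas_mL > 0:
                    removed_co2 += n_co2[k] * s.gas_mL / 1000.0 / headspace_V_L
        n_c = n_co2[0] + nahco3_mol - n_co2[-1] - removed_co2
        if n_c <= 0:
            raise ValueError("substrate (CO2) consumption must be > 0")
        factor = carbons_per_product if basis == "carbon" else 1.0
        return 100.0 * factor * n_prod / n_c

    raise ValueError(f"unknown mode {mode!r}; expected 'het' or 'auto'")


def h2_balance(product: str) -> dict:
    """Stoichiometric coefficients of the CO2-reduction balance
    ``C CO2 + a H2 (+ N NH3) -> product + w H2O`` for a registered product.

    Element balances: O gives ``w = 2C - O_p``; H gives
    ``a = H_p/2 + 2C - O_p - 1.5 N``.
    """
    if product not in FORMULAS:
        raise KeyError(f"no formula registered for product {product!r}")
    f = FORMULAS[product]
    C, H, O = f.get("C", 0), f.get("H", 0), f.get("O", 0)
    N = f.get("N", 0)
    w = 2 * C - O
    a = H / 2.0 + 2 * C - O - 1.5 * N
    return {"co2": C, "h2": a, "nh3": N, "h2o": w}


def theoretical_h2(product: str, n_mol: float = 1.0) -> float:
    """Moles of H2 stoichiometrically required to build ``n_mol`` of product
    from CO2 (and NH3 for nitrogenous biomass)."""
    return h2_balance(product)["h2"] * n_mol


def hydrogen_efficiency(products_mol: dict, h2_consumed_mol: float,
                        biomass_mol: float = 0.0,
                        include_biomass: bool = False) -> float:
    """Hydrogen efficiency [%]: theoretical H2 demand of the products formed
    over the H2 actually consumed. ``products_mol`` maps registered product
    names to moles formed; biomass (with NH3 as N source) is counted only
    when ``include_biomass``."""
    if h2_consumed_mol <= 0:
        raise ValueError("H2 consumed must be > 0")
    n_theory = sum(theoretical_h2(name, n) for name, n in products_mol.items())
    if include_biomass and biomass_mol > 0:
        n_theory += theoretical_h2("biomass", biomass_mol)
    return 100.0 * n_theory / h2_consumed_mol


# Pathway stoichiometry: products are made from 2 pyruvate; fructose yields
# 2 pyruvate per molecule, the Calvin cycle fixes 6 CO2 per 2 pyruvate of
# which 2 CO2 are released again during acetoin synthesis (net 4).
_PYRUVATE_PER_PRODUCT = 2
_SUBSTRATE_PER_2_PYRUVATE = {"fructose": 1.0, "co2": 6.0}
_CO2_RELEASED_PER_PRODUCT = 2.0
_C4_PRODUCTS = ("acetoin", "bdo")


def theoretical_max_yield(substrate: str, product: str) -> float:
    """Stoichiometric ceiling [%] on the mole yield of product per substrate:
    100% for fructose -> acetoin/2,3-BDO (1 mol/mol), 25% for CO2-derived
    products (net 4 CO2 per product)."""
    substrate = substrate.lower()
    product = product.lower().replace("2,3-bdo", "bdo")
    if product == substrate:
        return 100.0
    if product not in _C4_PRODUCTS or substrate not in _SUBSTRATE_PER_2_PYRUVATE:
        raise ValueError(f"unsupported substrate/product pair {substrate!r} -> {product!r}")
    substrate_per_product = _SUBSTRATE_PER_2_PYRUVATE[substrate]
    if substrate == "co2":
        substrate_per_product -= _CO2_RELEASED_PER_PRODUCT
    return 100.0 / substrate_per_product


def volumetric_productivity(conc_mg_L, times_h, at="first") -> float:
    """Volumetric productivity [mg L^-1 h^-1]: product gained since the start
    divided by elapsed time, evaluated at the first sampling point, at a
    named time, or maximized over the supplied (possibly dense) grid."""
    c = np.asarray(conc_mg_L, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if len(c) < 2 or len(c) != len(t):
        raise ValueError("need >= 2 aligned time points")
    gained = c - c[0]
    elapsed = t - t[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(elapsed > 0, gained / np.where(elapsed > 0, elapsed, 1.0), 0.0)
    if at == "first":
        return float(rate[1])
    if at == "max":
        return float(np.max(rate))
    idx = int(np.argmin(np.abs(t - float(at))))
    return float(rate[idx])
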