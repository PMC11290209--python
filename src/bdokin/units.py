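"""Physical constants, unit conversions and gas solubilities.

Internal unit system
--------------------
Liquid concentrations are g L^-1 (dissolved gases: mol L^-1), time is hours,
volumes are litres. The gas-phase model works in atm with
R = 0.082057 L atm mol^-1 K^-1 so that atm-based Henry constants plug into
``c* = x * P * H`` without mixed Pa/m^3 conversions. Headspace mole
accounting for yield calculations uses SI (Pa, m^3, R = 8.314 J mol^-1 K^-1)
at ambient sampling temperature.
"""

from __future__ import annotations

import math

# Gas constants
R_SI = 8.314  # J mol^-1 K^-1, used for headspace mole accounting
R_L_ATM = 0.082057  # L atm mol^-1 K^-1, used inside the gas-phase ODEs

# Temperatures
T_MODEL = 303.15  # K, cultivation temperature (30 degC)
T_AMBIENT = 298.15  # K, ambient temperature assumed at gas sampling

ATM_PER_BAR = 0.986923

# Molar masses [g mol^-1]
MOLAR_MASS = {
    "fructose": 180.16,
    "acetoin": 88.11,
    "bdo": 90.12,  # 2,3-butanediol
    "biomass": 93.0,  # C4H7O1.5N, rounded convention
    "co2": 44.01,
    "nahco3": 84.01,
}

#: Elemental composition of compounds used in stoichiometric balances.
FORMULAS = {
    "acetoin": {"C": 4, "H": 8, "O": 2},
    "bdo": {"C": 4, "H": 10, "O": 2},
    "biomass": {"C": 4, "H": 7, "O": 1.5, "N": 1},
    "fructose": {"C": 6, "H": 12, "O": 6},
    "co2": {"C": 1, "O": 2},
}

ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

# Henry's-law solubilities H [mol L^-1 atm^-1] at the 298.15 K reference,
# with van 't Hoff temperature-dependence coefficients d(ln H)/d(1/T) [K]
# (standard compilation values; overridable through AutoParams).
HENRY_REF_298 = {"o2": 1.3e-3, "co2": 3.4e-2, "h2": 7.8e-4}
HENRY_VANT_HOFF_K = {"o2": 1500.0, "co2": 2400.0, "h2": 500.0}


def molar_mass_of(formula: dict[str, float]) -> float:
    """Molar mass [g mol^-1] of an elemental composition dict."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())


def henry_constant(gas: str, T: float = T_MODEL) -> float:
    """Henry solubility H [mol L^-1 atm^-1] of ``gas`` at temperature ``T`` [K].

    van 't Hoff correction from the 298.15 K reference value:
    ``H(T) = H_ref * exp(C * (1/T - 1/298.15))``.
    """
    key = gas.lower()
    if key not in HENRY_REF_298:
        raise KeyError(f"no Henry constant tabulated for gas {gas!r}")
    h_ref = HENRY_REF_298[key]
    c = HENRY_VANT_HOFF_K[key]
    return h_ref * math.exp(c * (1.0 / T - 1.0 / 298.15))


def mm_to_g_per_l(value_mM: float, compound: str) -> float:
    """Convert mM to g L^-1 using the compound's molar mass."""
    return value_mM * MOLAR_MASS[compound] / 1000.0


def g_per_l_to_mm(value_gL: float, compound: str) -> float:
    """Convert g L^-1 to mM."""
    return value_gL * 1000.0 / MOLAR_MASS[compound]
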