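"""Synthetic batch datasets with known ground truth.

Emulates the study designs end to end: heterotrophic flasks started at
OD600 = 0.05 with 20 mM fructose and sampled roughly daily; autotrophic
closed 1-L bottles at OD600 = 4 with 50 mL liquid under 80/5/15%
H2/CO2/O2 at 1 bar, where each sampling withdraws 1 mL of liquid and 30 mL
of headspace gas and the pressure is restored with inert N2. Observations
are the ground-truth trajectory evaluated at the sampling times, corrupted
by multiplicative Gaussian noise with a small additive floor and clipped at
zero; OD600 readings are produced by inverting the dry-weight calibration so
that estimation exercises the OD-to-biomass path. A seed fixes the entire
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .estimate import Dataset
from .model_auto import AutoParams, AutoState, GasEnv
from .model_het import HetParams, HetState, ModelStructure
from .simulate import Trajectory, integrate
from .units import g_per_l_to_mm, mm_to_g_per_l
from .yields import SamplingRecord, biomass_od_from_dry_mass, od_to_biomass

__all__ = [
    "NoiseModel",
    "SamplingProtocol",
    "SynthDesign",
    "default_het_params",
    "default_auto_params",
    "default_het_design",
    "default_auto_design",
    "apply_sampling_protocol",
    "generate_batch_dataset",
]

# Default measurement noise: coefficients of variation per observable class
# and small additive floors (internal units).
DEFAULT_CV = {"OD600": 0.05, "fructose": 0.05, "acetoin": 0.05, "bdo": 0.05,
              "o2_frac": 0.02, "co2_frac": 0.02, "h2_frac": 0.02}
DEFAULT_FLOOR = {"OD600": 0.01, "fructose": 0.005, "acetoin": 0.005,
                 "bdo": 0.005, "o2_frac": 0.001, "co2_frac": 0.001,
                 "h2_frac": 0.001}


@dataclass
class NoiseModel:
    cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))
    floor: dict = field(default_factory=lambda: dict(DEFAULT_FLOOR))

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cv.values()) or any(
                v < 0 for v in self.floor.values()):
            raise ValueError("noise CVs and floors must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(cv={k: 0.0 for k in DEFAULT_CV},
                   floor={k: 0.0 for k in DEFAULT_FLOOR})


@dataclass
class SamplingProtocol:
    liquid_sample_mL: float = 1.0
    gas_sample_mL: float = 0.0  # 30.0 for the autotrophic bottle protocol
    n2_topup: bool = True


@dataclass
class SynthDesign:
    """Full specification of a synthetic experiment."""

    mode: str  # "het" | "auto"
    params: object
    structure: ModelStructure
    state0: object
    sampling_times: np.ndarray
    noise: NoiseModel = field(default_factory=NoiseModel)
    protocol: SamplingProtocol = field(default_factory=SamplingProtocol)
    env: Optional[GasEnv] = None
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(self.sampling_times) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    def horizon(self) -> tuple:
        return (float(self.sampling_times[0]), float(self.sampling_times[-1]))


def default_het_params() -> HetParams:
    """Ground-truth heterotrophic parameters.

    Chosen to reproduce the observed magnitudes of the flask runs: specific
    growth rate in the 0.05 h^-1 range, 20 mM fructose consumed within
    roughly two days, ~14 mM acetoin and ~6 mM 2,3-BDO accumulated, a slow
    back-reaction after fructose exhaustion with an acetoin-per-BDO yield
    near 0.97 g/g, and product inhibition only relevant above ~10 mM BDO.
    """
    return HetParams(
        mu_max=0.055, K_S_F=0.3, Y_X_F=0.085, Y_X_A=0.25, Y_X_B=0.55,
        mu_d_min=0.0005, mu_d_max=0.008,
        q_B_max=0.01, K_P_B=0.2, Y_A_B=0.97,
        t_lag=10.0, K_I_B=0.9,
    )


def default_het_structure() -> ModelStructure:
    return ModelStructure(use_lag=True, use_product_inhibition=True,
                          use_het_reverse=True)


def default_auto_params() -> AutoParams:
    """Ground-truth autotrophic parameters.

    Cell-suspension bottles grow slowly (mu_max = 0.02 h^-1); gas yields
    follow the knallgas biomass stoichiometry (~15 g/mol O2, ~22 g/mol CO2,
    ~3.4 g/mol H2, an H2/CO2 consumption ratio near 6.5) so the 5% CO2
    headspace (~2.2 mmol) is consumed within the first day, products reach
    ~6-10 mM BDO, and the exchange reactions run at the gentle rates seen
    after depletion. kLa reflects a shaken closed bottle.
    """
    return AutoParams(
        mu_max=0.018, K_O2=1e-4, K_CO2=2e-4, K_H2=2e-4,
        Y_X_A=3.0, Y_X_B=1.3, Y_X_O2=15.0, Y_X_CO2=22.0, Y_X_H2=3.3,
        kLa=30.0, mu_d_min=0.0005, mu_d_max=0.005,
        q_f1_A_max=0.004, K_f1_A=0.1, Y_f1_B_A=1.0,
        q_f2_A_max=0.002, K_f2_A=0.1, Y_f2_B_A=1.0,
        q_r_B_max=0.004, K_r_B=0.2, Y_r_A_B=0.97,
    )


def default_auto_structure() -> ModelStructure:
    return ModelStructure(use_gas_switch=True, use_auto_forward1=True,
                          use_auto_forward2=True, use_auto_reverse=True)


def _het_state0() -> HetState:
    return HetState(X=od_to_biomass(0.05), cS_F=mm_to_g_per_l(20.0, "fructose"))


def _auto_state0(params: AutoParams, env: GasEnv) -> AutoState:
    # dissolved gases start at equilibrium with the initial headspace
    return AutoState(
        X=od_to_biomass(4.0), cP_A=0.0, cP_B=0.0,
        cO2_g=0.15, cCO2_g=0.05, cH2_g=0.80,
        cO2_l=0.15 * env.P * params.H_O2,
        cCO2_l=0.05 * env.P * params.H_CO2,
        cH2_l=0.80 * env.P * params.H_H2,
    )


def default_het_design(seed: int = 0, n_points: int = 12,
                       horizon_h: float = 120.0,
                       noise: Optional[NoiseModel] = None) -> SynthDesign:
    """Heterotrophic flask run sampled at ``n_points`` evenly spread over
    the horizon (12 points over 120 h by default, roughly daily)."""
    return SynthDesign(
        mode="het", params=default_het_params(),
        structure=default_het_structure(), state0=_het_state0(),
        sampling_times=np.linspace(0.0, horizon_h, n_points),
        noise=noise if noise is not None else NoiseModel(),
        protocol=SamplingProtocol(liquid_sample_mL=1.0, gas_sample_mL=0.0),
        env=None, seed=seed, label="synthetic-het",
    )


def default_auto_design(seed: int = 0, n_points: int = 6,
                        horizon_h: float = 120.0,
                        noise: Optional[NoiseModel] = None) -> SynthDesign:
    """Autotrophic closed-bottle run with daily-ish sampling and the 1 mL
    liquid / 30 mL gas withdrawal protocol."""
    params = default_auto_params()
    env = GasEnv()
    return SynthDesign(
        mode="auto", params=params, structure=default_auto_structure(),
        state0=_auto_state0(params, env),
        sampling_times=np.linspace(0.0, horizon_h, n_points),
        noise=noise if noise is not None else NoiseModel(),
        protocol=SamplingProtocol(liquid_sample_mL=1.0, gas_sample_mL=30.0),
        env=env, seed=seed, label="synthetic-auto",
    )


def apply_sampling_protocol(truth: Trajectory, design: SynthDesign) -> pd.DataFrame:
    """Per-sampling-time bookkeeping of the withdrawal protocol.

    Liquid volume shrinks by the liquid sample at each point; each gas sample
    removes a proportional share of every gas's moles and the N2 top-up
    restores total pressure, so the tracked mole fractions shrink by the
    sampled share ``v_gas / V_G`` cumulatively.

    Returns a frame with ``time_h``, ``v_liq_L`` (volume in place when the
    sample is drawn) and ``gas_dilution`` (cumulative factor applied to the
    tracked headspace fractions at that time).
    """
    times = design.sampling_times
    v0 = design.env.V_L if design.env is not None else 0.3
    v_gas = design.env.V_G if design.env is not None else None
    liq = design.protocol.liquid_sample_mL / 1000.0
    rows = []
    removed = 0.0
    dilution = 1.0
    for k, t in enumerate(times):
        v_liq = v0 - removed
        if v_liq <= 0:
            raise ValueError("cumulative liquid sampling exceeds the initial volume")
        rows.append({"time_h": float(t), "v_liq_L": v_liq,
                     "gas_dilution": dilution})
        removed += liq
        if design.protocol.gas_sample_mL > 0 and v_gas is not None:
            share = design.protocol.gas_sample_mL / 1000.0 / v_gas
            if design.protocol.n2_topup:
                dilution *= 1.0 - share
    return pd.DataFrame(rows)


def generate_batch_dataset(design: SynthDesign):
    """Simulate the ground truth, observe it at the sampling times through
    the withdrawal protocol and the noise model, and return
    ``(Dataset, truth Trajectory)``. Identical seeds give identical output.
    """
    rng = np.random.default_rng(design.seed)
    t0, t_end = design.horizon()
    dense = np.union1d(np.linspace(t0, t_end, 241), design.sampling_times)
    truth = integrate(design.mode, design.state0, design.params,
                      design.structure, design.env, t_span=(t0, t_end),
                      t_eval=dense)
    book = apply_sampling_protocol(truth, design)

    def noisy(obs_name: str, value: float) -> float:
        cv = design.noise.cv.get(obs_name, 0.0)
        floor = design.noise.floor.get(obs_name, 0.0)
        v = value * (1.0 + cv * rng.standard_normal()) + floor * rng.standard_normal()
        return max(v, 0.0)

    rows = []
    for k, t in enumerate(design.sampling_times):
        x_true = truth.interp("X", t)
        od_true = float(biomass_od_from_dry_mass(x_true))
        rows.append((t, "OD600", noisy("OD600", od_true), ""))
        if design.mode == "het":
            for obs, state in (("fructose", "cS_F"), ("acetoin", "cP_A"),
                               ("bdo", "cP_B")):
                rows.append((t, obs, noisy(obs, float(truth.interp(state, t))),
                             "g/L"))
        else:
            for obs, state in (("acetoin", "cP_A"), ("bdo", "cP_B")):
                rows.append((t, obs, noisy(obs, float(truth.interp(state, t))),
                             "g/L"))
            dil = float(book.loc[k, "gas_dilution"])
            fracs = {
                obs: noisy(obs, float(truth.interp(state, t)) * dil)
                for obs, state in (("o2_frac", "cO2_g"), ("co2_frac", "cCO2_g"),
                                   ("h2_frac", "cH2_g"))
            }
            # gas chromatograms report normalized fractions: rescale if
            # measurement noise pushed the tracked sum above one
            s = sum(fracs.values())
            if s > 1.0:
                fracs = {obs: v / s for obs, v in fracs.items()}
            for obs, v in fracs.items():
                rows.append((t, obs, v, "frac"))

    obs = pd.DataFrame(rows, columns=["time_h", "observable", "value", "unit"])
    dataset = Dataset(observations=obs,
                      liquid_volume=book[["time_h", "v_liq_L"]],
                      label=design.label)
    return dataset, truth
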