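import numpy as np
import pytest

from bdokin.model_het import HetParams, HetState, ModelStructure
from bdokin.model_auto import AutoParams, AutoState, GasEnv
from bdokin.synthetic_data import (
    NoiseModel,
    default_auto_design,
    default_het_design,
)


@pytest.fixture
def het_params() -> HetParams:
    return HetParams(mu_max=0.055, K_S_F=0.3, Y_X_F=0.085, Y_X_A=0.25,
                     Y_X_B=0.55, mu_d_min=0.0005, mu_d_max=0.008,
                     q_B_max=0.01, K_P_B=0.2, Y_A_B=0.97,
                     t_lag=10.0, K_I_B=0.9)


@pytest.fixture
def het_state() -> HetState:
    return HetState(X=0.1, cS_F=3.6, cP_A=0.2, cP_B=0.1)


@pytest.fixture
def plain_structure() -> ModelStructure:
    return ModelStructure()


@pytest.fixture
def auto_params() -> AutoParams:
    return AutoParams(mu_max=0.018, K_O2=1e-4, K_CO2=2e-4, K_H2=2e-4,
                      Y_X_A=3.0, Y_X_B=1.3, Y_X_O2=15.0, Y_X_CO2=22.0,
                      Y_X_H2=3.3, kLa=30.0, mu_d_min=0.0005, mu_d_max=0.005,
                      q_f1_A_max=0.004, K_f1_A=0.1, Y_f1_B_A=1.0,
                      q_f2_A_max=0.002, K_f2_A=0.1, Y_f2_B_A=1.0,
                      q_r_B_max=0.004, K_r_B=0.2, Y_r_A_B=0.97)


@pytest.fixture
def gas_env() -> GasEnv:
    return GasEnv()


@pytest.fixture
def auto_state(auto_params, gas_env) -> AutoState:
    return AutoState(X=2.63, cP_A=0.1, cP_B=0.3,
                     cO2_g=0.15, cCO2_g=0.05, cH2_g=0.80,
                     cO2_l=0.15 * auto_params.H_O2,
                     cCO2_l=0.05 * auto_params.H_CO2,
                     cH2_l=0.80 * auto_params.H_H2)


@pytest.fixture(scope="session")
def noiseless_het():
    """Noiseless heterotrophic dataset with paired ground truth."""
    from bdokin.synthetic_data import generate_batch_dataset
    design = default_het_design(seed=11, noise=NoiseModel.noiseless())
    dataset, truth = generate_batch_dataset(design)
    return design, dataset, truth


@pytest.fixture(scope="session")
def noiseless_auto():
    from bdokin.synthetic_data import generate_batch_dataset
    design = default_auto_design(seed=11, noise=NoiseModel.noiseless())
    dataset, truth = generate_batch_dataset(design)
    return design, dataset, truth
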