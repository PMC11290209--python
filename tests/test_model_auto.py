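"""Autotrophic kinetics: solubilities, gas-coupled growth, exchange
reactions and the closed-bottle mass balances."""

import numpy as np
import pytest

from bdokin.model_auto import (
    AutoParams,
    AutoState,
    GasEnv,
    auto_death_rate,
    auto_growth_rate,
    auto_rhs,
    equilibrium_solubility,
    exchange_rates,
)
from bdokin.model_het import ConfigurationError, InvalidStateError, ModelStructure
from bdokin.units import henry_constant

from oracles import gas_moles, rk4


class TestSolubility:
    def test_zero_fraction_zero_solubility(self, gas_env):
        assert equilibrium_solubility(0.0, gas_env, 0.03) == 0.0

    def test_linear_in_fraction(self, gas_env):
        c1 = equilibrium_solubility(0.05, gas_env, 0.03)
        c2 = equilibrium_solubility(0.10, gas_env, 0.03)
        assert c2 == pytest.approx(2 * c1)

    def test_co2_solubility_against_tabulated_henry(self, gas_env):
        # independent check: CO2 Henry solubility at 30 degC is about
        # 2.95e-2 mol/(L atm) (3.4e-2 at 25 degC, van 't Hoff ~2400 K)
        h = henry_constant("co2", 303.15)
        assert h == pytest.approx(2.97e-2, rel=0.02)
        c = equilibrium_solubility(0.05, gas_env, h)
        assert c == pytest.approx(0.05 * h, rel=1e-12)


class TestGrowthAndDeath:
    def test_any_zero_gas_kills_growth_in_full_regime(self, auto_params, plain_structure):
        for idx in (6, 7, 8):
            y = np.array([1.0, 0, 0, 0.15, 0.05, 0.8, 1e-3, 1e-3, 1e-3])
            y[idx] = 0.0
            assert auto_growth_rate(y, auto_params, plain_structure, "full") == 0.0

    def test_switched_regime_ignores_co2(self, auto_params, plain_structure):
        y = np.array([1.0, 0, 0, 0.15, 0.05, 0.8, 1.0, 0.0, 1.0])
        mu = auto_growth_rate(y, auto_params, plain_structure, "switched")
        assert mu == pytest.approx(auto_params.mu_max, rel=1e-3)

    def test_triple_half_saturation_gives_eighth(self, auto_params, plain_structure):
        y = np.array([1.0, 0, 0, 0.15, 0.05, 0.8,
                      auto_params.K_O2, auto_params.K_CO2, auto_params.K_H2])
        mu = auto_growth_rate(y, auto_params, plain_structure, "full")
        assert mu == pytest.approx(auto_params.mu_max / 8)

    def test_death_rate_limits(self, auto_params, plain_structure):
        y0 = np.array([1.0, 0, 0, 0.15, 0.05, 0.8, 0, 0, 0])
        assert auto_death_rate(y0, auto_params, plain_structure, "full") == \
            pytest.approx(auto_params.mu_d_min)
        y1 = np.array([1.0, 0, 0, 0.15, 0.05, 0.8, 1.0, 1.0, 1.0])
        assert auto_death_rate(y1, auto_params, plain_structure, "full") == \
            pytest.approx(auto_params.mu_d_min + auto_params.mu_d_max, rel=1e-3)

    def test_switched_death_double_half_saturation(self, auto_params, plain_structure):
        y = np.array([1.0, 0, 0, 0.15, 0.05, 0.8,
                      auto_params.K_O2, 0.0, auto_params.K_H2])
        mu_d = auto_death_rate(y, auto_params, plain_structure, "switched")
        assert mu_d == pytest.approx(
            auto_params.mu_d_min + auto_params.mu_d_max / 4)

    def test_unknown_regime_rejected(self, auto_params, auto_state, plain_structure):
        with pytest.raises(ValueError, match="regime"):
            auto_growth_rate(auto_state, auto_params, plain_structure, "hybrid")


class TestExchangeRates:
    @pytest.fixture
    def full_structure(self):
        return ModelStructure(use_auto_forward1=True, use_auto_forward2=True,
                              use_auto_reverse=True)

    def test_no_exchange_in_growth_regime(self, auto_params, auto_state, full_structure):
        rates = exchange_rates(auto_state, auto_params, full_structure, "growth")
        assert all(v == 0.0 for v in rates.values())

    def test_zero_acetoin_zero_forward(self, auto_params, full_structure):
        y = AutoState(X=1.0, cP_A=0.0, cP_B=0.5)
        rates = exchange_rates(y, auto_params, full_structure, "co2_depleted")
        assert rates["q_f1_A"] == 0.0

    def test_forward_half_saturation(self, auto_params, full_structure):
        y = AutoState(X=1.0, cP_A=auto_params.K_f1_A, cP_B=0.0)
        rates = exchange_rates(y, auto_params, full_structure, "co2_depleted")
        assert rates["q_f1_A"] == pytest.approx(auto_params.q_f1_A_max / 2)

    def test_coupled_rate_is_yield_scaled(self, auto_params, auto_state, full_structure):
        rates = exchange_rates(auto_state, auto_params, full_structure, "co2_depleted")
        assert rates["q_f1_A"] > 0
        assert rates["q_f1_BA"] / rates["q_f1_A"] == pytest.approx(
            auto_params.Y_f1_B_A)
        assert rates["q_r_AB"] / rates["q_r_B"] == pytest.approx(
            auto_params.Y_r_A_B)

    def test_reverse_stops_after_o2_depletion(self, auto_params, auto_state, full_structure):
        rates = exchange_rates(auto_state, auto_params, full_structure, "o2_depleted")
        assert rates["q_r_B"] == 0.0
        assert rates["q_f2_A"] > 0.0
        assert rates["q_f1_A"] == 0.0


class TestRhs:
    def test_equilibrium_no_biomass_is_stationary(self, auto_params, gas_env,
                                                  plain_structure):
        y = AutoState(X=0.0, cO2_g=0.15, cCO2_g=0.05, cH2_g=0.80,
                      cO2_l=0.15 * auto_params.H_O2,
                      cCO2_l=0.05 * auto_params.H_CO2,
                      cH2_l=0.80 * auto_params.H_H2)
        d = auto_rhs(0.0, y, auto_params, gas_env, plain_structure)
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_abiotic_transfer_conserves_each_gas(self, auto_params, gas_env,
                                                 plain_structure):
        """Brute-force mole bookkeeping: with X = 0 and dissolved gases out
        of equilibrium, headspace + dissolved moles of each gas are constant
        along an RK4 integration of the rhs."""
        y0 = AutoState(X=0.0, cO2_g=0.15, cCO2_g=0.05, cH2_g=0.80,
                       cO2_l=0.0, cCO2_l=0.0, cH2_l=0.0).to_array()
        f = lambda t, y: auto_rhs(t, np.clip(y, 0, None), auto_params,
                                  gas_env, plain_structure)
        _, rec = rk4(f, y0, 0.0, 2.0, 1e-3)
        for gi in range(3):
            n0 = gas_moles(y0[3 + gi], y0[6 + gi], gas_env)
            n1 = gas_moles(rec[-1][3 + gi], rec[-1][6 + gi], gas_env)
            assert n1 == pytest.approx(n0, rel=1e-9)

    def test_single_euler_step_matches_hand_arithmetic(self):
        p = AutoParams(mu_max=0.02, K_O2=1e-4, K_CO2=1e-4, K_H2=1e-4,
                       Y_X_A=2.0, Y_X_B=1.0, Y_X_O2=10.0, Y_X_CO2=20.0,
                       Y_X_H2=4.0, kLa=10.0, H_O2=1e-3, H_CO2=3e-2, H_H2=8e-4)
        env = GasEnv(V_L=0.05, V_G=1.0, P=1.0, T=300.0, R=0.082057)
        y = np.array([1.0, 0.0, 0.0, 0.2, 0.1, 0.5, 1e-4, 2e-3, 3e-4])
        # hand-computed pieces
        mu = 0.02 * (1e-4 / 2e-4) * (2e-3 / 2.1e-3) * (3e-4 / 4e-4)
        stars = [0.2 * 1e-3, 0.1 * 3e-2, 0.5 * 8e-4]
        scale = 0.05 * 0.082057 * 300.0 / (1.0 * 1.0)
        d = auto_rhs(0.0, y, p, env, ModelStructure())
        assert d[0] == pytest.approx((mu - 0.0) * 1.0, rel=1e-9)
        assert d[1] == pytest.approx(mu / 2.0, rel=1e-9)
        assert d[2] == pytest.approx(mu / 1.0, rel=1e-9)
        for gi, (star, cl, yld) in enumerate(zip(stars, [1e-4, 2e-3, 3e-4],
                                                 [10.0, 20.0, 4.0])):
            transfer = 10.0 * (star - cl)
            avail = cl / (cl + 1e-8)  # uptake availability regularization
            assert d[6 + gi] == pytest.approx(transfer - mu / yld * avail,
                                              rel=1e-9)
            assert d[3 + gi] == pytest.approx(-transfer * scale, rel=1e-9)

    def test_nan_state_raises_named_error(self, auto_params, gas_env, plain_structure):
        y = np.zeros(9)
        y[4] = float("nan")
        with pytest.raises(InvalidStateError, match="cCO2_g"):
            auto_rhs(0.0, y, auto_params, gas_env, plain_structure)


class TestGasEnv:
    def test_si_constant_with_atm_pressure_rejected(self):
        with pytest.raises(ConfigurationError, match="inconsistent"):
            GasEnv(P=1.0, R=8.314).validate()

    def test_atm_constant_with_pa_pressure_rejected(self):
        with pytest.raises(ConfigurationError, match="inconsistent"):
            GasEnv(P=101325.0, R=0.082057).validate()

    def test_total_moles_of_default_bottle(self):
        env = GasEnv()
        # 1.08 L at 1 atm, 303.15 K
        assert env.total_gas_moles == pytest.approx(0.0434, abs=2e-4)

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(InvalidStateError):
            AutoState(X=1.0, cO2_g=0.5, cCO2_g=0.4, cH2_g=0.3)
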