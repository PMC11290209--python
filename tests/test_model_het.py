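"""Heterotrophic kinetics: rate laws, mass balances and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdokin.model_het import (
    ConfigurationError,
    HetParams,
    HetState,
    InvalidStateError,
    ModelStructure,
    het_death_rate,
    het_growth_rate,
    het_rhs,
    het_specific_rates,
)


class TestGrowthRate:
    def test_zero_substrate_gives_zero_growth(self, het_params, plain_structure):
        s = HetState(X=0.1, cS_F=0.0)
        assert het_growth_rate(s, het_params, 5.0, plain_structure) == 0.0

    def test_half_saturation(self, het_params, plain_structure):
        s = HetState(X=0.1, cS_F=het_params.K_S_F)
        mu = het_growth_rate(s, het_params, 1e6, plain_structure)
        assert mu == pytest.approx(het_params.mu_max / 2)

    def test_lag_factor_scalar_example(self):
        # independently hand-coded: mu = 0.2 * (1.5/2.0) * (1 - e^-1)
        p = HetParams(mu_max=0.2, K_S_F=0.5, Y_X_F=0.3, Y_X_A=0.3, Y_X_B=0.3,
                      t_lag=7.0)
        s = HetState(X=0.1, cS_F=1.5)
        mu = het_growth_rate(s, p, 7.0, ModelStructure(use_lag=True))
        assert mu == pytest.approx(0.2 * 0.75 * (1 - math.exp(-1)), rel=1e-12)

    def test_inhibition_factor(self, het_params):
        st_ = ModelStructure(use_product_inhibition=True)
        s = HetState(X=0.1, cS_F=100.0, cP_B=het_params.K_I_B)
        mu = het_growth_rate(s, het_params, 0.0, st_)
        # saturated Monod and cP_B = K_I_B halves the rate
        assert mu == pytest.approx(
            het_params.mu_max * (100 / (100 + het_params.K_S_F)) / 2)

    def test_missing_lag_parameter_is_config_error(self):
        p = HetParams(mu_max=0.1, K_S_F=0.5, Y_X_F=0.3, Y_X_A=0.3, Y_X_B=0.3)
        with pytest.raises(ConfigurationError, match="t_lag"):
            het_growth_rate(HetState(X=0.1, cS_F=1.0), p, 1.0,
                            ModelStructure(use_lag=True))

    def test_bounded_by_mu_max(self, het_params):
        st_ = ModelStructure(use_lag=True, use_product_inhibition=True)
        for cs, cb, t in [(0.01, 0.0, 1.0), (50.0, 3.0, 200.0), (1.0, 0.5, 8.0)]:
            mu = het_growth_rate(HetState(X=0.1, cS_F=cs, cP_B=cb),
                                 het_params, t, st_)
            assert 0.0 <= mu <= het_params.mu_max

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cs1=st.floats(0, 50), cs2=st.floats(0, 50))
    def test_monotone_in_substrate(self, cs1, cs2):
        p = HetParams(mu_max=0.1, K_S_F=0.4, Y_X_F=0.1, Y_X_A=0.3, Y_X_B=0.5)
        structure = ModelStructure()
        mu1 = het_growth_rate(HetState(X=0.1, cS_F=cs1), p, 1.0, structure)
        mu2 = het_growth_rate(HetState(X=0.1, cS_F=cs2), p, 1.0, structure)
        if cs1 <= cs2:
            assert mu1 <= mu2 + 1e-15

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cb1=st.floats(0, 50), cb2=st.floats(0, 50))
    def test_antitone_in_product_with_inhibition(self, cb1, cb2):
        p = HetParams(mu_max=0.1, K_S_F=0.4, Y_X_F=0.1, Y_X_A=0.3, Y_X_B=0.5,
                      K_I_B=0.9)
        st_ = ModelStructure(use_product_inhibition=True)
        mu1 = het_growth_rate(HetState(X=0.1, cS_F=5, cP_B=cb1), p, 1.0, st_)
        mu2 = het_growth_rate(HetState(X=0.1, cS_F=5, cP_B=cb2), p, 1.0, st_)
        if cb1 <= cb2:
            assert mu1 >= mu2 - 1e-15


class TestDeathRate:
    def test_limits(self, het_params, plain_structure):
        high = het_death_rate(HetState(X=0.1, cS_F=1e9), het_params, plain_structure)
        assert high == pytest.approx(het_params.mu_d_min, rel=1e-6)
        low = het_death_rate(HetState(X=0.1, cS_F=0.0), het_params, plain_structure)
        assert low == pytest.approx(het_params.mu_d_min + het_params.mu_d_max)

    def test_half_saturation(self, het_params, plain_structure):
        mid = het_death_rate(HetState(X=0.1, cS_F=het_params.K_S_F),
                             het_params, plain_structure)
        assert mid == pytest.approx(het_params.mu_d_min + het_params.mu_d_max / 2)

    def test_inhibition_scales_variable_part(self, het_params):
        st_ = ModelStructure(use_product_inhibition=True)
        s = HetState(X=0.1, cS_F=0.0, cP_B=het_params.K_I_B)
        mu_d = het_death_rate(s, het_params, st_)
        assert mu_d == pytest.approx(het_params.mu_d_min + het_params.mu_d_max / 2)


class TestSpecificRates:
    def test_zero_growth_zero_rates(self, het_params, het_state, plain_structure):
        q = het_specific_rates(0.0, het_state, het_params, plain_structure)
        assert all(v == 0.0 for v in q.values())

    def test_uptake_is_growth_over_yield(self, het_params, het_state, plain_structure):
        q = het_specific_rates(0.09, het_state,
                               het_params.with_values(Y_X_F=0.3), plain_structure)
        assert q["q_S_F"] == pytest.approx(0.3)

    def test_reverse_inactive_above_threshold(self, het_params):
        st_ = ModelStructure(use_het_reverse=True)
        s = HetState(X=0.1, cS_F=1.0, cP_B=0.5)  # fructose above 0.05 g/L
        assert het_specific_rates(0.0, s, het_params, st_)["q_P_AB"] == 0.0

    def test_reverse_active_below_threshold(self, het_params):
        st_ = ModelStructure(use_het_reverse=True)
        s = HetState(X=0.1, cS_F=0.0, cP_B=het_params.K_P_B)
        q = het_specific_rates(0.0, s, het_params, st_)
        assert q["q_P_AB"] == pytest.approx(
            het_params.Y_A_B * het_params.q_B_max / 2)

    def test_zero_bdo_zero_reverse(self, het_params):
        st_ = ModelStructure(use_het_reverse=True)
        s = HetState(X=0.1, cS_F=0.0, cP_B=0.0)
        assert het_specific_rates(0.0, s, het_params, st_)["q_P_AB"] == 0.0


class TestRhs:
    def test_no_biomass_no_change(self, het_params, plain_structure):
        d = het_rhs(1.0, HetState(X=0.0, cS_F=2.0, cP_A=0.5, cP_B=0.2),
                    het_params, plain_structure)
        assert np.all(d == 0.0)

    def test_reverse_coupling_locked_by_yield(self, het_params):
        """During reverse-only operation the acetoin gain per unit BDO loss
        is exactly Y_A_B."""
        st_ = ModelStructure(use_het_reverse=True)
        d = het_rhs(1.0, HetState(X=0.4, cS_F=0.0, cP_A=1.0, cP_B=0.5),
                    het_params, st_)
        dA, dB = d[2], d[3]
        assert dA > 0 and dB < 0
        assert dA == pytest.approx(-het_params.Y_A_B * dB, rel=1e-12)

    def test_single_euler_step_matches_hand_arithmetic(self):
        p = HetParams(mu_max=0.1, K_S_F=0.5, Y_X_F=0.2, Y_X_A=0.4, Y_X_B=0.8,
                      mu_d_min=0.01, mu_d_max=0.02)
        s = HetState(X=1.0, cS_F=1.0, cP_A=0.0, cP_B=0.0)
        # hand: mu = 0.1*(1/1.5) = 1/15; mu_d = 0.01 + 0.02*(0.5/1.5)
        mu = 0.1 / 1.5
        mu_d = 0.01 + 0.02 / 3
        d = het_rhs(0.0, s, p, ModelStructure())
        h = 0.1
        expected = np.array([
            1.0 + h * (mu - mu_d) * 1.0,
            1.0 - h * (mu / 0.2),
            0.0 + h * (mu / 0.4),
            0.0 + h * (mu / 0.8),
        ])
        stepped = s.to_array() + h * d
        np.testing.assert_allclose(stepped, expected, rtol=1e-14)

    def test_nan_state_raises_named_error(self, het_params, plain_structure):
        with pytest.raises(InvalidStateError, match="cS_F"):
            het_rhs(0.0, np.array([0.1, float("nan"), 0.0, 0.0]),
                    het_params, plain_structure)

    def test_grossly_negative_state_raises(self, het_params, plain_structure):
        with pytest.raises(InvalidStateError, match="cP_A"):
            het_rhs(0.0, np.array([0.1, 1.0, -0.5, 0.0]),
                    het_params, plain_structure)

    def test_depleted_field_not_driven_negative_by_euler_step(
            self, het_params, plain_structure):
        """Clipping contract: one explicit Euler step from a zeroed field
        stays non-negative."""
        s = HetState(X=0.5, cS_F=0.0, cP_A=0.1, cP_B=0.1)
        d = het_rhs(1.0, s, het_params, plain_structure)
        stepped = s.to_array() + 0.5 * d
        assert np.all(stepped >= -1e-12)


class TestValidation:
    def test_yield_ceiling_catches_unit_mistakes(self):
        p = HetParams(mu_max=0.1, K_S_F=0.5, Y_X_F=85.0, Y_X_A=0.3, Y_X_B=0.3)
        with pytest.raises(ConfigurationError, match="ceiling"):
            p.validate()

    def test_nonpositive_parameter_rejected(self):
        p = HetParams(mu_max=0.0, K_S_F=0.5, Y_X_F=0.3, Y_X_A=0.3, Y_X_B=0.3)
        with pytest.raises(ConfigurationError, match="mu_max"):
            p.validate()

    def test_inverted_switch_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelStructure(switch_mode="smooth")

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelStructure(depletion_thresholds={"fructose": -0.1})
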