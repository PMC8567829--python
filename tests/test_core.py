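"""Node-equation unit tests: currents, transfer function, drifts,
steady-state gating, and the single-synapse kinetics oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdmf import (
    Concentrations,
    ModelParameters,
    NodeState,
    SynapseOracleConfig,
    destexhe_oracle,
    gating_drift,
    input_currents,
    plasticity_drift,
    steady_state_gating,
    transfer_rate,
)


class TestModelParameters:
    def test_defaults_are_standard_set(self, params):
        assert params.I0 == 0.382
        assert params.WI * params.I0 == pytest.approx(0.2674)
        assert (params.alphaE, params.betaE) == (0.072, 0.0066)
        assert (params.alphaI, params.betaI) == (0.53, 0.18)
        assert (params.G, params.gamma, params.rho) == (0.69, 1.0, 3.0)

    @pytest.mark.parametrize("bad", [{"rho": 0.0}, {"aE": -1.0}, {"betaI": 0.0}])
    def test_nonpositive_constants_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            Concentrations(Tglu=-1.0)


class TestInputCurrents:
    def test_zero_gating_gives_external_currents_only(self, params):
        st_ = NodeState(SE=np.zeros(3), SI=np.zeros(3), J=np.full(3, 5.0))
        C = np.zeros((3, 3))
        IE, II = input_currents(st_, params, C)
        assert IE == pytest.approx([0.382] * 3)
        assert II == pytest.approx([0.2674] * 3)

    def test_single_node_worked_value(self, params):
        st_ = NodeState(SE=np.array([0.2]), SI=np.array([0.1]), J=np.array([1.0]))
        IE, _ = input_currents(st_, params, np.zeros((1, 1)), G=0.0)
        assert IE[0] == pytest.approx(0.382 + 1.4 * 0.15 * 0.2 - 0.1)

    def test_long_range_term(self, params):
        st_ = NodeState(SE=np.array([0.2, 0.4]), SI=np.zeros(2), J=np.zeros(2))
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        IE, _ = input_currents(st_, params, C, G=0.69)
        local = params.WE * params.I0 + params.wplus * params.JNMDA * 0.2
        assert IE[0] - local == pytest.approx(0.69 * 0.15 * 0.4)

    def test_nonzero_diagonal_rejected(self, params):
        st_ = NodeState(SE=np.zeros(2), SI=np.zeros(2), J=np.zeros(2))
        with pytest.raises(ValueError, match="diagonal"):
            input_currents(st_, params, np.eye(2))

    def test_dimension_mismatch_rejected(self, params):
        st_ = NodeState(SE=np.zeros(3), SI=np.zeros(3), J=np.zeros(3))
        with pytest.raises(ValueError):
            input_currents(st_, params, np.zeros((2, 2)))


class TestTransferRate:
    def test_removable_singularity_limit(self, params):
        # a I = b  ->  r = 1/d
        assert transfer_rate(params.bE / params.aE, params.aE, params.bE, params.dE) \
            == pytest.approx(1.0 / params.dE)

    @pytest.mark.parametrize(
        "I,expected",
        [(0.5, 30.0 / -np.expm1(-4.8)), (0.4, 5.763327647909741)],
    )
    def test_worked_values_excitatory(self, I, expected, params):
        assert transfer_rate(I, params.aE, params.bE, params.dE) == pytest.approx(expected)

    def test_continuity_around_singularity(self, params):
        a, b, d = params.aE, params.bE, params.dE
        eps = 1e-7
        left = transfer_rate(b / a - eps, a, b, d)
        right = transfer_rate(b / a + eps, a, b, d)
        assert left == pytest.approx(1 / d, abs=1e-4)
        assert right == pytest.approx(1 / d, abs=1e-4)

    def test_nonfinite_input_rejected(self, params):
        with pytest.raises(ValueError):
            transfer_rate(np.nan, params.aE, params.bE, params.dE)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=-2.0, max_value=2.0))
    def test_nonnegative_everywhere(self, I):
        assert transfer_rate(I, 310.0, 125.0, 0.16) >= 0.0

    def test_asymptotically_linear(self, params):
        # r(I) - (a I - b) -> 0 for strong drive
        I = 1.5
        x = params.aE * I - params.bE
        assert transfer_rate(I, params.aE, params.bE, params.dE) - x == pytest.approx(0.0, abs=1e-10)

    def test_deeply_hyperpolarized_rate_is_zero(self, params):
        assert transfer_rate(-1e4, params.aE, params.bE, params.dE) == 0.0


class TestGatingDrift:
    def test_absorbing_floor(self, params, conc):
        st_ = NodeState(SE=np.zeros(2), SI=np.zeros(2), J=np.ones(2))
        dSE, dSI = gating_drift(st_, np.zeros(2), np.zeros(2), conc, params)
        assert np.all(dSE == 0) and np.all(dSI == 0)

    def test_pure_decay_at_saturation(self, params, conc):
        st_ = NodeState(SE=np.ones(1), SI=np.ones(1), J=np.ones(1))
        dSE, dSI = gating_drift(st_, np.array([50.0]), np.array([50.0]), conc, params)
        assert dSE[0] == pytest.approx(-params.betaE)
        assert dSI[0] == pytest.approx(-params.betaI)

    def test_zero_drift_at_analytic_steady_state(self, params, conc):
        sss = steady_state_gating(params.alphaE, params.betaE, conc.Tglu, 3.0)
        st_ = NodeState(SE=np.array([sss]), SI=np.array([0.0]), J=np.ones(1))
        dSE, _ = gating_drift(st_, np.array([3.0]), np.array([0.0]), conc, params)
        assert dSE[0] == pytest.approx(0.0, abs=1e-12)

    def test_boundary_signs_keep_gating_in_unit_interval(self, params, conc):
        st_ = NodeState(SE=np.array([0.0, 1.0]), SI=np.array([0.0, 1.0]), J=np.ones(2))
        rates = np.array([123.0, 321.0])
        dSE, dSI = gating_drift(st_, rates, rates, conc, params)
        assert dSE[0] >= 0 and dSI[0] >= 0
        assert dSE[1] <= 0 and dSI[1] <= 0

    def test_negative_rate_rejected(self, params, conc):
        st_ = NodeState(SE=np.zeros(1), SI=np.zeros(1), J=np.ones(1))
        with pytest.raises(ValueError):
            gating_drift(st_, np.array([-1.0]), np.zeros(1), conc, params)


class TestPlasticityDrift:
    def test_zero_at_target_rate(self, params):
        assert plasticity_drift(params.rho, 9.0, params) == 0.0

    def test_zero_when_inhibition_silent(self, params):
        assert plasticity_drift(10.0, 0.0, params) == 0.0

    def test_unit_convention_worked_value(self, params):
        # rE=4, rI=9, gamma=1: gamma * (9/1000) * (1/1000) per ms
        assert plasticity_drift(4.0, 9.0, params) == pytest.approx(9.0e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(min_value=0.0, max_value=100.0),
           st.floats(min_value=0.01, max_value=100.0))
    def test_sign_changes_only_at_target(self, rE, rI):
        p = ModelParameters()
        drift = plasticity_drift(rE, rI, p)
        assert np.sign(drift) == np.sign(rE - p.rho)


class TestSteadyStateGating:
    def test_silent_input_gives_zero(self):
        assert steady_state_gating(0.072, 0.0066, 7.46, 0.0) == 0.0

    def test_saturates_below_one(self):
        assert steady_state_gating(0.072, 0.0066, 7.46, 1e9) == pytest.approx(1.0, abs=1e-4)
        assert steady_state_gating(0.072, 0.0066, 7.46, 1e9) < 1.0

    def test_gaba_worked_value(self):
        assert steady_state_gating(0.53, 0.18, 1.82, 9.0) == pytest.approx(0.046, abs=5e-4)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError):
            steady_state_gating(0.072, 0.0, 7.46, 3.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(min_value=0.0, max_value=299.0),
           st.floats(min_value=0.1, max_value=14.0))
    def test_monotone_in_rate_and_concentration(self, r, T):
        lo = steady_state_gating(0.53, 0.18, T, r)
        assert steady_state_gating(0.53, 0.18, T, r + 1.0) >= lo
        assert steady_state_gating(0.53, 0.18, T + 1.0, r) >= lo
        assert 0.0 <= lo < 1.0


class TestDestexheOracle:
    def test_silent_synapse(self):
        cfg = SynapseOracleConfig(rate=0.0, Tmax=7.46, alpha=0.072, beta=0.0066)
        assert destexhe_oracle(cfg).mean_gating == 0.0

    def test_nmda_matches_analytic_steady_state(self):
        cfg = SynapseOracleConfig(rate=3.0, Tmax=7.46, alpha=0.072, beta=0.0066,
                                  duration=120_000.0, seed=4)
        res = destexhe_oracle(cfg)
        assert res.converged
        expected = steady_state_gating(0.072, 0.0066, 7.46, 3.0)
        assert res.mean_gating == pytest.approx(expected, abs=0.03)

    def test_gaba_fast_kinetics_close_at_moderate_rate(self):
        cfg = SynapseOracleConfig(rate=60.0, Tmax=1.82, alpha=0.53, beta=0.18,
                                  duration=60_000.0, seed=5)
        res = destexhe_oracle(cfg)
        expected = steady_state_gating(0.53, 0.18, 1.82, 60.0)
        assert res.mean_gating == pytest.approx(expected, abs=0.01)

    def test_short_duration_flagged(self):
        cfg = SynapseOracleConfig(rate=10.0, Tmax=7.46, alpha=0.072, beta=0.0066,
                                  duration=500.0, seed=1)
        with pytest.warns(RuntimeWarning, match="too short"):
            res = destexhe_oracle(cfg)
        assert not res.converged

    def test_rate_outside_supported_range_rejected(self):
        with pytest.raises(ValueError):
            SynapseOracleConfig(rate=400.0, Tmax=1.0, alpha=0.5, beta=0.1)
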