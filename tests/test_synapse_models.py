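"""Synapse models: Ohmic coupling, graded activation/kinetics, chemical
transmitter-pulse kinetics, and unit discipline (µS x mV -> nA)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridclamp.synapse_models import (
    ChemicalSynapse,
    ChemicalSynapseParams,
    ChemicalSynapseState,
    ElectricalSynapseParams,
    GradedSynapse,
    GradedSynapseParams,
    chemical_step,
    electrical_current,
    graded_activation,
    graded_current,
    graded_slow_step,
    synapse_from_preset,
)

volts = st.floats(min_value=-120.0, max_value=60.0)


class TestElectrical:
    def test_ohmic_arithmetic(self):
        p = ElectricalSynapseParams(g=0.2)
        assert electrical_current(p, -40.0, -60.0) == pytest.approx(4.0)  # nA

    def test_equal_voltages_give_zero(self):
        assert electrical_current(ElectricalSynapseParams(0.5), -50.0, -50.0) == 0.0

    def test_zero_conductance_gives_zero(self):
        for v1, v2 in [(-80.0, 30.0), (10.0, -90.0)]:
            assert electrical_current(ElectricalSynapseParams(0.0), v1, v2) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(v1=volts, v2=volts, g=st.floats(min_value=0.0, max_value=5.0))
    def test_antisymmetry_exact(self, v1, v2, g):
        p = ElectricalSynapseParams(g=g)
        assert electrical_current(p, v1, v2) == -electrical_current(p, v2, v1)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ElectricalSynapseParams(g=-0.1)


class TestGradedActivation:
    RANGE = (-62.0, -30.0)

    def test_half_activation_at_absolute_threshold(self):
        p = GradedSynapseParams(v_threshold_pct=0.15, slope_pct=0.01)
        v_th = -62.0 + 0.15 * 32.0
        assert graded_activation(p, v_th, self.RANGE) == pytest.approx(0.5)

    def test_fast_synapse_convention_half_at_midrange(self):
        # fast synapses sit at 50% threshold / 5% slope of the range
        p = GradedSynapseParams(v_threshold_pct=0.5, slope_pct=0.05)
        v_mid = -46.0
        assert graded_activation(p, v_mid, self.RANGE) == pytest.approx(0.5)
        s_abs = 0.05 * 32.0
        a = graded_activation(p, v_mid + s_abs, self.RANGE)
        assert a == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), rel=1e-12)

    def test_far_below_threshold_is_negligible(self):
        p = GradedSynapseParams(v_threshold_pct=0.5, slope_pct=0.05)
        v = -46.0 - 10 * (0.05 * 32.0)  # ten slopes below threshold
        assert graded_activation(p, v, self.RANGE) < 1e-4
        assert graded_activation(p, v, self.RANGE) == pytest.approx(
            1.0 / (1.0 + math.exp(10.0)), rel=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(v=volts, dv=st.floats(min_value=0.0, max_value=50.0))
    def test_monotone_non_decreasing(self, v, dv):
        p = GradedSynapseParams(v_threshold_pct=0.15, slope_pct=0.01)
        assert (graded_activation(p, v + dv, self.RANGE)
                >= graded_activation(p, v, self.RANGE))

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            graded_activation(GradedSynapseParams(), -50.0, (-40.0, -40.0))


class TestGradedKinetics:
    RANGE = (-62.0, -30.0)

    def test_equilibrium_matches_fixed_point_formula(self):
        """Pinned full activation with k1=14, k2=4 converges to
        14/18 = 0.7778 (fixed-point oracle)."""
        p = GradedSynapseParams(k1=14.0, k2=4.0, mode="slow")
        m = 0.0
        for _ in range(2000):
            m = graded_slow_step(p, m, 100.0, self.RANGE, dt=1e-3)
        assert m == pytest.approx(14.0 / 18.0, abs=1e-9)

    def test_hundred_random_rate_triples_converge_to_closed_form(self):
        rng = np.random.default_rng(42)
        cases = [(14.0, 4.0, 1.0)] + [
            (rng.uniform(0.5, 30.0), rng.uniform(0.5, 30.0), rng.uniform(0.0, 1.0))
            for _ in range(99)
        ]
        for k1, k2, a in cases:
            # pin the activation by driving far above/below threshold
            p = GradedSynapseParams(k1=k1, k2=k2, mode="slow",
                                    v_threshold_pct=0.5, slope_pct=0.01)
            v_th = -62.0 + 0.5 * 32.0
            s_abs = 0.01 * 32.0
            v_pre = v_th - s_abs * math.log(1.0 / a - 1.0) if 0 < a < 1 else (
                100.0 if a >= 1 else -200.0)
            a_actual = graded_activation(p, v_pre, self.RANGE)
            m = 0.5
            for _ in range(4000):
                m = graded_slow_step(p, m, v_pre, self.RANGE, dt=2e-3)
            expected = k1 * a_actual / (k1 * a_actual + k2)
            assert abs(m - expected) < 1e-6

    def test_zero_activation_decays_monotonically(self):
        p = GradedSynapseParams(k1=14.0, k2=4.0, mode="slow")
        m, prev = 0.9, 0.9
        for _ in range(200):
            m = graded_slow_step(p, m, -200.0, self.RANGE, dt=1e-3)
            assert 0.0 <= m <= prev
            prev = m

    def test_equilibrium_persists_within_1e9_per_step(self):
        p = GradedSynapseParams(k1=14.0, k2=4.0, mode="slow")
        a = graded_activation(p, -40.0, self.RANGE)
        m_star = 14.0 * a / (14.0 * a + 4.0)
        m = graded_slow_step(p, m_star, -40.0, self.RANGE, dt=1e-4)
        assert abs(m - m_star) < 1e-9

    def test_gate_bounded_over_1e6_random_steps(self):
        rng = np.random.default_rng(7)
        p = GradedSynapseParams(k1=14.0, k2=4.0, mode="slow")
        m = 0.0
        vs = rng.uniform(-120.0, 40.0, 1_000_000)
        dts = rng.uniform(1e-5, 5e-2, 1_000_000)
        for v, dt in zip(vs, dts):
            m = graded_slow_step(p, m, v, self.RANGE, dt)
            assert 0.0 <= m <= 1.0

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            graded_slow_step(GradedSynapseParams(mode="slow"), 0.5, -40.0,
                             self.RANGE, dt=0.0)


class TestGradedCurrent:
    def test_zero_gate_gives_zero_current(self):
        p = GradedSynapseParams(g=0.8, E_syn=-62.0)
        assert graded_current(p, 0.0, -40.0) == 0.0

    def test_reversal_gives_zero_current(self):
        p = GradedSynapseParams(g=0.8, E_syn=-62.0)
        assert graded_current(p, 1.0, -62.0) == 0.0

    def test_unit_arithmetic_us_times_mv_is_na(self):
        # 0.8 uS fully open across a 10 mV driving force -> 8 nA
        p = GradedSynapseParams(g=0.8, E_syn=-50.0)
        assert graded_current(p, 1.0, -40.0) == pytest.approx(8.0)

    def test_inhibitory_sign_convention(self):
        """Positive current is withdrawn from the postsynaptic cell when
        it sits above the reversal potential."""
        p = GradedSynapseParams(g=0.5, E_syn=-70.0)
        assert graded_current(p, 0.8, -50.0) > 0.0

    def test_stateful_synapse_resolves_deferred_reversal(self):
        """A deferred reversal lands 30 mV below the postsynaptic minimum
        (below the slow-wave trough), so the synapse stays inhibitory over
        the whole postsynaptic cycle."""
        params = GradedSynapseParams(g=0.5, E_syn=None)
        syn = GradedSynapse(params, pre_range=(-62.0, -30.0), post_min=-65.0)
        assert syn.params.E_syn == -95.0
        assert syn.step(100.0, -95.0, 1e-4) == pytest.approx(0.0)
        assert syn.step(100.0, -65.0, 1e-4) > 0.0  # withdrawn at the trough


class TestChemical:
    def test_decay_matches_closed_form_without_spikes(self):
        p = ChemicalSynapseParams(beta=0.18)
        state = ChemicalSynapseState(s_open=0.7)
        t, dt = 0.0, 0.1
        for _ in range(100):
            state, _ = chemical_step(p, state, [], t, -60.0, dt)
            t += dt
        assert state.s_open == pytest.approx(0.7 * math.exp(-p.beta * t), rel=1e-9)

    def test_long_pulse_saturates_at_closed_form(self):
        p = ChemicalSynapseParams(alpha=0.94, beta=0.18, T_max=1.0,
                                  pulse_duration=1e9)
        state = ChemicalSynapseState(s_open=0.0)
        state, _ = chemical_step(p, state, [0.0], 0.0, -60.0, dt=500.0)
        s_inf = 0.94 / (0.94 + 0.18)
        assert state.s_open == pytest.approx(s_inf, abs=1e-6)

    def test_silent_synapse_carries_no_current(self):
        p = ChemicalSynapseParams()
        state = ChemicalSynapseState(s_open=0.0)
        t = 0.0
        for _ in range(50):
            state, current = chemical_step(p, state, [], t, -40.0, 0.5)
            assert current == 0.0
            t += 0.5

    def test_unsorted_spike_times_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            chemical_step(ChemicalSynapseParams(), ChemicalSynapseState(),
                          [3.0, 1.0], 0.0, -50.0, 0.1)

    def test_spike_detector_fires_once_per_crossing(self):
        syn = ChemicalSynapse(ChemicalSynapseParams(), spike_threshold=0.0,
                              refractory=2.0)
        v_pre = [-60, -60, 10, 20, 10, -60, -60, 15, -60]
        fired = []
        for i, v in enumerate(v_pre):
            syn.step(float(v), -60.0, float(i), 1.0)
            fired.append(syn.state.last_spike)
        assert fired[2] == 2.0  # first crossing
        assert fired[4] == 2.0  # held through the plateau
        assert fired[7] == 7.0  # next crossing after refractory


def test_validation_presets_ship_in_registry():
    slow = synapse_from_preset("slow_inhibitory_graded")
    assert (slow.k1, slow.k2, slow.mode) == (14.0, 4.0, "slow")
    assert (slow.g, slow.v_threshold_pct, slow.slope_pct) == (0.2, 0.15, 0.01)
    fast = synapse_from_preset("fast_inhibitory_graded")
    assert (fast.g, fast.v_threshold_pct, fast.slope_pct, fast.mode) == (
        0.8, 0.5, 0.05, "fast")
    assert synapse_from_preset("fast_inhibitory_graded_hr").g == 1.0
    assert synapse_from_preset("fast_inhibitory_graded_rulkov").g == 0.2
    assert synapse_from_preset("slow_inhibitory_graded_hr").g == 0.1
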