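import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopacircuit.channels import (
    ChannelSpec,
    ConfigurationError,
    DOPAMINE_SENSITIVE,
    DopamineModulationRule,
    GatingVariableSpec,
    InvalidStateError,
    apply_dopamine,
    channel_current,
    evaluate_gate,
    steady_state,
    time_constant,
)

GATE = GatingVariableSpec(
    name="m", exponent=3, v_half=-38.0, k=7.0,
    tau_min=0.5, tau_amp=4.0, tau_vhalf=-40.0, tau_s1=15.0, tau_s2=15.0,
)


class TestGateKinetics:
    def test_fixed_point_has_zero_derivative(self):
        V = -52.3
        x = steady_state(GATE, V)
        assert evaluate_gate(GATE, V, x) == pytest.approx(0.0, abs=1e-15)

    def test_first_order_identity_at_empty_gate(self):
        # steady state ~1 (very depolarized), x = 0 -> derivative = 1/tau
        V = 200.0
        tau = time_constant(GATE, V)
        assert evaluate_gate(GATE, V, 0.0) == pytest.approx(1.0 / tau, rel=1e-6)

    def test_clamped_voltage_relaxation_matches_closed_form(self):
        """Forward Euler at dt -> 0 reproduces x(t) = x_inf + (x0-x_inf)e^(-t/tau)."""
        V, x0, T = -45.0, 0.1, 20.0
        xinf, tau = steady_state(GATE, V), time_constant(GATE, V)
        dt = 1e-4
        x = x0
        for _ in range(int(T / dt)):
            x += dt * evaluate_gate(GATE, V, x)
        exact = xinf + (x0 - xinf) * math.exp(-T / tau)
        assert x == pytest.approx(exact, abs=1e-6)

    def test_invalid_states_rejected(self):
        with pytest.raises(InvalidStateError):
            evaluate_gate(GATE, float("nan"), 0.5)
        with pytest.raises(InvalidStateError):
            evaluate_gate(GATE, -60.0, 1.5)

    @given(V=st.floats(-100, 60))
    @settings(max_examples=200, deadline=None)
    def test_steady_state_bounded_and_tau_positive(self, V):
        assert 0.0 <= steady_state(GATE, V) <= 1.0
        assert time_constant(GATE, V) > 0.0

    def test_shipped_gates_bounded_on_physiological_range(self, full_net):
        Vgrid = np.linspace(-100, 60, 321)
        for neuron in full_net.neurons:
            for comp in neuron.compartments:
                for ch in comp.channels:
                    for g in ch.gates:
                        for V in Vgrid:
                            assert 0.0 <= steady_state(g, V) <= 1.0
                            assert time_constant(g, V) > 0.0


class TestChannelCurrent:
    CH = ChannelSpec(name="Na", g_max=2.0, E_rev=55.0, gates=(GATE,))

    def test_zero_driving_force(self):
        assert channel_current(self.CH, [0.7], 55.0) == 0.0

    def test_closed_gate(self):
        assert channel_current(self.CH, [0.0], -20.0) == 0.0

    def test_unit_scaling(self):
        ch = ChannelSpec(name="k", g_max=1.0, E_rev=0.0, gates=())
        assert channel_current(ch, [], 10.0) == pytest.approx(10.0)

    @given(g=st.floats(0.01, 10.0), dv=st.floats(-100, 100), x=st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_linear_in_gmax_and_driving_force(self, g, dv, x):
        ch = ChannelSpec(name="c", g_max=g, E_rev=0.0, gates=(GATE,))
        base = channel_current(ch, [x], dv)
        ch2 = ChannelSpec(name="c", g_max=2 * g, E_rev=0.0, gates=(GATE,))
        assert channel_current(ch2, [x], dv) == pytest.approx(2 * base, rel=1e-12)
        assert channel_current(ch, [x], 2 * dv) == pytest.approx(2 * base, rel=1e-12)

    def test_gate_count_mismatch(self):
        with pytest.raises(ConfigurationError):
            channel_current(self.CH, [0.5, 0.5], -30.0)


class TestDopamineModulation:
    def test_leak_unchanged_at_any_dopamine(self):
        leak = ChannelSpec(name="leak", g_max=0.01, E_rev=-65.0)
        rule = DopamineModulationRule(channel="leak", slope=0.5)
        # a leak is never dopamine sensitive, so even a matching rule is a no-op
        assert apply_dopamine(rule, leak, 0.0) is leak
        assert apply_dopamine(rule, leak, 1.0) is leak

    def test_sensitive_channel_differs_across_extremes(self):
        kas = ChannelSpec(name="KAs", g_max=0.1, E_rev=-90.0,
                          dopamine_sensitive=True, mod_slope=0.35)
        rule = DopamineModulationRule(channel="KAs", slope=0.35)
        lo = apply_dopamine(rule, kas, 0.0)
        hi = apply_dopamine(rule, kas, 1.0)
        assert lo.g_max != hi.g_max
        assert hi.g_max > kas.g_max > lo.g_max  # positive slope boosts with DA

    def test_idempotent_at_fixed_dopamine(self):
        kas = ChannelSpec(name="KAs", g_max=0.1, E_rev=-90.0,
                          dopamine_sensitive=True, mod_slope=0.35)
        rule = DopamineModulationRule(channel="KAs", slope=0.35)
        once = apply_dopamine(rule, kas, 0.8)
        twice = apply_dopamine(rule, once, 0.8)
        assert twice.g_max == pytest.approx(once.g_max, rel=1e-15)

    def test_transform_continuous_in_dopamine(self):
        rule = DopamineModulationRule(channel="x", slope=0.5)
        das = np.linspace(0, 1, 101)
        factors = [rule.factor(d) for d in das]
        assert np.all(np.abs(np.diff(factors)) < 0.01)

    def test_domain_error(self):
        rule = DopamineModulationRule(channel="x", slope=0.5)
        with pytest.raises(ValueError):
            rule.factor(1.5)

    def test_sensitive_set_is_exactly_the_named_families(self, full_net):
        """Ca/Can/KS/NaP on pyramidal compartments, KAs/CaL1.2 on the MSN,
        and nothing else, is dopamine sensitive."""
        for neuron in full_net.neurons:
            expected = DOPAMINE_SENSITIVE[neuron.type]
            for comp in neuron.compartments:
                for ch in comp.channels:
                    assert ch.dopamine_sensitive == (ch.name in expected)
                    if not ch.dopamine_sensitive:
                        assert ch.mod_slope == 0.0
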