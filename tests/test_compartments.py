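import numpy as np
import pytest

from dopacircuit.channels import ChannelSpec, ConfigurationError
from dopacircuit.compartments import (
    Compartment,
    NeuronModel,
    TopologyError,
    coupling_current,
    membrane_derivative,
)
from dopacircuit.fixtures import passive_cell
from dopacircuit.simulate import integrate


def _comp(cid, V, neighbors=None):
    return Compartment(id=cid, C_m=0.05,
                       channels=[ChannelSpec(name="leak", g_max=0.01, E_rev=-65.0)],
                       neighbors=neighbors or {}, V=V)


class TestCoupling:
    def test_isopotential_zero(self):
        a = _comp("a", -60.0, {"b": 1.0})
        b = _comp("b", -60.0, {"a": 1.0})
        assert coupling_current(a, b, 1.0) == 0.0

    def test_antisymmetry(self):
        a = _comp("a", -55.0, {"b": 1.0})
        b = _comp("b", -60.0, {"a": 1.0})
        assert coupling_current(a, b, 1.0) == pytest.approx(5.0)
        assert coupling_current(b, a, 1.0) == pytest.approx(-5.0)

    def test_non_neighbors_rejected(self):
        a = _comp("a", -55.0)
        b = _comp("b", -60.0)
        with pytest.raises(TopologyError):
            coupling_current(a, b, 1.0)

    def test_conservation_over_random_network_state(self, compiled_full, rng):
        """Physical coupling currents over both ends of every edge sum to zero."""
        cn = compiled_full
        V = rng.uniform(-80, -40, cn.n_eq)
        total = 0.0
        for e in range(cn.ed_g.size):
            a, b = cn.ed_a[e], cn.ed_b[e]
            into_a = cn.ed_count[e] * cn.ed_g[e] * (V[b] - V[a])
            into_b = cn.ed_count[e] * cn.ed_g[e] * (V[a] - V[b])
            assert into_a + into_b == pytest.approx(0.0, abs=1e-12)
            total += into_a + into_b
        assert total == pytest.approx(0.0, abs=1e-9)


class TestMembraneDerivative:
    def test_equilibrium(self):
        assert membrane_derivative(0.05, 0.0, 0.0, 0.0, 0.0) == 0.0

    def test_inverse_capacitance_scaling(self):
        d1 = membrane_derivative(0.05, 0.1, 0.02, 0.3, -0.05)
        d2 = membrane_derivative(0.10, 0.1, 0.02, 0.3, -0.05)
        assert d2 == pytest.approx(d1 / 2)

    def test_four_current_balance_sign_convention(self):
        # C dV/dt + I_ions + I_comp + I_syn = I_stim with outward-positive sums
        C, i_ion, i_syn_out, i_comp_out, i_stim = 0.05, 0.4, 0.1, -0.2, 0.3
        dvdt = membrane_derivative(C, i_ion, -i_syn_out, i_stim, -i_comp_out)
        assert C * dvdt + i_ion + i_comp_out + i_syn_out == pytest.approx(i_stim)


class TestNeuronModel:
    def test_compartment_count_invariants(self, full_net):
        expected = {"MSN": 11, "Pyra": 3, "PV": 1, "CB": 1}
        for neuron in full_net.neurons:
            assert neuron.n_logical_compartments == expected[neuron.type]

    def test_msn_dendrites_share_one_equation(self, full_net):
        msn = full_net.neuron("MSN")
        assert msn.n_logical_compartments == 11
        assert msn.n_membrane_equations == 2
        dend = next(c for c in msn.compartments if c.id != msn.soma_id)
        assert dend.multiplicity == 10

    def test_asymmetric_coupling_rejected(self):
        a = _comp("a", -65.0, {"b": 0.1})
        b = _comp("b", -65.0)  # does not list a back
        with pytest.raises(TopologyError):
            NeuronModel(name="n", type="Pyra", region="mPFC",
                        compartments=[a, b, _comp("c", -65.0)], soma_id="a")

    def test_nonpositive_capacitance_rejected(self):
        with pytest.raises(ConfigurationError):
            Compartment(id="x", C_m=0.0)


class TestPassiveOracle:
    def test_rc_relaxation_matches_closed_form(self):
        """A leak-only compartment under constant current is an RC circuit."""
        g, E, C, I, V0 = 0.01, -65.0, 0.05, 0.2, -65.0
        net = passive_cell(g_leak=g, E_leak=E, C_m=C, stim=I, V0=V0)
        tr = integrate(net, duration=50.0, v_jitter=0.0)
        tau = C / g
        vinf = E + I / g
        exact = vinf + (V0 - vinf) * np.exp(-tr.t / tau)
        err = np.max(np.abs(tr.V[:, 0] - exact) / np.abs(exact))
        assert err < 1e-3  # < 0.1 %

    def test_steady_state_is_ohmic(self):
        net = passive_cell(g_leak=0.01, E_leak=-65.0, stim=0.2)
        tr = integrate(net, duration=100.0, v_jitter=0.0)
        assert tr.V[-1, 0] == pytest.approx(-65.0 + 0.2 / 0.01, rel=1e-4)


class TestRestingStability:
    @pytest.mark.parametrize("ntype", ["MSN", "Pyra", "PV", "CB"])
    def test_silenced_neuron_settles_without_spikes(self, ntype):
        """With synapses absent and the stimulus off, each neuron type relaxes
        to a stable subthreshold rest."""
        from dopacircuit.fixtures import isolated_neuron
        from dopacircuit.metrics import detect_spikes

        net = isolated_neuron(ntype, stim=0.0)
        tr = integrate(net, duration=500.0, v_jitter=0.0)
        v = tr.soma_V(0)
        assert detect_spikes(v, tr.t).count == 0
        assert -90.0 < v[-1] < -40.0
        # settled: drift over the last 100 ms is tiny
        assert abs(v[-1] - v[-2000]) < 0.5
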