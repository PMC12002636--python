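import numpy as np
import pytest

from dopacircuit.energy import (
    EnergyReport,
    aggregate_energy,
    component_power,
    energy_table,
    integrate_energy,
    neuron_energy_report,
    split_synaptic_energy,
)
from dopacircuit.fixtures import passive_cell, single_synapse_pair
from dopacircuit.simulate import integrate


class TestIntegrateEnergy:
    def test_zero_power(self):
        t = np.arange(0, 100, 0.05)
        assert integrate_energy(np.zeros_like(t), t) == 0.0

    def test_microwatt_second_unit_identity(self):
        """1 uW (1e6 pW) held for 3,000 ms integrates to exactly 3,000 nJ."""
        t = np.arange(0, 3000.0 + 0.05, 0.05)
        nJ = integrate_energy(np.full(t.size, 1e6), t)
        assert nJ == pytest.approx(3000.0, rel=1e-12)

    def test_additive_over_disjoint_windows(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 200.0 + 0.05, 0.05)
        p = rng.normal(size=t.size)
        whole = integrate_energy(p, t, (0, 200.0))
        halves = integrate_energy(p, t, (0, 100.0)) + integrate_energy(p, t, (100.0, 200.0))
        assert whole == pytest.approx(halves, abs=1e-12)

    def test_empty_window_is_zero(self):
        t = np.arange(0, 10, 0.05)
        assert integrate_energy(np.ones_like(t), t, (4.0, 4.0)) == 0.0


class TestOhmicOracle:
    def test_constant_current_through_clamped_potential(self):
        """At steady state the stimulus power is I*V and its integral I*V*T."""
        g, E, I = 0.01, -65.0, 0.2
        net = passive_cell(g_leak=g, E_leak=E, stim=I)
        tr = integrate(net, duration=600.0, v_jitter=0.0)
        vinf = E + I / g
        window = (400.0, 600.0)
        e_stim = integrate_energy(tr.h_stim[:, 0], tr.t, window)
        assert e_stim == pytest.approx(I * vinf * 200.0 * 1e-6, rel=1e-3)

    def test_dead_circuit_has_zero_power(self):
        net = passive_cell(g_leak=0.01, E_leak=-65.0, stim=0.0, V0=-65.0)
        tr = integrate(net, duration=50.0, v_jitter=0.0)
        for series in (tr.h_stim, tr.h_comp, tr.h_syn, tr.h_all):
            assert np.max(np.abs(series)) < 1e-9


class TestPowerIdentity:
    def test_component_sum_equals_circuit_power_everywhere(self, short_trace):
        """The four-component combination and the capacitor+dissipation route
        agree to 1e-9 of the peak power on a full-circuit trace."""
        total = short_trace.h_all
        direct = short_trace.h_all_direct
        scale = np.max(np.abs(direct))
        assert np.max(np.abs(total - direct)) < 1e-9 * scale

    def test_component_power_returns_consistent_series(self, short_trace):
        for i in range(short_trace.n_neurons):
            pdc = component_power(short_trace, i)
            recon = (pdc.h_stimuli + pdc.h_compartments + pdc.h_synapses
                     + pdc.h_ions)
            assert np.allclose(recon, pdc.h_all)
            assert np.allclose(pdc.h_epsc + pdc.h_ipsc, pdc.h_synapses,
                               atol=1e-12)

    def test_ionic_power_is_dissipative_in_aggregate(self, short_trace):
        """Integrated battery power (consumption-positive) is non-negative
        for every neuron: channels dissipate."""
        for i in range(short_trace.n_neurons):
            e_ion = integrate_energy(short_trace.h_ion[:, i], short_trace.t)
            assert e_ion >= 0.0


class TestSynapticSplit:
    def test_partition_sums_to_synaptic_energy(self, short_trace):
        for i in range(short_trace.n_neurons):
            e, ip = split_synaptic_energy(short_trace, i)
            rep = neuron_energy_report(short_trace, i)
            assert e + ip == pytest.approx(rep.synaptic, abs=1e-9)

    def test_no_inhibitory_afferents_means_zero_ipsc_energy(self):
        net = single_synapse_pair("AMPA", g_syn=0.005, pre_stim=0.5)
        tr = integrate(net, duration=200.0)
        _, ipsc = split_synaptic_energy(tr, "post")
        epsc, _ = split_synaptic_energy(tr, "post")
        assert ipsc == 0.0
        assert epsc != 0.0


class TestAggregation:
    def test_network_equals_sum_of_regions(self, short_trace):
        table = energy_table(short_trace)
        nac = table[(table.scope_kind == "region") & (table.region == "NAc")]
        mpfc = table[(table.scope_kind == "region") & (table.region == "mPFC")]
        net_row = table[table.scope_kind == "network"]
        assert net_row.actual_nJ.iloc[0] == pytest.approx(
            nac.actual_nJ.iloc[0] + mpfc.actual_nJ.iloc[0], abs=1e-9
        )
        assert net_row.spikes.iloc[0] == nac.spikes.iloc[0] + mpfc.spikes.iloc[0]

    def test_single_member_aggregate_is_identity(self, short_trace):
        rep = neuron_energy_report(short_trace, "MSN")
        agg = aggregate_energy([rep], scope="solo")
        for field in ("actual", "ionic", "synaptic", "epsc", "ipsc", "spikes"):
            assert getattr(agg, field) == getattr(rep, field)

    def test_mixed_replicates_rejected(self, short_trace):
        a = neuron_energy_report(short_trace, 0)
        b = neuron_energy_report(short_trace, 1)
        b.replicate = 99
        with pytest.raises(ValueError):
            aggregate_energy([a, b], scope="bad")

    def test_report_internal_consistency(self, short_trace):
        rep = neuron_energy_report(short_trace, "Pyra_01")
        assert rep.actual == pytest.approx(rep.external + rep.ionic, abs=1e-9)

    def test_energy_per_spike_missing_when_silent(self):
        rep = EnergyReport(scope="x", level="Low", replicate=0, window=(0, 1),
                           actual=1.0, ionic=1.0, stimulus=0.0, compartment=0.0,
                           synaptic=0.0, epsc=0.0, ipsc=0.0, spikes=0)
        assert np.isnan(rep.energy_per_spike)
        rep4 = EnergyReport(scope="x", level="Low", replicate=0, window=(0, 1),
                            actual=1.0, ionic=1.0, stimulus=0.0, compartment=0.0,
                            synaptic=0.0, epsc=0.0, ipsc=0.0, spikes=4)
        assert rep4.energy_per_spike == pytest.approx(0.25)
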