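"""Simulate one isolated fast-spiking PV interneuron and account for its energy.

Builds a point neuron from the shipped parameter set, drives it with a
constant 0.3 nA somatic current for one second, and prints its firing rate,
the four energy components and the actual (net) energy.  The actual energy
equals the sum of the external components and the ionic consumption; a
negative component denotes energy supplied to the circuit rather than
consumed.
"""

from dopacircuit.energy import neuron_energy_report
from dopacircuit.fixtures import isolated_neuron
from dopacircuit.metrics import detect_spikes, firing_rate
from dopacircuit.simulate import integrate

net = isolated_neuron("PV", stim=0.3)
trace = integrate(net, duration=1000.0, v_jitter=0.0)

train = detect_spikes(trace.soma_V(0), trace.t)
report = neuron_energy_report(trace, 0)

print(f"firing rate          : {firing_rate(train, trace.duration):6.1f} Hz")
print(f"ionic energy         : {report.ionic:8.4f} nJ  (battery consumption)")
print(f"stimulus component   : {report.stimulus:8.4f} nJ")
print(f"synaptic component   : {report.synaptic:8.4f} nJ  (no synapses here)")
print(f"compartment component: {report.compartment:8.4f} nJ  (point neuron)")
print(f"actual energy        : {report.actual:8.4f} nJ")
print(f"energy per spike     : {report.energy_per_spike:8.5f} nJ/spike")
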