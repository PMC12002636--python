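"""Compare whole-network energy under Low vs Full dopamine input.

Assembles the 28-neuron NAc-mPFC microcircuit (69 membrane equations,
1,527 state variables), runs one 1,000 ms replicate per condition, and
prints the regional and network actual energies.  Low dopamine models the
depressive-like state; Full models the normal control.  Expect the mPFC
(and hence network) energy to collapse under Low dopamine while the NAc
barely moves.
"""

from dopacircuit import build_network
from dopacircuit.energy import energy_table
from dopacircuit.simulate import integrate

for level in ("Low", "Full"):
    net = build_network(level, seed=1)
    trace = integrate(net, duration=1000.0, replicate=0)
    table = energy_table(trace)
    rows = table[table.scope_kind.isin(["region", "network"])]
    print(f"--- {level} dopamine ({net.n_neurons} neurons, "
          f"{net.n_membrane_equations} membrane equations)")
    for _, row in rows.iterrows():
        print(f"  {row.scope:8s} actual {row.actual_nJ:8.3f} nJ | "
              f"ionic {row.ionic_nJ:8.3f} nJ | spikes {int(row.spikes):5d}")
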