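# dopacircuit

Energy coding in a dopaminergic NAc–mPFC microcircuit.

Major depressive disorder is associated with reduced dopamine signalling
along the VTA→NAc→mPFC reward pathway and with abnormal brain energy
metabolism, but the link between the two is hard to probe experimentally.
`dopacircuit` approaches the question computationally: it simulates a
28-neuron conductance-based microcircuit of the pathway — one D2-type
medium spiny neuron (MSN), one PV and one CB interneuron in the nucleus
accumbens; twenty D1-type pyramidal (Pyra) neurons, three PV and two CB
interneurons in the medial prefrontal cortex — under a stochastic global
dopamine input, and accounts for every picowatt the equivalent electrical
circuit consumes or supplies.  The Low dopamine regime (uniform in
[0, 0.25)) models the depressive-like state; Full ([0.75, 1]) models the
control.  The package is aimed at computational neuroscientists studying
metabolic correlates of neural coding.

## The model in brief

Each compartment obeys a Hodgkin–Huxley current balance

```
C_m dV_m/dt + Σ I_Ions + Σ I_Compartments + Σ I_Synapses = I_Stimuli
```

with first-order gate kinetics `dx/dt = (x_∞(V) − x)/τ_x(V)`, ohmic
dendritic coupling, and AMPA / NMDA (Mg²⁺-blocked) / GABA_a synapses.
Dopamine scales six conductances (Ca, Can, KS, NaP on pyramidal
compartments; KAs, CaL1.2 on the MSN), implementing D1 facilitation in
cortex and D2 suppression in striatum.  The assembled circuit integrates
**69 membrane equations** and **1,527 state variables** (the MSN's ten
identical dendrites share one representative equation).

The instantaneous neural power of each neuron decomposes as

```
H_All = H_Stimuli + Σ H_Compartments + Σ H_Synapses + H_Ions
```

(`H_Ions = −Σ I_i E_i`, consumption-positive; positive power = consumption,
negative = supply), and identically equals the capacitor-plus-dissipation
power of the circuit — an identity asserted at every recorded instant.
Time integrals give the *actual energy* (nJ), its *ionic* and *external*
parts, the EPSC/IPSC split, energy per spike, and the **P–V correlation**
(Pearson r between somatic potential and actual power), computed per
neuron, type, region and network over a 4-level × 9-replicate design and
compared with an assumption-guided ANOVA / Welch / Kruskal–Wallis pipeline.

All channel, synapse, connectivity and stimulus parameters ship as a
**synthetic parameter set** (`src/dopacircuit/params/synthetic_*.yaml`)
constructed and calibrated for this package; absolute energies are
properties of that set, while directions and significance patterns are the
scientific claims (see `docs/methods.md`).

## Worked example

`examples/02_microcircuit_low_vs_full.py` builds the circuit and runs one
1,000 ms replicate per condition:

```
--- Low dopamine (28 neurons, 69 membrane equations)
  NAc      actual    0.422 nJ | ionic    0.569 nJ | spikes   108
  mPFC     actual    1.115 nJ | ionic    1.578 nJ | spikes   168
  network  actual    1.537 nJ | ionic    2.146 nJ | spikes   276
--- Full dopamine (28 neurons, 69 membrane equations)
  NAc      actual    0.356 nJ | ionic    0.514 nJ | spikes   109
  mPFC     actual    3.525 nJ | ionic    4.061 nJ | spikes   774
  network  actual    3.881 nJ | ionic    4.575 nJ | spikes   883
```

Low dopamine collapses mPFC firing and energy consumption (1.115 vs
3.525 nJ) while the NAc barely moves — the depressive-like state is a
low-energy cortical state, driven by the dopamine-sensitive pyramidal
conductances.  `examples/03_pv_correlation.py` prints the per-type P–V
correlations for one replicate:

```
CB    (NAc ): P-V r = 0.741 (mean over 1 neuron, rate   6.0 Hz)
MSN   (NAc ): P-V r = 0.617 (mean over 1 neuron, rate   5.0 Hz)
PV    (mPFC): P-V r = 0.735 (mean over 3 neurons, rate  80.7 Hz)
Pyra  (mPFC): P-V r = 0.735 (mean over 20 neurons, rate  26.2 Hz)
```

Correlations well below 1 mean the energy code carries information the
potential code does not.  The other examples cover a single neuron's
energy budget and the statistics pipeline.

A thin CLI mirrors the library:
`dopacircuit simulate --level low --replicates 9 --seed 42 --out runs/`,
then `dopacircuit energy --runs runs/ --out energy.tsv`,
`dopacircuit metrics --runs runs/ --out metrics.tsv`,
`dopacircuit stats --energy energy.tsv --metrics metrics.tsv --out stats/`.

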