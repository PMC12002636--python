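# Methods

## The model

`dopacircuit` simulates a 28-neuron conductance-based microcircuit spanning
the two dopaminoceptive stations of the mesocorticolimbic reward pathway:
the nucleus accumbens (NAc: one D2-type medium spiny neuron, one PV and one
CB interneuron) and the medial prefrontal cortex (mPFC: twenty D1-type
pyramidal neurons, three PV and two CB interneurons).  The ventral
tegmental area enters only as a *global dopamine concentration input* — a
normalized scalar DA(t) in [0, 1] — not as a cell population.

Every compartment obeys a Hodgkin–Huxley current balance

    C_m dV/dt + ΣI_ions + ΣI_compartments + ΣI_synapses = I_stimulus

with HH-style channels `I = g_max Π x_i^p_i (V − E)`, first-order gates
`dx/dt = (x_∞(V) − x)/τ_x(V)` (Boltzmann steady states, bell-shaped time
constants), ohmic compartment coupling `g_c (V_from − V_to)`, and
first-order transmitter-binding synapses (AMPA, NMDA with the standard
1 mM-Mg2+ block `B(V) = 1/(1 + e^{−0.062V}/3.57)`, and GABA_a), released as
a sigmoid function of the presynaptic somatic potential so the whole
network is one smooth ODE system.

Morphologies are reduced: the MSN is a soma plus ten *identical* dendrites,
the pyramidal neuron a soma plus proximal and distal dendrite, the
interneurons are points.  Because the MSN's dendrites are identical in both
parameters and inputs, their potentials coincide and a single
representative dendritic equation is integrated with multiplicity 10.  The
assembled system therefore has exactly **69 membrane equations** for the 28
neurons and, together with 260 channel gates and 1,198 synaptic gates,
**1,527 state variables**.

### Dopamine input and modulation

The dopamine input is piecewise constant: one uniform draw per recording
interval (0.05 ms) from the active level's range — Low [0, 0.25), Medium
[0.25, 0.5), High [0.5, 0.75), Full [0.75, 1] (midpoints 0.125 … 0.875).
Low models the depressive-like (MDD) condition, Full the normal control.
The redraw cadence is a modelling choice (the underlying process is only
specified as "uniform within the range at each moment"); it is configurable
and the results are insensitive to it in expectation.

Dopamine acts exclusively by scaling six channel conductances linearly,
`g_eff = g_max (1 + s·(DA − 0.5))`:

| channel | site | slope s | effect of DA |
|---|---|---|---|
| NaP | Pyra proximal | +0.3 | more persistent Na → more excitable |
| KS  | Pyra proximal | −0.3 | less slow K → more excitable |
| Ca  | Pyra soma     | +0.3 | costlier spikes |
| Can | Pyra distal   | +0.3 | costlier dendritic activity |
| KAs | MSN soma+dendrites | +0.35 | more slow A-type K → less excitable |
| CaL1.2 | MSN soma+dendrites | −0.35 | less L-type Ca → less excitable |

This implements D1-type facilitation in the cortex and D2-type suppression
in the striatum: pyramidal firing rises with DA, while for the MSN the
falling intrinsic excitability roughly offsets the rising cortical drive,
so its rate stays nearly level across conditions.

### The synthetic parameter set

All kinetics, conductances, the connectivity and the stimulus amplitudes
are a **synthetic parameter set constructed for this package** (the
`params/synthetic_*.yaml` files).  They were designed from the standard
conductance-based modelling literature (Traub-like Na/K spike machinery,
Destexhe-type synapse kinetics, an MSN with hyperpolarized rest and a
slowly-inactivating A-type K current, a fast-spiking PV cell, a CB cell
carrying an HCN-like H-current) and then calibrated — once, before the test
suite was frozen — so the circuit reproduces the qualitative physiology the
model targets: all types fire in both conditions, pyramidal rates increase
with dopamine, MSN rates do not, and the energy pattern described below
emerges.  Absolute energies in nJ are therefore properties of this
parameter set, not of any external reference; only directions, ratios and
significance patterns are meaningful claims.

Two deliberate sources of heterogeneity break the symmetry of the otherwise
identical same-type neurons: per-neuron stimulus amplitudes are jittered by
5 % (Gaussian, drawn deterministically from the build seed) and each
replicate displaces all initial potentials uniformly within ±2 mV.  Without
them, the twenty pyramidal cells would be mathematically identical and
would stay perfectly synchronized.

## Energy accounting

Treating the membrane as an equivalent electrical circuit, each neuron's
instantaneous power (pW = nA·mV) is decomposed into

* `H_Stimuli = I_stim·V` — power delivered by the stimulus source,
* `H_Compartments` — coupling power attributed to the *receiving*
  compartment (`I_in·V`), summed over the neuron's couplings,
* `H_Synapses = −I_syn·V` — synaptic power, split by receptor class into
  EPSC (AMPA+NMDA) and IPSC (GABA_a) parts,
* `H_Ions = −Σ I_i·E_i` — the power drawn from the ionic batteries, stored
  consumption-positive.

The *actual* power is their vector sum,
`H_All = H_Stimuli + H_Compartments + H_Synapses + H_Ions`, and circuit
algebra gives the independent identity
`H_All = C_m·V·dV/dt + Σ I_i (V − E_i)` (capacitor power plus resistive
dissipation).  Both routes are computed separately at every recorded
instant and asserted equal to 1e-9 relative — this is the master
consistency check tying channels, synapses, coupling and stimuli together,
alongside the per-equation current-balance residual.  Positive energy
denotes consumption, negative denotes supply.  Note the convention: with
`H_Ions` stored consumption-positive the combination rule carries a plus
sign; equivalently, with the battery sign convention (`H_Ions = Σ I_i E_i`)
it is a minus.

Energies are trapezoidal time integrals on the 0.05 ms recording grid,
reported in nJ (1 pW·ms = 1e-6 nJ).  Per-neuron energies include all
physical compartments (the MSN counts its soma and ten dendrites).  The
"external" energy is the sum of the stimulus, compartment and synaptic
components and always equals actual − ionic.

An important structural consequence of this bookkeeping: over a long
window the actual energy of a neuron is (up to a vanishing capacitor term)
exactly its ionic Joule heating `∫ Σ g_i (V − E_i)² dt`.  Spikes dominate
this integral, which is why energy-per-spike differences between
conditions require either different spike trajectories or substantial
subthreshold dissipation — the CB interneuron's H-current supplies the
latter in the inhibition-dominated Full condition.

## Spiking and coding metrics

Spikes are upward 0 mV crossings of the somatic potential with a 2 ms
refractory window (the criterion is configurable; HH spikes overshoot 0 mV
by tens of mV, so the detection is insensitive to the threshold over a wide
band).  Energy per spike divides the window's actual energy by the spike
count and is *missing* (never 0 or ∞) for a silent neuron.  The P–V
correlation is the plain Pearson coefficient between the somatic membrane
potential and the neuron's whole-cell actual power on the recording grid,
without smoothing; it is invariant under affine rescaling of either series.

## Simulation

Fixed-step classical RK4 with dt = 0.025 ms, recording every 0.05 ms,
default duration 3,000 ms with no discard window.  A fixed-step explicit
method was chosen so that a run is bit-reproducible from its seed (the
stochastic dopamine path precludes adaptive step control).  Gates and
synaptic states are clamped to [0, 1] after each step with a counter (the
counter stays at zero in all shipped configurations); |V| > 200 mV or a
non-finite state aborts with the failure time.  A self-convergence test
(halving dt) bounds the discretization error well below 0.5 mV on the full
circuit.  The right-hand side is compiled with numba; a pure-Python
evaluation built from the public gate/channel/synapse operations is kept as
an independent cross-check and the two are asserted to agree to 1e-10 on
random states.

Seeding: replicate r of level ℓ uses the generator
`default_rng([base_seed, level_index, r])`; it drives the initial-condition
jitter and then the dopamine path, so every run is reproducible in
isolation.

## Statistics

Nine replicates per dopamine level.  Within one replicate, same-type
neurons are first averaged (20 Pyra, 3 mPFC PV, 2 mPFC CB) so the
replicate, not the neuron, is the statistical unit.  The test-selection
protocol is: Shapiro–Wilk normality per group and Brown–Forsythe variance
homogeneity at α = 0.05; all-normal + homogeneous → one-way ANOVA with
Tukey; all-normal + heterogeneous → Welch ANOVA with Games–Howell;
otherwise Kruskal–Wallis with Bonferroni-adjusted Dunn.  All tests are
two-tailed, summaries are mean ± SEM, and no correction is applied across
metrics (only within post-hoc families).  Dunn's test is implemented in
the package (rank-sum z statistics with tie correction); the others come
from scipy and pingouin.  Null-calibration simulations confirm a type-I
error of ~5 % and >99 % power against a 3-SD shift at n = 9.  An optional
ordinary-least-squares regression of any metric on the level midpoints is
provided, with uncorrected p.

## Problem sizes used by the shipped checks

The acceptance test layer and `scripts/acceptance.py` both run the full
design — 4 levels × 9 replicates × 3,000 ms (36 runs, ~69 equations and
1,527 states each).  Unit and property tests use degenerate circuits
(single passive compartments, single synapses) and a 200 ms full-circuit
trace.  The statistics calibration uses 1,000 simulated null and 1,000
alternative datasets at n = 9.

## What the synthetic data can and cannot show

The generator emulates the *structure* of the study — stochastic
uniform-band dopamine, heterogeneous same-type neurons, the four-current
energy bookkeeping — but its parameters are not fitted to any recordings.
Passing tests therefore demonstrate internal correctness (oracle and
conservation checks), the structural counts, and that the implemented
dopamine mechanisms are *sufficient* to produce the qualitative
energy-coding pattern: higher mPFC/network energy and lower energy-per-
spike at high dopamine, a striatal MSN whose consumption moves opposite to
cortex, EPSC-driven growth of synaptic energy supply with dopamine, and
P–V correlations in the 0.6–0.9 band.  They do not validate the parameter
values against biology, and absolute nJ figures should not be compared
with measurements.

## Known limitations

* The MSN's per-spike energy difference between conditions is small
  relative to replicate noise; its direction holds at the full design size
  but it is not a significant contrast in this parameter set.
* In this parameter set the P–V correlations of the MSN and of the mPFC CB
  interneuron are slightly *higher* in the Low condition (the heavy
  synaptic bombardment and H-current dissipation of the Full condition
  decorrelate power from potential), and the MSN's Full-condition
  correlation sits at the lower edge of the 0.6–0.9 band.  The
  corresponding directional acceptance checks are expected to fail and are
  retained unmodified.
* Dopamine modulation is restricted to linear conductance scaling of six
  channels; kinetic (voltage-shift) modulation is representable in the
  parameter schema but not used.
* No synaptic delays, plasticity, or receptor desensitization; dopamine is
  never a synaptic transmitter here.
* Energies are sensitive to the stimulus convention (`I·V` counts the
  source's power at the node, which for hyperpolarized V is a supply);
  alternative conventions exist in the literature and would shift the
  external-component split, though not `H_All`.
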