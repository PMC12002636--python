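"""Neural energy accounting on the equivalent electrical circuit.

For every neuron the instantaneous power is decomposed into four
components, each the product of a current and the potential it works
against (pW = nA * mV):

* ``H_Stimuli``     = I_stim * V               (external source at the node)
* ``H_Compartments``= sum over coupling currents into each receiving
                      compartment times its potential
* ``H_Synapses``    = -I_syn * V_post, split into EPSC (AMPA/NMDA) and IPSC
                      (GABAa) classes
* ``H_Ions``        = -sum_i I_i * E_i, the power drawn from the ionic
                      batteries, stored consumption-positive

and the *actual* power of the circuit is their vector sum,

    H_All = H_Stimuli + H_Compartments + H_Synapses + H_Ions,

which identically equals the capacitor power plus the resistive dissipation
``C_m V dV/dt + sum_i I_i (V - E_i)`` -- the identity is computed through
both routes independently and asserted, never enforced by subtraction.
Positive power/energy denotes consumption, negative denotes supply.

Energies are trapezoidal time integrals of power and are reported in nJ
(1 pW * ms = 1e-6 nJ).  Per-neuron energies include all compartments (the
whole MSN counts its soma and ten dendrites; the whole pyramidal neuron its
three compartments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import detect_spikes, energy_per_spike
from .simulate import SimulationTrace

__all__ = [
    "PowerDecomposition",
    "EnergyReport",
    "component_power",
    "integrate_energy",
    "split_synaptic_energy",
    "neuron_energy_report",
    "aggregate_energy",
    "energy_table",
]

PW_MS_TO_NJ = 1e-6

#: relative tolerance of the dual-route power identity
IDENTITY_RTOL = 1e-9


class IncompleteTraceError(ValueError):
    pass


@dataclass
class PowerDecomposition:
    """Per-neuron instantaneous power components on the trace grid (pW)."""

    neuron: str
    t: np.ndarray
    h_stimuli: np.ndarray
    h_compartments: np.ndarray
    h_synapses: np.ndarray
    h_epsc: np.ndarray
    h_ipsc: np.ndarray
    h_ions: np.ndarray  # consumption-positive
    h_all: np.ndarray


def component_power(trace: SimulationTrace, neuron: str | int) -> PowerDecomposition:
    """Extract one neuron's power decomposition, asserting the dual-route
    identity between the component sum and the equivalent-circuit power."""
    for name in ("h_stim", "h_comp", "h_syn", "h_ion", "h_cap", "h_res"):
        if getattr(trace, name) is None:
            raise IncompleteTraceError(f"trace lacks power series {name!r}")
    i = neuron if isinstance(neuron, int) else trace.neuron_index(neuron)
    total = trace.h_stim[:, i] + trace.h_comp[:, i] + trace.h_syn[:, i] + trace.h_ion[:, i]
    direct = trace.h_cap[:, i] + trace.h_res[:, i]
    scale = max(1.0, float(np.max(np.abs(direct))) if direct.size else 1.0)
    err = float(np.max(np.abs(total - direct))) if direct.size else 0.0
    if err > IDENTITY_RTOL * scale:
        raise AssertionError(
            f"power identity violated for {trace.neuron_names[i]}: "
            f"max|components - circuit| = {err:g} pW"
        )
    return PowerDecomposition(
        neuron=trace.neuron_names[i],
        t=trace.t,
        h_stimuli=trace.h_stim[:, i],
        h_compartments=trace.h_comp[:, i],
        h_synapses=trace.h_syn[:, i],
        h_epsc=trace.h_epsc[:, i],
        h_ipsc=trace.h_ipsc[:, i],
        h_ions=trace.h_ion[:, i],
        h_all=total,
    )


def integrate_energy(power: np.ndarray, t: np.ndarray, window=None) -> float:
    """Trapezoidal integral of a power series (pW over ms) in nJ.

    Additive over disjoint windows; an empty window integrates to 0.
    """
    if window is not None:
        t0, t1 = window
        if t1 < t0:
            raise ValueError("window must have t0 <= t1")
        mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
        t = t[mask]
        power = power[mask]
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(power, t)) * PW_MS_TO_NJ


def split_synaptic_energy(trace: SimulationTrace, neuron: str | int, window=None):
    """(EPSC energy, IPSC energy) in nJ; their sum is the synaptic energy."""
    i = neuron if isinstance(neuron, int) else trace.neuron_index(neuron)
    e = integrate_energy(trace.h_epsc[:, i], trace.t, window)
    ip = integrate_energy(trace.h_ipsc[:, i], trace.t, window)
    return e, ip


@dataclass
class EnergyReport:
    """Scalar energy bookkeeping for one scope, replicate and window (nJ)."""

    scope: str  # neuron name, neuron type, region, or "network"
    level: str
    replicate: int
    window: tuple
    actual: float
    ionic: float
    stimulus: float
    compartment: float
    synaptic: float
    epsc: float
    ipsc: float
    spikes: int
    members: int = 1

    @property
    def external(self) -> float:
        """Combined effect of the three external currents (stimulus,
        compartment, synaptic); equals actual - ionic."""
        return self.stimulus + self.compartment + self.synaptic

    @property
    def energy_per_spike(self) -> float:
        """Actual energy per somatic action potential; NaN when no spikes
        occurred (excluded from statistics, never 0 or infinity)."""
        return energy_per_spike(self.actual, self.spikes)

    def _check(self) -> None:
        if abs(self.actual - (self.external + self.ionic)) > 1e-9:
            raise AssertionError("energy components do not sum to the actual energy")
        if abs(self.synaptic - (self.epsc + self.ipsc)) > 1e-9:
            raise AssertionError("EPSC + IPSC does not equal the synaptic energy")


def neuron_energy_report(
    trace: SimulationTrace,
    neuron: str | int,
    window=None,
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> EnergyReport:
    """Full energy report for one neuron over the window (default: whole run)."""
    i = neuron if isinstance(neuron, int) else trace.neuron_index(neuron)
    pd_ = component_power(trace, i)
    w = window
    stim = integrate_energy(pd_.h_stimuli, pd_.t, w)
    comp = integrate_energy(pd_.h_compartments, pd_.t, w)
    syn = integrate_energy(pd_.h_synapses, pd_.t, w)
    epsc, ipsc = split_synaptic_energy(trace, i, w)
    ionic = integrate_energy(pd_.h_ions, pd_.t, w)
    actual = integrate_energy(pd_.h_all, pd_.t, w)
    train = detect_spikes(trace.soma_V(i), trace.t, threshold, refractory)
    report = EnergyReport(
        scope=trace.neuron_names[i],
        level=trace.level,
        replicate=trace.replicate,
        window=(float(trace.t[0]), float(trace.t[-1])) if w is None else tuple(w),
        actual=actual,
        ionic=ionic,
        stimulus=stim,
        compartment=comp,
        synaptic=syn,
        epsc=epsc,
        ipsc=ipsc,
        spikes=len(train.times),
    )
    report._check()
    return report


def aggregate_energy(reports: list[EnergyReport], scope: str) -> EnergyReport:
    """Sum energies (and spike counts) over member reports.

    All members must share level, replicate and window.  A single-member
    aggregate equals the input report (re-labelled).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    first = reports[0]
    for r in reports[1:]:
        if r.level != first.level or r.replicate != first.replicate or r.window != first.window:
            raise ValueError("aggregation over mixed levels/replicates/windows")
    agg = EnergyReport(
        scope=scope,
        level=first.level,
        replicate=first.replicate,
        window=first.window,
        actual=sum(r.actual for r in reports),
        ionic=sum(r.ionic for r in reports),
        stimulus=sum(r.stimulus for r in reports),
        compartment=sum(r.compartment for r in reports),
        synaptic=sum(r.synaptic for r in reports),
        epsc=sum(r.epsc for r in reports),
        ipsc=sum(r.ipsc for r in reports),
        spikes=sum(r.spikes for r in reports),
        members=sum(r.members for r in reports),
    )
    agg._check()
    return agg


def energy_table(trace: SimulationTrace, window=None) -> pd.DataFrame:
    """One row per neuron plus per-type, per-region and network aggregates."""
    per_neuron = [
        neuron_energy_report(trace, i, window) for i in range(trace.n_neurons)
    ]
    rows = []

    def row(rep: EnergyReport, scope_kind: str, ntype="", region=""):
        rows.append(
            dict(
                scope=rep.scope,
                scope_kind=scope_kind,
                type=ntype,
                region=region,
                level=rep.level,
                replicate=rep.replicate,
                actual_nJ=rep.actual,
                ionic_nJ=rep.ionic,
                external_nJ=rep.external,
                stimulus_nJ=rep.stimulus,
                compartment_nJ=rep.compartment,
                synaptic_nJ=rep.synaptic,
                epsc_nJ=rep.epsc,
                ipsc_nJ=rep.ipsc,
                spikes=rep.spikes,
                energy_per_spike_nJ=rep.energy_per_spike,
                members=rep.members,
            )
        )

    types = trace.neuron_types
    regions = trace.neuron_regions
    for i, rep in enumerate(per_neuron):
        row(rep, "neuron", types[i], regions[i])
    for key in sorted({(t, r) for t, r in zip(types, regions)}):
        members = [per_neuron[i] for i in range(len(per_neuron))
                   if (types[i], regions[i]) == key]
        row(aggregate_energy(members, f"{key[0]}_{key[1]}"), "type", key[0], key[1])
    for region in sorted(set(regions)):
        members = [per_neuron[i] for i in range(len(per_neuron)) if regions[i] == region]
        row(aggregate_energy(members, region), "region", "", region)
    row(aggregate_energy(per_neuron, "network"), "network")
    return pd.DataFrame(rows)
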