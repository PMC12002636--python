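"""Degenerate network builders for testing and calibration.

These construct minimal :class:`~dopacircuit.network.NetworkModel` instances
-- a single passive compartment, one isolated neuron of any shipped type, or
a two-cell circuit with a single synapse -- that exercise every stage of the
pipeline against closed-form oracles (RC relaxation, first-order gate
kinetics, synaptic fixed points, Ohmic power) before the full 28-neuron
circuit is assembled.
"""

from __future__ import annotations

from .channels import ChannelSpec
from .compartments import Compartment, NeuronModel
from .network import LEVELS, NetworkModel, StimulusSpec, load_neuron_params, build_neuron
from .synapses import SynapseSpec

__all__ = [
    "passive_cell",
    "isolated_neuron",
    "single_synapse_pair",
    "two_compartment_passive",
]


def _wrap(neurons, synapses, stimuli, level="Full", seed=0) -> NetworkModel:
    lv = LEVELS[level] if isinstance(level, str) else level
    return NetworkModel(
        neurons=neurons,
        synapses=synapses,
        stimuli=stimuli,
        level=lv,
        modulation={},
        seed=seed,
    )


def passive_cell(
    g_leak: float = 0.01,
    E_leak: float = -65.0,
    C_m: float = 0.05,
    stim: float = 0.2,
    V0: float = -65.0,
    name: str = "cell",
) -> NetworkModel:
    """A single leak-only compartment under constant current: an RC circuit
    with closed-form response V(t) = V_inf + (V0 - V_inf) exp(-t/tau),
    V_inf = E_leak + I/g_leak, tau = C_m/g_leak."""
    comp = Compartment(
        id="soma",
        C_m=C_m,
        channels=[ChannelSpec(name="leak", g_max=g_leak, E_rev=E_leak)],
        V=V0,
    )
    neuron = NeuronModel(name=name, type="PV", region="NAc", compartments=[comp])
    return _wrap([neuron], [], {name: StimulusSpec(name, stim)})


def two_compartment_passive(
    g_c: float = 0.05,
    g_leak: float = 0.01,
    E_leak: float = -65.0,
    stim: float = 0.2,
) -> NetworkModel:
    """Two coupled passive compartments (stimulus into the 'soma');
    exercises the coupling current and its energy attribution."""
    soma = Compartment(
        id="soma", C_m=0.05,
        channels=[ChannelSpec(name="leak", g_max=g_leak, E_rev=E_leak)],
        neighbors={"dend": g_c},
    )
    dend = Compartment(
        id="dend", C_m=0.05,
        channels=[ChannelSpec(name="leak", g_max=g_leak, E_rev=E_leak)],
        neighbors={"soma": g_c},
    )
    neuron = NeuronModel(name="cell", type="Pyra", region="mPFC",
                         compartments=[soma, dend, _spacer(g_leak, E_leak)],
                         soma_id="soma")
    return _wrap([neuron], [], {"cell": StimulusSpec("cell", stim)})


def _spacer(g_leak: float, E_leak: float) -> Compartment:
    # third, uncoupled compartment so the 3-compartment Pyra invariant holds
    return Compartment(
        id="distal", C_m=0.05,
        channels=[ChannelSpec(name="leak", g_max=g_leak, E_rev=E_leak)],
    )


def isolated_neuron(
    neuron_type: str,
    stim: float,
    level: str = "Full",
    params_dir=None,
    modulation: dict | None = None,
    seed: int = 0,
) -> NetworkModel:
    """One neuron of a shipped type (MSN, Pyra, PV or CB) with no synaptic
    input, under constant somatic current."""
    region = "NAc" if neuron_type in ("MSN",) else "mPFC"
    doc = load_neuron_params(neuron_type, params_dir)
    neuron = build_neuron("cell", neuron_type, region, doc, modulation or {})
    net = _wrap([neuron], [], {"cell": StimulusSpec("cell", stim)}, level=level, seed=seed)
    net.modulation = {neuron_type: dict(modulation or {})}
    return net


def single_synapse_pair(
    receptor: str = "AMPA",
    g_syn: float = 0.005,
    pre_stim: float = 0.4,
    post_stim: float = 0.0,
    params_dir=None,
) -> NetworkModel:
    """Two PV point neurons connected by one synapse; the presynaptic cell
    is driven to fire, the postsynaptic cell is passive unless stimulated."""
    doc = load_neuron_params("PV", params_dir)
    pre = build_neuron("pre", "PV", "mPFC", doc, {})
    post = build_neuron("post", "PV", "mPFC", doc, {})
    syn = SynapseSpec(receptor=receptor, g_max=g_syn, pre="pre", post=("post", "soma"))
    return _wrap(
        [pre, post],
        [syn],
        {"pre": StimulusSpec("pre", pre_stim), "post": StimulusSpec("post", post_stim)},
    )
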