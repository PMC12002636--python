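"""Compartmental membrane models and inter-compartment coupling.

Four neuron classes are supported:

* ``MSN``  -- NAc medium spiny neuron (D2-type): one soma plus ten identical
  dendrites.  Because the dendrites are identical in parameters *and* receive
  identical inputs, their membrane potentials coincide; the model therefore
  integrates a single representative dendritic membrane equation carried with
  multiplicity 10.  The neuron exposes 11 logical compartments but
  contributes 2 membrane equations to the assembled system.
* ``Pyra`` -- mPFC pyramidal neuron (D1-type): soma, proximal dendrite,
  distal dendrite (3 equations).
* ``PV`` / ``CB`` -- parvalbumin / calbindin interneurons: point neurons
  (1 equation each).

The membrane equation of every compartment balances four current types:

    C_m dV/dt + sum(I_ions) + sum(I_compartments) + sum(I_synapses) = I_stim

Compartment (coupling) currents are ohmic, ``g_c * (V_from - V_to)`` into
the receiving compartment, and antisymmetric under exchange of endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .channels import ChannelSpec, ConfigurationError

__all__ = [
    "Compartment",
    "NeuronModel",
    "TopologyError",
    "coupling_current",
    "membrane_derivative",
]


class TopologyError(ValueError):
    """Raised for coupling between compartments that are not neighbors."""


@dataclass
class Compartment:
    """One isopotential membrane compartment.

    ``C_m`` in nF.  ``neighbors`` maps neighbor compartment id to the
    coupling conductance g_c in uS (one entry per physical neighbor class).
    ``multiplicity`` is the number of identical physical copies this
    compartment equation represents (10 for the MSN's representative
    dendrite, 1 otherwise).
    """

    id: str
    C_m: float
    channels: list[ChannelSpec] = field(default_factory=list)
    neighbors: dict[str, float] = field(default_factory=dict)
    multiplicity: int = 1
    #: membrane potential state (mV); also the initial condition at t=0
    V: float = -65.0

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ConfigurationError(f"compartment {self.id}: C_m must be > 0")
        if self.multiplicity < 1:
            raise ConfigurationError(f"compartment {self.id}: multiplicity >= 1")

    @property
    def n_gates(self) -> int:
        return sum(len(ch.gates) for ch in self.channels)


@dataclass
class NeuronModel:
    """A neuron: an ordered list of compartments with symmetric coupling."""

    name: str
    type: str  # one of MSN, Pyra, PV, CB
    region: str  # NAc or mPFC
    compartments: list[Compartment]
    soma_id: str = "soma"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"{self.name}: duplicate compartment ids")
        if self.soma_id not in ids:
            raise ConfigurationError(f"{self.name}: soma id {self.soma_id!r} missing")
        byid = {c.id: c for c in self.compartments}
        for c in self.compartments:
            for nb in c.neighbors:
                if nb not in byid:
                    raise TopologyError(f"{self.name}: {c.id} lists unknown neighbor {nb}")
                if c.id not in byid[nb].neighbors:
                    raise TopologyError(
                        f"{self.name}: coupling {c.id}->{nb} is not symmetric"
                    )
        expected = {"MSN": 11, "Pyra": 3, "PV": 1, "CB": 1}
        if self.type in expected and self.n_logical_compartments != expected[self.type]:
            raise ConfigurationError(
                f"{self.name}: {self.type} must have {expected[self.type]} "
                f"compartments, found {self.n_logical_compartments}"
            )

    @property
    def soma(self) -> Compartment:
        return next(c for c in self.compartments if c.id == self.soma_id)

    @property
    def n_logical_compartments(self) -> int:
        """Physical compartment count (MSN dendrites count 10 times)."""
        return sum(c.multiplicity for c in self.compartments)

    @property
    def n_membrane_equations(self) -> int:
        """Number of distinct membrane ODEs actually integrated."""
        return len(self.compartments)

    @property
    def n_gate_variables(self) -> int:
        return sum(c.n_gates for c in self.compartments)


def coupling_current(c_from: Compartment, c_to: Compartment, g_c: float) -> float:
    """Ohmic coupling current (nA) flowing into ``c_to`` from ``c_from``.

    ``g_c * (V_from - V_to)`` per physical edge instance; antisymmetric under
    exchange of the two compartments.  Requires the compartments to be
    declared neighbors.
    """
    if c_to.id not in c_from.neighbors or c_from.id not in c_to.neighbors:
        raise TopologyError(f"{c_from.id} and {c_to.id} are not coupled")
    return g_c * (c_from.V - c_to.V)


def membrane_derivative(
    C_m: float, I_ions: float, I_syn_in: float, I_stim: float, I_comp_in: float
) -> float:
    """dV/dt in mV/ms for one compartment.

    Sign convention: ``I_ions`` is the total ionic current, outward positive
    (``g * (V - E)``); ``I_stim``, ``I_comp_in`` and ``I_syn_in`` are
    currents flowing *into* the compartment (depolarizing positive).  The
    resulting equation is algebraically the four-current balance
    ``C_m dV/dt + sum I_ions + sum I_comp + sum I_syn = I_stim`` where the
    compartment and synaptic sums use the outward-positive convention.
    """
    if C_m <= 0:
        raise ConfigurationError("C_m must be > 0")
    return (I_stim + I_comp_in + I_syn_in - I_ions) / C_m
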