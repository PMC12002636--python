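"""Chemical synapse kinetics: AMPA, NMDA and GABAa receptors.

Transmitter release is voltage-based (the network is a continuously coupled
ODE system): the transmitter concentration seen by the receptor is a sigmoid
function of the presynaptic somatic potential,

    T(V_pre) = T_max / (1 + exp(-(V_pre - V_T) / K_p)),

and the receptor open fraction ``s`` follows first-order binding kinetics

    ds/dt = alpha * T(V_pre) * (1 - s) - beta * s,

so ``s`` stays in [0, 1] along any trajectory.  The synaptic current is

    I_syn = g_max * s * B(V_post) * (V_post - E_rev)   (outward positive)

where ``B`` is the magnesium-block factor for NMDA receptors
(``B(V) = 1 / (1 + [Mg] exp(-0.062 V) / 3.57)`` with [Mg] = 1 mM) and
identically 1 for AMPA and GABAa.  AMPA and NMDA currents are excitatory
postsynaptic currents (EPSC, E_rev = 0 mV); GABAa currents are inhibitory
(IPSC, hyperpolarized E_rev).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .channels import ConfigurationError

__all__ = [
    "RECEPTOR_KINETICS",
    "SynapseSpec",
    "SynapseState",
    "transmitter_concentration",
    "synaptic_gating_derivative",
    "nmda_block",
    "synaptic_current",
    "classify_current",
]

#: Default first-order binding kinetics per receptor:
#: (alpha [1/(mM ms)], beta [1/ms], E_rev [mV]).
RECEPTOR_KINETICS = {
    "AMPA": (1.1, 0.19, 0.0),
    "NMDA": (0.072, 0.0066, 0.0),
    "GABAa": (5.0, 0.18, -80.0),
}

T_MAX = 1.0  # mM
T_VHALF = 2.0  # mV
T_KP = 5.0  # mV
MG_CONC = 1.0  # mM


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse: receptor class, strength and endpoints.

    ``pre`` is the presynaptic neuron name; ``post`` is a
    ``(neuron, compartment)`` pair.  ``g_max`` in uS.
    """

    receptor: str
    g_max: float
    pre: str
    post: tuple[str, str]
    alpha: float | None = None
    beta: float | None = None
    E_rev: float | None = None

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTOR_KINETICS:
            raise ConfigurationError(f"unknown receptor {self.receptor!r}")
        if self.g_max < 0:
            raise ConfigurationError("g_max must be >= 0")

    @property
    def kinetics(self) -> tuple[float, float, float]:
        a0, b0, e0 = RECEPTOR_KINETICS[self.receptor]
        return (
            self.alpha if self.alpha is not None else a0,
            self.beta if self.beta is not None else b0,
            self.E_rev if self.E_rev is not None else e0,
        )


@dataclass
class SynapseState:
    """Receptor open fraction; invariant: s in [0, 1]."""

    s: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ConfigurationError(f"synaptic gating value {self.s!r} outside [0, 1]")


def transmitter_concentration(V_pre: float) -> float:
    """Transmitter concentration (mM) released at presynaptic potential V_pre."""
    return T_MAX / (1.0 + math.exp(-(V_pre - T_VHALF) / T_KP))


def synaptic_gating_derivative(spec: SynapseSpec, state: SynapseState, V_pre: float) -> float:
    """ds/dt (1/ms): rises with presynaptic depolarization, decays otherwise."""
    alpha, beta, _ = spec.kinetics
    T = transmitter_concentration(V_pre)
    return alpha * T * (1.0 - state.s) - beta * state.s


def nmda_block(V_post: float) -> float:
    """Voltage-dependent magnesium block factor B(V) in (0, 1)."""
    return 1.0 / (1.0 + MG_CONC * math.exp(-0.062 * V_post) / 3.57)


def synaptic_current(spec: SynapseSpec, state: SynapseState, V_post: float) -> float:
    """Synaptic current in nA, outward positive:
    ``g_max * s * B(V_post) * (V_post - E_rev)``.
    """
    _, _, E_rev = spec.kinetics
    B = nmda_block(V_post) if spec.receptor == "NMDA" else 1.0
    return spec.g_max * state.s * B * (V_post - E_rev)


def classify_current(spec: SynapseSpec) -> str:
    """'EPSC' for AMPA/NMDA, 'IPSC' for GABAa."""
    if spec.receptor in ("AMPA", "NMDA"):
        return "EPSC"
    if spec.receptor == "GABAa":
        return "IPSC"
    raise ConfigurationError(f"unknown receptor {spec.receptor!r}")
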