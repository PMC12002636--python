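"""Voltage-gated ion channel models and their dopaminergic modulation.

Every channel is a Hodgkin-Huxley style conductance: a maximal conductance
``g_max`` (uS), a reversal potential ``E_rev`` (mV) and a product of gating
variables, each obeying first-order relaxation kinetics

    dx/dt = (x_inf(V) - x) / tau_x(V)

with a Boltzmann steady state and a bell-shaped voltage-dependent time
constant.  A leak channel is simply a channel with no gates.

Dopamine enters the model exclusively through multiplicative scaling of the
maximal conductance of six named channel families: Ca, Can, KS and NaP on
mPFC pyramidal compartments (D1-type modulation) and KAs, CaL1.2 on the NAc
medium spiny neuron (D2-type).  The scale factor is linear and continuous in
the normalized dopamine concentration ``DA`` in [0, 1] and equals 1 at the
midpoint DA = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GatingVariableSpec",
    "ChannelSpec",
    "DopamineModulationRule",
    "DOPAMINE_SENSITIVE",
    "steady_state",
    "time_constant",
    "evaluate_gate",
    "channel_current",
    "apply_dopamine",
]

#: Channel families whose conductance is dopamine sensitive, per neuron type.
#: D1-type (pyramidal): Ca, Can, KS, NaP.  D2-type (MSN): KAs, CaL1.2.
DOPAMINE_SENSITIVE = {
    "Pyra": frozenset({"Ca", "Can", "KS", "NaP"}),
    "MSN": frozenset({"KAs", "CaL1.2"}),
    "PV": frozenset(),
    "CB": frozenset(),
}


class InvalidStateError(ValueError):
    """Raised when a gate value or membrane potential is out of domain."""


class ConfigurationError(ValueError):
    """Raised when a spec is internally inconsistent."""


@dataclass(frozen=True)
class GatingVariableSpec:
    """One first-order gating variable of a channel.

    ``x_inf(V) = 1 / (1 + exp((v_half - V) / k))`` -- ``k > 0`` for
    activation gates, ``k < 0`` for inactivation gates.

    ``tau(V) = tau_min + tau_amp / (exp((V - tau_vhalf)/tau_s1)
                                    + exp(-(V - tau_vhalf)/tau_s2))``
    which is strictly positive for ``tau_min > 0``.
    """

    name: str
    exponent: int
    v_half: float  # mV
    k: float  # mV slope factor; sign encodes activation vs inactivation
    tau_min: float  # ms
    tau_amp: float  # ms
    tau_vhalf: float  # mV
    tau_s1: float  # mV
    tau_s2: float  # mV

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ConfigurationError(f"gate {self.name}: exponent must be >= 0")
        if self.tau_min <= 0:
            raise ConfigurationError(f"gate {self.name}: tau_min must be > 0")
        if self.tau_amp < 0:
            raise ConfigurationError(f"gate {self.name}: tau_amp must be >= 0")
        if self.k == 0:
            raise ConfigurationError(f"gate {self.name}: slope k must be nonzero")


def steady_state(spec: GatingVariableSpec, V: float) -> float:
    """Steady-state open fraction x_inf(V); always in (0, 1)."""
    return 1.0 / (1.0 + math.exp((spec.v_half - V) / spec.k))


def time_constant(spec: GatingVariableSpec, V: float) -> float:
    """Voltage-dependent time constant tau(V) in ms; strictly positive."""
    u = V - spec.tau_vhalf
    return spec.tau_min + spec.tau_amp / (
        math.exp(u / spec.tau_s1) + math.exp(-u / spec.tau_s2)
    )


def evaluate_gate(spec: GatingVariableSpec, V: float, x: float) -> float:
    """Time derivative dx/dt (1/ms) of a gate at potential ``V``.

    First-order relaxation toward ``steady_state(spec, V)`` with time
    constant ``time_constant(spec, V)``; the fixed point is the steady state.
    """
    if not math.isfinite(V):
        raise InvalidStateError(f"non-finite membrane potential {V!r}")
    if not (0.0 <= x <= 1.0):
        raise InvalidStateError(f"gate value {x!r} outside [0, 1]")
    return (steady_state(spec, V) - x) / time_constant(spec, V)


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance-based membrane channel.

    ``g_max`` in uS (whole-compartment), ``E_rev`` in mV.  ``mod_slope`` is
    the dopamine sensitivity: the effective conductance under normalized
    dopamine concentration ``DA`` is ``g_max * (1 + mod_slope*(DA - 0.5))``.
    Insensitive channels have ``mod_slope == 0``.
    """

    name: str
    g_max: float
    E_rev: float
    gates: tuple[GatingVariableSpec, ...] = field(default_factory=tuple)
    dopamine_sensitive: bool = False
    mod_slope: float = 0.0
    #: unmodulated conductance; None until a modulation rule has been applied
    g_base: float | None = None

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ConfigurationError(f"channel {self.name}: g_max must be >= 0")
        if not self.dopamine_sensitive and self.mod_slope != 0.0:
            raise ConfigurationError(
                f"channel {self.name}: insensitive channel cannot carry "
                f"mod_slope={self.mod_slope}"
            )
        if abs(self.mod_slope) >= 2.0:
            raise ConfigurationError(
                f"channel {self.name}: |mod_slope| must be < 2 so the "
                "conductance stays positive on DA in [0, 1]"
            )

    @property
    def is_leak(self) -> bool:
        return len(self.gates) == 0


def channel_current(spec: ChannelSpec, gate_values, V: float) -> float:
    """Channel current in nA, outward positive:
    ``g_max * prod(x_i**p_i) * (V - E_rev)``.
    """
    if len(gate_values) != len(spec.gates):
        raise ConfigurationError(
            f"channel {spec.name}: {len(gate_values)} gate values for "
            f"{len(spec.gates)} gates"
        )
    g = spec.g_max
    for gate, x in zip(spec.gates, gate_values):
        if not (0.0 <= x <= 1.0):
            raise InvalidStateError(f"gate value {x!r} outside [0, 1]")
        g *= x**gate.exponent
    return g * (V - spec.E_rev)


@dataclass(frozen=True)
class DopamineModulationRule:
    """Linear conductance scaling of one channel family by dopamine.

    ``factor(DA) = 1 + slope * (DA - 0.5)``, deterministic and continuous on
    DA in [0, 1]; the factor is 1 at the interval midpoint.
    """

    channel: str
    slope: float

    def factor(self, DA: float) -> float:
        if not (0.0 <= DA <= 1.0):
            raise ValueError(f"dopamine concentration {DA!r} outside [0, 1]")
        return 1.0 + self.slope * (DA - 0.5)


def apply_dopamine(rule: DopamineModulationRule, spec: ChannelSpec, DA: float) -> ChannelSpec:
    """Return the channel spec with its conductance scaled for dopamine ``DA``.

    Channels whose family does not match the rule (or that are insensitive)
    are returned unchanged.  The transform is idempotent at fixed DA: it
    always scales the *unmodulated* base conductance, which is remembered on
    the returned spec, so applying the rule twice equals applying it once.
    """
    if not (0.0 <= DA <= 1.0):
        raise ValueError(f"dopamine concentration {DA!r} outside [0, 1]")
    if not spec.dopamine_sensitive or spec.name != rule.channel:
        return spec
    base = spec.g_max if spec.g_base is None else spec.g_base
    return replace(spec, g_max=base * rule.factor(DA), g_base=base)
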