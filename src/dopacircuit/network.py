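"""Assembly of the 28-neuron NAc-mPFC microcircuit.

The network contains 1 MSN, 1 PV and 1 CB interneuron in the NAc, and 20
pyramidal neurons, 3 PV and 2 CB interneurons in the mPFC.  Dopamine is not
a cell population: it enters as a global normalized concentration parameter
drawn uniformly at random within one of four level ranges (Low 0-25%,
Medium 25-50%, High 50-75%, Full 75-100%) and redrawn once per recording
step.  The Low condition models the depressive-like (MDD) state, Full the
normal control.

Assembled out of the synthetic parameter set shipped with the package, the
circuit integrates 69 membrane equations (the MSN's ten identical dendrites
share one representative equation) and 1,527 state variables in total
(69 membrane potentials + 260 channel gates + 1,198 synaptic gates).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .channels import ChannelSpec, ConfigurationError, DOPAMINE_SENSITIVE, DopamineModulationRule, GatingVariableSpec
from .compartments import Compartment, NeuronModel
from .synapses import SynapseSpec

__all__ = [
    "DopamineLevel",
    "LEVELS",
    "StimulusSpec",
    "NetworkModel",
    "AssemblyError",
    "load_neuron_params",
    "build_network",
    "sample_dopamine",
    "sample_dopamine_path",
    "stimulus_current",
    "replicate_rng",
]

#: population name -> (region, neuron type, count)
POPULATIONS = {
    "MSN": ("NAc", "MSN", 1),
    "PV_NAc": ("NAc", "PV", 1),
    "CB_NAc": ("NAc", "CB", 1),
    "Pyra": ("mPFC", "Pyra", 20),
    "PV_mPFC": ("mPFC", "PV", 3),
    "CB_mPFC": ("mPFC", "CB", 2),
}


class AssemblyError(ValueError):
    """Raised when the assembled network violates a structural invariant."""


@dataclass(frozen=True)
class DopamineLevel:
    """One of the four uniform dopamine-input regimes on [lo, hi)."""

    name: str
    lo: float
    hi: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


LEVELS: dict[str, DopamineLevel] = {
    "Low": DopamineLevel("Low", 0.0, 0.25),
    "Medium": DopamineLevel("Medium", 0.25, 0.50),
    "High": DopamineLevel("High", 0.50, 0.75),
    "Full": DopamineLevel("Full", 0.75, 1.00),
}

LEVEL_ORDER = ("Low", "Medium", "High", "Full")


@dataclass(frozen=True)
class StimulusSpec:
    """Constant somatic current injection (nA) for one neuron."""

    neuron: str
    amplitude: float


def stimulus_current(stim: StimulusSpec, t: float) -> float:
    """Stimulus current (nA) at time t (ms); deterministic in t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return stim.amplitude


@dataclass
class NetworkModel:
    """The assembled microcircuit."""

    neurons: list[NeuronModel]
    synapses: list[SynapseSpec]
    stimuli: dict[str, StimulusSpec]
    level: DopamineLevel
    modulation: dict[str, dict[str, float]]  # neuron type -> channel -> slope
    seed: int = 0
    dopamine_refresh_ms: float = 0.05  # redraw cadence of the dopamine input

    def neuron(self, name: str) -> NeuronModel:
        return next(n for n in self.neurons if n.name == name)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_membrane_equations(self) -> int:
        return sum(n.n_membrane_equations for n in self.neurons)

    @property
    def n_gate_variables(self) -> int:
        return sum(n.n_gate_variables for n in self.neurons)

    @property
    def n_synaptic_variables(self) -> int:
        return len(self.synapses)

    @property
    def n_state_variables(self) -> int:
        return (
            self.n_membrane_equations
            + self.n_gate_variables
            + self.n_synaptic_variables
        )

    def modulation_rules(self) -> list[DopamineModulationRule]:
        return [
            DopamineModulationRule(channel=ch, slope=s)
            for rules in self.modulation.values()
            for ch, s in rules.items()
        ]

    def structure_hash(self) -> str:
        """Deterministic digest of the full structural description."""
        desc = {
            "level": self.level.name,
            "neurons": [
                (
                    n.name,
                    n.type,
                    n.region,
                    [
                        (
                            c.id,
                            c.C_m,
                            c.multiplicity,
                            sorted(c.neighbors.items()),
                            [
                                (
                                    ch.name,
                                    ch.g_max,
                                    ch.E_rev,
                                    ch.mod_slope,
                                    [
                                        (
                                            g.name,
                                            g.exponent,
                                            g.v_half,
                                            g.k,
                                            g.tau_min,
                                            g.tau_amp,
                                            g.tau_vhalf,
                                            g.tau_s1,
                                            g.tau_s2,
                                        )
                                        for g in ch.gates
                                    ],
                                )
                                for ch in c.channels
                            ],
                        )
                        for c in n.compartments
                    ],
                )
                for n in self.neurons
            ],
            "synapses": [
                (s.receptor, s.g_max, s.pre, s.post) for s in self.synapses
            ],
            "stimuli": sorted((k, v.amplitude) for k, v in self.stimuli.items()),
        }
        return hashlib.sha256(json.dumps(desc, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# parameter-file loading and validation


def _params_dir() -> Path:
    return Path(resources.files("dopacircuit") / "params")


def _load_yaml(name: str, params_dir: str | Path | None) -> dict:
    path = (Path(params_dir) if params_dir else _params_dir()) / name
    with open(path) as fh:
        return yaml.safe_load(fh)


def _gate_from_dict(d: dict) -> GatingVariableSpec:
    return GatingVariableSpec(
        name=d["name"],
        exponent=int(d["exponent"]),
        v_half=float(d["v_half"]),
        k=float(d["k"]),
        tau_min=float(d["tau_min"]),
        tau_amp=float(d["tau_amp"]),
        tau_vhalf=float(d["tau_vhalf"]),
        tau_s1=float(d["tau_s1"]),
        tau_s2=float(d["tau_s2"]),
    )


def load_neuron_params(
    neuron_type: str,
    params_dir: str | Path | None = None,
    modulation: dict[str, float] | None = None,
) -> dict:
    """Load and validate one neuron type's parameter document.

    Returns the raw dict; ``build_neuron`` turns it into a NeuronModel.
    Validation: every dopamine-sensitive flag must match the channel's
    membership in the type's sensitive set, and gate/channel parameters must
    satisfy their invariants (checked by the spec dataclasses).
    """
    fname = {
        "MSN": "synthetic_msn.yaml",
        "Pyra": "synthetic_pyra.yaml",
        "PV": "synthetic_pv.yaml",
        "CB": "synthetic_cb.yaml",
    }[neuron_type]
    doc = _load_yaml(fname, params_dir)
    if doc.get("type") != neuron_type:
        raise ConfigurationError(
            f"{fname}: declared type {doc.get('type')!r} != {neuron_type!r}"
        )
    sensitive = DOPAMINE_SENSITIVE[neuron_type]
    for comp in doc["compartments"]:
        for ch in comp["channels"]:
            flagged = bool(ch.get("dopamine_sensitive", False))
            if flagged != (ch["name"] in sensitive):
                raise ConfigurationError(
                    f"{fname}: channel {ch['name']} dopamine_sensitive flag "
                    f"inconsistent with the {neuron_type} sensitive set"
                )
    return doc


def build_neuron(
    name: str,
    neuron_type: str,
    region: str,
    doc: dict,
    modulation: dict[str, float],
) -> NeuronModel:
    """Instantiate a NeuronModel from a validated parameter document."""
    compartments = []
    coupling = doc.get("coupling") or []
    neighbor_map: dict[str, dict[str, float]] = {}
    for edge in coupling:
        neighbor_map.setdefault(edge["a"], {})[edge["b"]] = float(edge["g_c"])
        neighbor_map.setdefault(edge["b"], {})[edge["a"]] = float(edge["g_c"])
    for comp in doc["compartments"]:
        channels = []
        for ch in comp["channels"]:
            slope = modulation.get(ch["name"], 0.0)
            channels.append(
                ChannelSpec(
                    name=ch["name"],
                    g_max=float(ch["g_max"]),
                    E_rev=float(ch["E_rev"]),
                    gates=tuple(_gate_from_dict(g) for g in ch.get("gates", [])),
                    dopamine_sensitive=bool(ch.get("dopamine_sensitive", False)),
                    mod_slope=slope if ch.get("dopamine_sensitive", False) else 0.0,
                )
            )
        compartments.append(
            Compartment(
                id=comp["id"],
                C_m=float(comp["C_m"]),
                channels=channels,
                neighbors=neighbor_map.get(comp["id"], {}),
                multiplicity=int(comp.get("multiplicity", 1)),
                V=float(comp.get("V_init", -65.0)),
            )
        )
    return NeuronModel(
        name=name,
        type=neuron_type,
        region=region,
        compartments=compartments,
        soma_id=doc.get("soma", "soma"),
    )


def _population_members(pop: str) -> list[str]:
    region, ntype, count = POPULATIONS[pop]
    if count == 1:
        return [pop]
    return [f"{pop}_{i + 1:02d}" for i in range(count)]


def build_network(
    level: str | DopamineLevel = "Full",
    seed: int = 0,
    params_dir: str | Path | None = None,
    dopamine_refresh_ms: float = 0.05,
    stim_jitter: float = 0.05,
) -> NetworkModel:
    """Assemble the full microcircuit from the shipped parameter files.

    ``stim_jitter`` is the relative spread of per-neuron stimulus
    amplitudes around the population value (Gaussian, drawn from a
    generator derived deterministically from ``seed``): same-type neurons
    share parameters but not drive, so their firing patterns differ.
    Assembly is deterministic -- identical arguments and files give an
    identical structure hash.

    Raises :class:`AssemblyError` if the assembled structure does not report
    exactly 28 neurons, 69 membrane equations and 1,527 state variables.
    """
    if isinstance(level, str):
        level = LEVELS[level]
    mod_doc = _load_yaml("synthetic_modulation.yaml", params_dir)["rules"]
    modulation = {t: {k: float(v) for k, v in d.items()} for t, d in mod_doc.items()}
    for ntype, rules in modulation.items():
        unknown = set(rules) - set(DOPAMINE_SENSITIVE.get(ntype, frozenset()))
        if unknown:
            raise ConfigurationError(
                f"modulation rules for non-sensitive channels {sorted(unknown)} "
                f"on {ntype}"
            )

    docs = {t: load_neuron_params(t, params_dir) for t in ("MSN", "Pyra", "PV", "CB")}
    neurons: list[NeuronModel] = []
    for pop, (region, ntype, count) in POPULATIONS.items():
        for member in _population_members(pop):
            neurons.append(
                build_neuron(member, ntype, region, docs[ntype], modulation.get(ntype, {}))
            )

    topo = _load_yaml("synthetic_topology.yaml", params_dir)["projections"]
    synapses: list[SynapseSpec] = []
    for proj in topo:
        pres = _population_members(proj["pre"])
        posts = _population_members(proj["post"])
        target = proj.get("target", "soma")
        for pre in pres:
            for post in posts:
                if pre == post:
                    continue  # no self-connections
                for receptor, g in proj["receptors"].items():
                    synapses.append(
                        SynapseSpec(
                            receptor=receptor,
                            g_max=float(g),
                            pre=pre,
                            post=(post, target),
                        )
                    )
    names = {n.name for n in neurons}
    for s in synapses:
        if s.pre not in names or s.post[0] not in names:
            raise AssemblyError(f"synapse endpoint missing: {s.pre} -> {s.post}")
        target_neuron = next(n for n in neurons if n.name == s.post[0])
        if s.post[1] not in {c.id for c in target_neuron.compartments}:
            raise AssemblyError(
                f"synapse targets unknown compartment {s.post[1]!r} on {s.post[0]}"
            )

    stim_doc = _load_yaml("synthetic_stimuli.yaml", params_dir)["amplitudes"]
    stim_rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 9137])
    stimuli = {}
    for pop in POPULATIONS:
        for member in _population_members(pop):
            amp = float(stim_doc[pop])
            if stim_jitter > 0:
                amp *= 1.0 + stim_jitter * stim_rng.standard_normal()
            stimuli[member] = StimulusSpec(neuron=member, amplitude=amp)

    net = NetworkModel(
        neurons=neurons,
        synapses=synapses,
        stimuli=stimuli,
        level=level,
        modulation=modulation,
        seed=seed,
        dopamine_refresh_ms=dopamine_refresh_ms,
    )

    expected = {"neurons": 28, "equations": 69, "variables": 1527}
    found = {
        "neurons": net.n_neurons,
        "equations": net.n_membrane_equations,
        "variables": net.n_state_variables,
    }
    if found != expected:
        raise AssemblyError(f"assembled counts {found} != declared topology {expected}")
    return net


# ---------------------------------------------------------------------------
# stochastic dopamine input


def replicate_rng(base_seed: int, level: DopamineLevel, replicate: int) -> np.random.Generator:
    """Per-run generator: all stochastic draws of (level, replicate) flow
    from one seed sequence derived from the base seed."""
    li = LEVEL_ORDER.index(level.name)
    return np.random.default_rng([int(base_seed) & 0x7FFFFFFF, li, int(replicate)])


def sample_dopamine(level: DopamineLevel, rng: np.random.Generator, n: int | None = None):
    """Uniform draw(s) of the normalized dopamine concentration in the
    level's range; successive samples independent."""
    return rng.uniform(level.lo, level.hi, size=n)


def sample_dopamine_path(level: DopamineLevel, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """A piecewise-constant dopamine sample path: one independent uniform
    draw per refresh interval."""
    return rng.uniform(level.lo, level.hi, size=n_steps)
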