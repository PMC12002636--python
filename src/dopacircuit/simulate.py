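"""Network integration: fixed-step RK4 with a stochastic dopamine input.

The integrator is deliberately a fixed-step explicit method so that a run is
bit-reproducible from its seed: the dopamine concentration is redrawn once
per recording interval (``dt_out``, default 0.05 ms), held constant between
redraws, and the whole sample path is drawn up front from a per-run
generator.  The default integration step is ``dt = 0.025 ms``; a
self-convergence test (halving dt) bounds the discretization error.

A :class:`SimulationTrace` records, on the ``dt_out`` grid, every membrane
potential, the per-equation current components (ionic, coupling, synaptic,
stimulus), the dopamine sample path, and the per-neuron instantaneous power
components used by the energy accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._compiled import CompiledNetwork, _integrate, compile_network
from .channels import channel_current, evaluate_gate
from .network import NetworkModel, replicate_rng, sample_dopamine_path
from .synapses import SynapseState, nmda_block, synaptic_gating_derivative

__all__ = [
    "SimulationTrace",
    "IntegrationError",
    "integrate",
    "run_replicates",
    "reference_rhs",
    "save_trace",
    "load_trace",
    "export_tsv",
]


class IntegrationError(RuntimeError):
    """Numerical divergence, reporting the time of failure in ms."""

    def __init__(self, t_fail: float):
        super().__init__(f"integration diverged at t = {t_fail:g} ms")
        self.t_fail = t_fail


@dataclass
class SimulationTrace:
    """Time-indexed record of one network run (grid spacing ``dt_out``)."""

    t: np.ndarray  # (n_t,) ms
    V: np.ndarray  # (n_t, n_eq) mV
    dvdt: np.ndarray  # (n_t, n_eq) mV/ms, from the RHS at the grid instant
    i_ion: np.ndarray  # (n_t, n_eq) nA, outward positive
    i_comp: np.ndarray  # (n_t, n_eq) nA, inward positive
    i_syn: np.ndarray  # (n_t, n_eq) nA, outward positive
    da: np.ndarray  # (n_t,) dopamine value governing each instant
    # per-neuron instantaneous powers, pW
    h_stim: np.ndarray
    h_comp: np.ndarray
    h_syn: np.ndarray
    h_epsc: np.ndarray
    h_ipsc: np.ndarray
    h_ion: np.ndarray  # consumption-positive battery power
    h_cap: np.ndarray  # capacitor term C V dV/dt
    h_res: np.ndarray  # resistive dissipation sum I_i (V - E_i)
    # metadata
    level: str = "Full"
    seed: int = 0
    replicate: int = 0
    dt: float = 0.025
    dt_out: float = 0.05
    clamp_count: int = 0
    neuron_names: list = field(default_factory=list)
    neuron_types: list = field(default_factory=list)
    neuron_regions: list = field(default_factory=list)
    soma_eq: np.ndarray | None = None
    eq_neuron: np.ndarray | None = None
    eq_labels: list = field(default_factory=list)
    cm: np.ndarray | None = None
    stim_amp: np.ndarray | None = None  # per-equation constant stimulus, nA

    @property
    def n_t(self) -> int:
        return self.t.size

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_names)

    @property
    def duration(self) -> float:
        return float(self.t[-1]) if self.t.size else 0.0

    @property
    def h_all(self) -> np.ndarray:
        """Actual (net) power per neuron: the vector sum of the stimulus,
        compartment and synaptic components and the ionic consumption."""
        return self.h_stim + self.h_comp + self.h_syn + self.h_ion

    @property
    def h_all_direct(self) -> np.ndarray:
        """Independent route to the same quantity: capacitor power plus
        resistive dissipation of the equivalent circuit."""
        return self.h_cap + self.h_res

    def soma_V(self, neuron: str | int) -> np.ndarray:
        idx = neuron if isinstance(neuron, int) else self.neuron_names.index(neuron)
        return self.V[:, self.soma_eq[idx]]

    def neuron_index(self, neuron: str) -> int:
        return self.neuron_names.index(neuron)

    def residual(self) -> np.ndarray:
        """Four-current balance residual per (instant, equation), nA:
        ``C_m dV/dt + I_ion + I_syn - I_comp - I_stim``; ~0 everywhere."""
        return (
            self.cm[None, :] * self.dvdt
            + self.i_ion
            + self.i_syn
            - self.i_comp
            - self.stim_amp[None, :]
        )


def integrate(
    net: NetworkModel,
    duration: float = 3000.0,
    dt: float = 0.025,
    dt_out: float = 0.05,
    replicate: int = 0,
    base_seed: int | None = None,
    compiled: CompiledNetwork | None = None,
    da_path: np.ndarray | None = None,
    v_jitter: float = 2.0,
) -> SimulationTrace:
    """Integrate the network for ``duration`` ms and record the trace.

    The per-run RNG is derived from ``(base_seed, level, replicate)`` and
    drives, in order, the initial-condition jitter (each compartment's
    starting potential is displaced uniformly within ``+/- v_jitter`` mV,
    desynchronizing otherwise-identical neurons) and then the dopamine
    sample path.  Identical arguments give a bit-identical trace.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n_sub = int(round(dt_out / dt))
    if abs(n_sub * dt - dt_out) > 1e-9:
        raise ValueError("dt_out must be an integer multiple of dt")
    cn = compiled if compiled is not None else compile_network(net)
    n_out = int(round(duration / dt_out))
    if abs(n_out * dt_out - duration) > 1e-6:
        raise ValueError("duration must be an integer multiple of dt_out")

    seed = net.seed if base_seed is None else base_seed
    rng = replicate_rng(seed, net.level, replicate)
    V0 = cn.v_init + (rng.uniform(-v_jitter, v_jitter, cn.n_eq) if v_jitter > 0 else 0.0)
    if da_path is None:
        da_path = sample_dopamine_path(net.level, max(1, n_out), rng)
    else:
        da_path = np.asarray(da_path, dtype=np.float64)
        if da_path.size < max(1, n_out):
            raise ValueError("da_path shorter than the number of intervals")

    n_t = n_out + 1
    n_eq, n_nrn = cn.n_eq, cn.n_neurons
    rec_V = np.empty((n_t, n_eq))
    rec_da = np.empty(n_t)
    rec_dvdt = np.empty((n_t, n_eq))
    rec_iion = np.empty((n_t, n_eq))
    rec_icomp = np.empty((n_t, n_eq))
    rec_isyn = np.empty((n_t, n_eq))
    pows = [np.empty((n_t, n_nrn)) for _ in range(8)]

    y0 = cn.initial_state(V0)
    status, clamps = _integrate(
        y0, dt, n_sub, da_path, n_out, *cn.kernel_args(), n_nrn,
        rec_V, rec_da, rec_dvdt, rec_iion, rec_icomp, rec_isyn, *pows,
    )
    if status >= 0:
        raise IntegrationError((status + 1) * dt_out)

    return SimulationTrace(
        t=np.arange(n_t) * dt_out,
        V=rec_V,
        dvdt=rec_dvdt,
        i_ion=rec_iion,
        i_comp=rec_icomp,
        i_syn=rec_isyn,
        da=rec_da,
        h_stim=pows[0],
        h_comp=pows[1],
        h_syn=pows[2],
        h_epsc=pows[3],
        h_ipsc=pows[4],
        h_ion=pows[5],
        h_cap=pows[6],
        h_res=pows[7],
        level=net.level.name,
        seed=seed,
        replicate=replicate,
        dt=dt,
        dt_out=dt_out,
        clamp_count=int(clamps),
        neuron_names=list(cn.neuron_names),
        neuron_types=list(cn.neuron_types),
        neuron_regions=list(cn.neuron_regions),
        soma_eq=cn.soma_eq.copy(),
        eq_neuron=cn.eq_neuron.copy(),
        eq_labels=list(cn.eq_labels),
        cm=cn.cm.copy(),
        stim_amp=cn.stim.copy(),
    )


@dataclass
class RunResult:
    """Outcome of one replicate run in a batch."""

    level: str
    replicate: int
    trace: SimulationTrace | None
    error: str | None = None


def run_replicates(
    levels,
    n: int = 9,
    base_seed: int = 0,
    duration: float = 3000.0,
    dt: float = 0.025,
    dt_out: float = 0.05,
    build=None,
    reduce=None,
):
    """Run ``n`` replicates per dopamine level; yields :class:`RunResult`.

    ``build(level_name) -> NetworkModel`` defaults to the shipped circuit.
    If ``reduce(trace)`` is given, each result carries ``reduce(trace)``
    instead of the full trace (keeps the batch memory-bounded).  Partial
    failures are reported per run, never fatal to the batch.
    """
    from .network import build_network

    if build is None:
        build = lambda lv: build_network(level=lv, seed=base_seed)
    compiled_cache: dict[str, tuple[NetworkModel, CompiledNetwork]] = {}
    for lv in levels:
        lv_name = lv if isinstance(lv, str) else lv.name
        if lv_name not in compiled_cache:
            net = build(lv_name)
            compiled_cache[lv_name] = (net, compile_network(net))
        net, cn = compiled_cache[lv_name]
        for r in range(n):
            try:
                trace = integrate(
                    net, duration=duration, dt=dt, dt_out=dt_out,
                    replicate=r, base_seed=base_seed, compiled=cn,
                )
                payload = reduce(trace) if reduce is not None else trace
                yield RunResult(lv_name, r, payload)
            except IntegrationError as exc:  # pragma: no cover - defensive
                yield RunResult(lv_name, r, None, error=str(exc))


# ---------------------------------------------------------------------------
# reference right-hand side built from the spec objects (used to cross-check
# the compiled kernel on random states)


def reference_rhs(net: NetworkModel, cn: CompiledNetwork, y: np.ndarray, DA: float) -> np.ndarray:
    """Evaluate the full system derivative via the dataclass-level operations
    (gate kinetics, channel/synapse/coupling currents), independently of the
    numba kernel, using the same state layout."""
    from .channels import DopamineModulationRule, apply_dopamine

    n_eq = cn.n_eq
    dy = np.zeros_like(y)
    eq_of = {lbl: i for i, lbl in enumerate(cn.eq_labels)}
    gate_cursor = 0
    i_ion = np.zeros(n_eq)
    for neuron in net.neurons:
        rules = net.modulation.get(neuron.type, {})
        for comp in neuron.compartments:
            eq = eq_of[f"{neuron.name}.{comp.id}"]
            V = y[eq]
            for ch in comp.channels:
                spec = ch
                if ch.dopamine_sensitive:
                    spec = apply_dopamine(
                        DopamineModulationRule(ch.name, rules[ch.name]), ch, DA
                    )
                gate_vals = []
                for gate in spec.gates:
                    x = y[n_eq + gate_cursor]
                    dy[n_eq + gate_cursor] = evaluate_gate(gate, V, x)
                    gate_vals.append(x)
                    gate_cursor += 1
                i_ion[eq] += channel_current(spec, gate_vals, V)

    i_comp = np.zeros(n_eq)
    for neuron in net.neurons:
        comps = {c.id: c for c in neuron.compartments}
        seen = set()
        for comp in neuron.compartments:
            for nb, g_c in comp.neighbors.items():
                key = tuple(sorted((comp.id, nb)))
                if key in seen:
                    continue
                seen.add(key)
                a = eq_of[f"{neuron.name}.{comp.id}"]
                b = eq_of[f"{neuron.name}.{nb}"]
                count = max(comp.multiplicity, comps[nb].multiplicity)
                dV = y[b] - y[a]
                i_comp[a] += (count / comp.multiplicity) * g_c * dV
                i_comp[b] -= (count / comps[nb].multiplicity) * g_c * dV

    i_syn = np.zeros(n_eq)
    soma_of = {n.name: eq_of[f"{n.name}.{n.soma_id}"] for n in net.neurons}
    for si, syn in enumerate(net.synapses):
        s = y[n_eq + cn.n_gates + si]
        state = SynapseState(s=min(max(s, 0.0), 1.0))
        v_pre = y[soma_of[syn.pre]]
        dy[n_eq + cn.n_gates + si] = synaptic_gating_derivative(syn, state, v_pre)
        post_eq = eq_of[f"{syn.post[0]}.{syn.post[1]}"]
        v_post = y[post_eq]
        _, _, E = syn.kinetics
        B = nmda_block(v_post) if syn.receptor == "NMDA" else 1.0
        i_syn[post_eq] += syn.g_max * state.s * B * (v_post - E)

    for eq in range(n_eq):
        dy[eq] = (cn.stim[eq] + i_comp[eq] - i_ion[eq] - i_syn[eq]) / cn.cm[eq]
    return dy


# ---------------------------------------------------------------------------
# persistence


def save_trace(trace: SimulationTrace, path: str | Path) -> None:
    """Store a trace in one HDF5 container (arrays + metadata attrs)."""
    import h5py

    arrays = dict(
        t=trace.t, V=trace.V, dvdt=trace.dvdt, i_ion=trace.i_ion,
        i_comp=trace.i_comp, i_syn=trace.i_syn, da=trace.da,
        h_stim=trace.h_stim, h_comp=trace.h_comp, h_syn=trace.h_syn,
        h_epsc=trace.h_epsc, h_ipsc=trace.h_ipsc, h_ion=trace.h_ion,
        h_cap=trace.h_cap, h_res=trace.h_res, soma_eq=trace.soma_eq,
        eq_neuron=trace.eq_neuron, cm=trace.cm, stim_amp=trace.stim_amp,
    )
    with h5py.File(path, "w") as fh:
        for k, v in arrays.items():
            fh.create_dataset(k, data=v)
        fh.attrs["level"] = trace.level
        fh.attrs["seed"] = trace.seed
        fh.attrs["replicate"] = trace.replicate
        fh.attrs["dt"] = trace.dt
        fh.attrs["dt_out"] = trace.dt_out
        fh.attrs["clamp_count"] = trace.clamp_count
        fh.attrs["neuron_names"] = list(trace.neuron_names)
        fh.attrs["neuron_types"] = list(trace.neuron_types)
        fh.attrs["neuron_regions"] = list(trace.neuron_regions)
        fh.attrs["eq_labels"] = list(trace.eq_labels)


def load_trace(path: str | Path) -> SimulationTrace:
    import h5py

    with h5py.File(path, "r") as fh:
        kw = {k: fh[k][...] for k in fh.keys()}
        return SimulationTrace(
            **kw,
            level=str(fh.attrs["level"]),
            seed=int(fh.attrs["seed"]),
            replicate=int(fh.attrs["replicate"]),
            dt=float(fh.attrs["dt"]),
            dt_out=float(fh.attrs["dt_out"]),
            clamp_count=int(fh.attrs["clamp_count"]),
            neuron_names=[str(s) for s in fh.attrs["neuron_names"]],
            neuron_types=[str(s) for s in fh.attrs["neuron_types"]],
            neuron_regions=[str(s) for s in fh.attrs["neuron_regions"]],
            eq_labels=[str(s) for s in fh.attrs["eq_labels"]],
        )


def export_tsv(trace: SimulationTrace, neuron: str, path: str | Path) -> None:
    """Write a light delimited-text export: time, somatic V and actual
    power of one neuron."""
    idx = trace.neuron_index(neuron)
    data = np.column_stack([trace.t, trace.soma_V(idx), trace.h_all[:, idx]])
    header = "t_ms\tV_soma_mV\tH_all_pW"
    np.savetxt(path, data, delimiter="\t", header=header, comments="")
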