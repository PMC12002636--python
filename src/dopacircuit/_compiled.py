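"""Flat-array network representation and the compiled integration kernel.

The assembled :class:`~dopacircuit.network.NetworkModel` is lowered to a set
of numpy arrays (one entry per membrane equation, channel, gate, coupling
edge and synapse) which a numba-compiled fixed-step RK4 loop integrates.
The kernel also evaluates, at every recording instant, the per-equation
current components and the per-neuron power components needed by the energy
accounting, so no per-synapse time series ever needs to be stored.

State vector layout (1,527 entries for the full circuit):

    y[0:n_eq]                 membrane potentials V (mV)
    y[n_eq:n_eq+n_gates]      channel gating variables, in channel order
    y[n_eq+n_gates:]          synaptic gating variables, in synapse order

All powers are in pW (nA * mV); energies integrate to pW*ms = 1e-6 nJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import NetworkModel

__all__ = ["CompiledNetwork", "compile_network"]


@dataclass
class CompiledNetwork:
    """Numpy lowering of a NetworkModel plus index metadata."""

    # membrane equations
    cm: np.ndarray  # (n_eq,) nF
    eq_mult: np.ndarray  # (n_eq,) physical copies of this equation
    eq_neuron: np.ndarray  # (n_eq,) neuron index
    v_init: np.ndarray  # (n_eq,) mV
    stim: np.ndarray  # (n_eq,) nA, constant
    # channels
    ch_eq: np.ndarray
    ch_g: np.ndarray
    ch_E: np.ndarray
    ch_slope: np.ndarray  # dopamine sensitivity slope (0 = insensitive)
    ch_gate0: np.ndarray  # first gate index
    ch_ng: np.ndarray  # number of gates
    # gates (state index = n_eq + i)
    g_eq: np.ndarray
    g_vh: np.ndarray
    g_k: np.ndarray
    g_tmin: np.ndarray
    g_tamp: np.ndarray
    g_tvh: np.ndarray
    g_ts1: np.ndarray
    g_ts2: np.ndarray
    g_exp: np.ndarray
    # coupling edges
    ed_a: np.ndarray
    ed_b: np.ndarray
    ed_g: np.ndarray
    ed_count: np.ndarray  # physical instances of the edge
    # synapses (state index = n_eq + n_gates + i)
    sy_pre_eq: np.ndarray
    sy_post_eq: np.ndarray
    sy_post_neuron: np.ndarray
    sy_g: np.ndarray
    sy_E: np.ndarray
    sy_alpha: np.ndarray
    sy_beta: np.ndarray
    sy_nmda: np.ndarray
    sy_exc: np.ndarray
    # metadata
    neuron_names: list = field(default_factory=list)
    neuron_types: list = field(default_factory=list)
    neuron_regions: list = field(default_factory=list)
    soma_eq: np.ndarray | None = None
    eq_labels: list = field(default_factory=list)

    @property
    def n_eq(self) -> int:
        return self.cm.size

    @property
    def n_gates(self) -> int:
        return self.g_vh.size

    @property
    def n_syn(self) -> int:
        return self.sy_g.size

    @property
    def n_state(self) -> int:
        return self.n_eq + self.n_gates + self.n_syn

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_names)

    def initial_state(self, V0: np.ndarray | None = None) -> np.ndarray:
        """Initial condition: V at the configured rest values (or ``V0``),
        gates at their steady state for that V, synapses closed."""
        y0 = np.zeros(self.n_state)
        y0[: self.n_eq] = self.v_init if V0 is None else V0
        V = y0[self.g_eq]
        xinf = 1.0 / (1.0 + np.exp((self.g_vh - V) / self.g_k))
        y0[self.n_eq : self.n_eq + self.n_gates] = xinf
        return y0

    def kernel_args(self) -> tuple:
        return (
            self.cm,
            self.eq_mult.astype(np.float64),
            self.eq_neuron,
            self.stim,
            self.ch_eq,
            self.ch_g,
            self.ch_E,
            self.ch_slope,
            self.ch_gate0,
            self.ch_ng,
            self.g_eq,
            self.g_vh,
            self.g_k,
            self.g_tmin,
            self.g_tamp,
            self.g_tvh,
            self.g_ts1,
            self.g_ts2,
            self.g_exp,
            self.ed_a,
            self.ed_b,
            self.ed_g,
            self.ed_count.astype(np.float64),
            self.sy_pre_eq,
            self.sy_post_eq,
            self.sy_post_neuron,
            self.sy_g,
            self.sy_E,
            self.sy_alpha,
            self.sy_beta,
            self.sy_nmda,
            self.sy_exc,
        )


def compile_network(net: NetworkModel) -> CompiledNetwork:
    """Lower a NetworkModel to flat arrays."""
    eq_index: dict[tuple[str, str], int] = {}
    cm, mult, eq_neuron, v_init, eq_labels = [], [], [], [], []
    ch_eq, ch_g, ch_E, ch_slope, ch_gate0, ch_ng = [], [], [], [], [], []
    g_eq, g_vh, g_k, g_tmin, g_tamp, g_tvh, g_ts1, g_ts2, g_exp = (
        [], [], [], [], [], [], [], [], [])
    ed_a, ed_b, ed_g, ed_count = [], [], [], []
    soma_eq = []

    for ni, neuron in enumerate(net.neurons):
        for comp in neuron.compartments:
            eq = len(cm)
            eq_index[(neuron.name, comp.id)] = eq
            cm.append(comp.C_m)
            mult.append(comp.multiplicity)
            eq_neuron.append(ni)
            v_init.append(comp.V)
            eq_labels.append(f"{neuron.name}.{comp.id}")
            for ch in comp.channels:
                ch_eq.append(eq)
                ch_g.append(ch.g_max)
                ch_E.append(ch.E_rev)
                ch_slope.append(ch.mod_slope)
                ch_gate0.append(len(g_vh))
                ch_ng.append(len(ch.gates))
                for gate in ch.gates:
                    g_eq.append(eq)
                    g_vh.append(gate.v_half)
                    g_k.append(gate.k)
                    g_tmin.append(gate.tau_min)
                    g_tamp.append(gate.tau_amp)
                    g_tvh.append(gate.tau_vhalf)
                    g_ts1.append(gate.tau_s1)
                    g_ts2.append(gate.tau_s2)
                    g_exp.append(gate.exponent)
        soma_eq.append(eq_index[(neuron.name, neuron.soma_id)])
        seen = set()
        for comp in neuron.compartments:
            for nb, g_c in comp.neighbors.items():
                key = tuple(sorted((comp.id, nb)))
                if key in seen:
                    continue
                seen.add(key)
                a = eq_index[(neuron.name, comp.id)]
                b = eq_index[(neuron.name, nb)]
                count = max(
                    comp.multiplicity,
                    next(c.multiplicity for c in neuron.compartments if c.id == nb),
                )
                ed_a.append(a)
                ed_b.append(b)
                ed_g.append(g_c)
                ed_count.append(count)

    name_to_idx = {n.name: i for i, n in enumerate(net.neurons)}
    sy_pre_eq, sy_post_eq, sy_post_neuron = [], [], []
    sy_g, sy_E, sy_alpha, sy_beta, sy_nmda, sy_exc = [], [], [], [], [], []
    for s in net.synapses:
        pre_neuron = net.neuron(s.pre)
        alpha, beta, E = s.kinetics
        sy_pre_eq.append(eq_index[(s.pre, pre_neuron.soma_id)])
        sy_post_eq.append(eq_index[s.post])
        sy_post_neuron.append(name_to_idx[s.post[0]])
        sy_g.append(s.g_max)
        sy_E.append(E)
        sy_alpha.append(alpha)
        sy_beta.append(beta)
        sy_nmda.append(1 if s.receptor == "NMDA" else 0)
        sy_exc.append(1 if s.receptor in ("AMPA", "NMDA") else 0)

    stim = np.zeros(len(cm))
    for ni, neuron in enumerate(net.neurons):
        stim[soma_eq[ni]] = net.stimuli[neuron.name].amplitude

    f64 = np.asarray
    return CompiledNetwork(
        cm=f64(cm, dtype=np.float64),
        eq_mult=np.asarray(mult, dtype=np.int64),
        eq_neuron=np.asarray(eq_neuron, dtype=np.int64),
        v_init=f64(v_init, dtype=np.float64),
        stim=stim,
        ch_eq=np.asarray(ch_eq, dtype=np.int64),
        ch_g=f64(ch_g, dtype=np.float64),
        ch_E=f64(ch_E, dtype=np.float64),
        ch_slope=f64(ch_slope, dtype=np.float64),
        ch_gate0=np.asarray(ch_gate0, dtype=np.int64),
        ch_ng=np.asarray(ch_ng, dtype=np.int64),
        g_eq=np.asarray(g_eq, dtype=np.int64),
        g_vh=f64(g_vh, dtype=np.float64),
        g_k=f64(g_k, dtype=np.float64),
        g_tmin=f64(g_tmin, dtype=np.float64),
        g_tamp=f64(g_tamp, dtype=np.float64),
        g_tvh=f64(g_tvh, dtype=np.float64),
        g_ts1=f64(g_ts1, dtype=np.float64),
        g_ts2=f64(g_ts2, dtype=np.float64),
        g_exp=np.asarray(g_exp, dtype=np.int64),
        ed_a=np.asarray(ed_a, dtype=np.int64),
        ed_b=np.asarray(ed_b, dtype=np.int64),
        ed_g=f64(ed_g, dtype=np.float64),
        ed_count=np.asarray(ed_count, dtype=np.int64),
        sy_pre_eq=np.asarray(sy_pre_eq, dtype=np.int64),
        sy_post_eq=np.asarray(sy_post_eq, dtype=np.int64),
        sy_post_neuron=np.asarray(sy_post_neuron, dtype=np.int64),
        sy_g=f64(sy_g, dtype=np.float64),
        sy_E=f64(sy_E, dtype=np.float64),
        sy_alpha=f64(sy_alpha, dtype=np.float64),
        sy_beta=f64(sy_beta, dtype=np.float64),
        sy_nmda=np.asarray(sy_nmda, dtype=np.int64),
        sy_exc=np.asarray(sy_exc, dtype=np.int64),
        neuron_names=[n.name for n in net.neurons],
        neuron_types=[n.type for n in net.neurons],
        neuron_regions=[n.region for n in net.neurons],
        soma_eq=np.asarray(soma_eq, dtype=np.int64),
        eq_labels=eq_labels,
    )


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _rhs(y, dy, DA, cm, eq_mult, eq_neuron, stim,
         ch_eq, ch_g, ch_E, ch_slope, ch_gate0, ch_ng,
         g_eq, g_vh, g_k, g_tmin, g_tamp, g_tvh, g_ts1, g_ts2, g_exp,
         ed_a, ed_b, ed_g, ed_count,
         sy_pre_eq, sy_post_eq, sy_post_neuron, sy_g, sy_E, sy_alpha,
         sy_beta, sy_nmda, sy_exc):
    n_eq = cm.size
    n_gates = g_vh.size
    n_syn = sy_g.size

    # gate kinetics
    for i in range(n_gates):
        V = y[g_eq[i]]
        x = y[n_eq + i]
        xinf = 1.0 / (1.0 + np.exp((g_vh[i] - V) / g_k[i]))
        u = V - g_tvh[i]
        tau = g_tmin[i] + g_tamp[i] / (np.exp(u / g_ts1[i]) + np.exp(-u / g_ts2[i]))
        dy[n_eq + i] = (xinf - x) / tau

    # ionic currents (outward positive), per equation
    i_ion = np.zeros(n_eq)
    for c in range(ch_g.size):
        eq = ch_eq[c]
        g = ch_g[c] * (1.0 + ch_slope[c] * (DA - 0.5))
        prod = 1.0
        for j in range(ch_ng[c]):
            x = y[n_eq + ch_gate0[c] + j]
            e = g_exp[ch_gate0[c] + j]
            for _ in range(e):
                prod *= x
        i_ion[eq] += g * prod * (y[eq] - ch_E[c])

    # coupling currents, inward positive, per equation instance
    i_comp = np.zeros(n_eq)
    for e in range(ed_g.size):
        a = ed_a[e]
        b = ed_b[e]
        dV = y[b] - y[a]
        i_comp[a] += (ed_count[e] / eq_mult[a]) * ed_g[e] * dV
        i_comp[b] -= (ed_count[e] / eq_mult[b]) * ed_g[e] * dV

    # synaptic gating and currents (outward positive)
    i_syn = np.zeros(n_eq)
    for s in range(n_syn):
        sv = y[n_eq + n_gates + s]
        vpre = y[sy_pre_eq[s]]
        T = 1.0 / (1.0 + np.exp(-(vpre - 2.0) / 5.0))
        dy[n_eq + n_gates + s] = sy_alpha[s] * T * (1.0 - sv) - sy_beta[s] * sv
        vpost = y[sy_post_eq[s]]
        B = 1.0
        if sy_nmda[s] == 1:
            B = 1.0 / (1.0 + np.exp(-0.062 * vpost) / 3.57)
        i_syn[sy_post_eq[s]] += sy_g[s] * sv * B * (vpost - sy_E[s])

    for eq in range(n_eq):
        dy[eq] = (stim[eq] + i_comp[eq] - i_ion[eq] - i_syn[eq]) / cm[eq]
    return dy


@njit(cache=True)
def _measure(y, DA, cm, eq_mult, eq_neuron, stim,
             ch_eq, ch_g, ch_E, ch_slope, ch_gate0, ch_ng,
             g_eq, g_vh, g_k, g_tmin, g_tamp, g_tvh, g_ts1, g_ts2, g_exp,
             ed_a, ed_b, ed_g, ed_count,
             sy_pre_eq, sy_post_eq, sy_post_neuron, sy_g, sy_E, sy_alpha,
             sy_beta, sy_nmda, sy_exc,
             n_neurons,
             out_dvdt, out_iion, out_icomp, out_isyn,
             out_hstim, out_hcomp, out_hsyn, out_hepsc, out_hipsc,
             out_hion, out_hcap, out_hres):
    """Evaluate current components and per-neuron powers at one instant.

    Powers (pW): H_stim = I_stim*V; H_comp = sum of coupling currents into
    each receiving compartment times its potential (physical totals);
    H_syn = -I_syn*V_post (EPSC/IPSC split by receptor class); H_ion is the
    battery power, stored consumption-positive as -sum I_i*E_i.  H_cap and
    H_res are the capacitor and resistive terms of the equivalent circuit,
    whose sum independently equals the component combination.
    """
    n_eq = cm.size
    n_gates = g_vh.size
    n_syn = sy_g.size

    for i in range(n_neurons):
        out_hstim[i] = 0.0
        out_hcomp[i] = 0.0
        out_hsyn[i] = 0.0
        out_hepsc[i] = 0.0
        out_hipsc[i] = 0.0
        out_hion[i] = 0.0
        out_hcap[i] = 0.0
        out_hres[i] = 0.0
    for eq in range(n_eq):
        out_iion[eq] = 0.0
        out_icomp[eq] = 0.0
        out_isyn[eq] = 0.0

    for c in range(ch_g.size):
        eq = ch_eq[c]
        g = ch_g[c] * (1.0 + ch_slope[c] * (DA - 0.5))
        prod = 1.0
        for j in range(ch_ng[c]):
            x = y[n_eq + ch_gate0[c] + j]
            e = g_exp[ch_gate0[c] + j]
            for _ in range(e):
                prod *= x
        I = g * prod * (y[eq] - ch_E[c])
        out_iion[eq] += I
        ni = eq_neuron[eq]
        out_hion[ni] += -eq_mult[eq] * I * ch_E[c]
        out_hres[ni] += eq_mult[eq] * I * (y[eq] - ch_E[c])

    for e in range(ed_g.size):
        a = ed_a[e]
        b = ed_b[e]
        dV = y[b] - y[a]
        ia = (ed_count[e] / eq_mult[a]) * ed_g[e] * dV  # into a, per instance
        ib = -(ed_count[e] / eq_mult[b]) * ed_g[e] * dV
        out_icomp[a] += ia
        out_icomp[b] += ib
        # physical totals for energy attribution to the receiving end
        out_hcomp[eq_neuron[a]] += eq_mult[a] * ia * y[a]
        out_hcomp[eq_neuron[b]] += eq_mult[b] * ib * y[b]

    for s in range(n_syn):
        sv = y[n_eq + n_gates + s]
        vpost = y[sy_post_eq[s]]
        B = 1.0
        if sy_nmda[s] == 1:
            B = 1.0 / (1.0 + np.exp(-0.062 * vpost) / 3.57)
        I = sy_g[s] * sv * B * (vpost - sy_E[s])
        out_isyn[sy_post_eq[s]] += I
        P = -I * vpost
        ni = sy_post_neuron[s]
        out_hsyn[ni] += P
        if sy_exc[s] == 1:
            out_hepsc[ni] += P
        else:
            out_hipsc[ni] += P

    for eq in range(n_eq):
        dvdt = (stim[eq] + out_icomp[eq] - out_iion[eq] - out_isyn[eq]) / cm[eq]
        out_dvdt[eq] = dvdt
        ni = eq_neuron[eq]
        out_hstim[ni] += eq_mult[eq] * stim[eq] * y[eq]
        out_hcap[ni] += eq_mult[eq] * cm[eq] * y[eq] * dvdt


@njit(cache=True)
def _integrate(y0, dt, n_sub, da_path, n_intervals,
               cm, eq_mult, eq_neuron, stim,
               ch_eq, ch_g, ch_E, ch_slope, ch_gate0, ch_ng,
               g_eq, g_vh, g_k, g_tmin, g_tamp, g_tvh, g_ts1, g_ts2, g_exp,
               ed_a, ed_b, ed_g, ed_count,
               sy_pre_eq, sy_post_eq, sy_post_neuron, sy_g, sy_E, sy_alpha,
               sy_beta, sy_nmda, sy_exc,
               n_neurons,
               rec_V, rec_da, rec_dvdt, rec_iion, rec_icomp, rec_isyn,
               rec_hstim, rec_hcomp, rec_hsyn, rec_hepsc, rec_hipsc,
               rec_hion, rec_hcap, rec_hres):
    """Fixed-step RK4 over ``n_intervals`` recording intervals of ``n_sub``
    sub-steps each; ``da_path`` holds one dopamine value per interval (and
    at least one value even for a zero-length run).  Returns
    (status, clamp_count): status is -1 on success, else the index of the
    recording interval where the state diverged."""
    n_eq = cm.size
    n_state = y0.size
    y = y0.copy()
    k1 = np.empty(n_state)
    k2 = np.empty(n_state)
    k3 = np.empty(n_state)
    k4 = np.empty(n_state)
    yt = np.empty(n_state)
    n_out = n_intervals
    clamps = 0

    args = (cm, eq_mult, eq_neuron, stim,
            ch_eq, ch_g, ch_E, ch_slope, ch_gate0, ch_ng,
            g_eq, g_vh, g_k, g_tmin, g_tamp, g_tvh, g_ts1, g_ts2, g_exp,
            ed_a, ed_b, ed_g, ed_count,
            sy_pre_eq, sy_post_eq, sy_post_neuron, sy_g, sy_E, sy_alpha,
            sy_beta, sy_nmda, sy_exc)

    # record the initial instant under the first dopamine value
    rec_V[0, :] = y[:n_eq]
    rec_da[0] = da_path[0]
    _measure(y, rec_da[0], *args, n_neurons,
             rec_dvdt[0], rec_iion[0], rec_icomp[0], rec_isyn[0],
             rec_hstim[0], rec_hcomp[0], rec_hsyn[0], rec_hepsc[0],
             rec_hipsc[0], rec_hion[0], rec_hcap[0], rec_hres[0])

    for k in range(n_out):
        DA = da_path[k]
        for _ in range(n_sub):
            _rhs(y, k1, DA, *args)
            for i in range(n_state):
                yt[i] = y[i] + 0.5 * dt * k1[i]
            _rhs(yt, k2, DA, *args)
            for i in range(n_state):
                yt[i] = y[i] + 0.5 * dt * k2[i]
            _rhs(yt, k3, DA, *args)
            for i in range(n_state):
                yt[i] = y[i] + dt * k3[i]
            _rhs(yt, k4, DA, *args)
            for i in range(n_state):
                y[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            # clamp gating variables to [0, 1]
            for i in range(n_eq, n_state):
                if y[i] < 0.0:
                    y[i] = 0.0
                    clamps += 1
                elif y[i] > 1.0:
                    y[i] = 1.0
                    clamps += 1
        diverged = False
        for eq in range(n_eq):
            if not np.isfinite(y[eq]) or np.abs(y[eq]) > 200.0:
                diverged = True
        if diverged:
            return k, clamps
        DA_rec = da_path[k + 1] if k + 1 < n_out else da_path[n_out - 1]
        rec_V[k + 1, :] = y[:n_eq]
        rec_da[k + 1] = DA_rec
        _measure(y, DA_rec, *args, n_neurons,
                 rec_dvdt[k + 1], rec_iion[k + 1], rec_icomp[k + 1],
                 rec_isyn[k + 1],
                 rec_hstim[k + 1], rec_hcomp[k + 1], rec_hsyn[k + 1],
                 rec_hepsc[k + 1], rec_hipsc[k + 1], rec_hion[k + 1],
                 rec_hcap[k + 1], rec_hres[k + 1])
    return -1, clamps
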