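"""High-level driver for the replicate study and its statistics.

Runs the full 4-level x n-replicate design (default 9 replicates of
3,000 ms per dopamine level), reduces every run to per-neuron energy and
metric tables, and feeds the same-type-averaged samples through the
test-selection pipeline.  This is the programmatic equivalent of the CLI
``simulate`` / ``energy`` / ``metrics`` / ``stats`` chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .energy import energy_table
from .metrics import metrics_table
from .network import LEVEL_ORDER, build_network
from .simulate import run_replicates
from .stats import GroupComparison, average_same_type, select_and_run_tests

__all__ = ["run_study", "study_statistics", "comparison_table"]

#: per-type scopes whose statistics use same-type averaging
TYPE_SCOPES = [
    ("MSN", "NAc"), ("PV", "NAc"), ("CB", "NAc"),
    ("Pyra", "mPFC"), ("PV", "mPFC"), ("CB", "mPFC"),
]


def run_study(
    levels=LEVEL_ORDER,
    n: int = 9,
    base_seed: int = 0,
    duration: float = 3000.0,
    dt: float = 0.025,
    dt_out: float = 0.05,
    progress=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the design and return (energy table, metrics table).

    Each trace is reduced immediately so the batch stays memory-bounded.
    """

    def _reduce(trace):
        et = energy_table(trace)
        mt = metrics_table(trace)
        et["replicate"] = trace.replicate
        mt["replicate"] = trace.replicate
        return et, mt

    ets, mts = [], []
    for res in run_replicates(
        levels, n=n, base_seed=base_seed, duration=duration, dt=dt,
        dt_out=dt_out,
        build=lambda lv: build_network(level=lv, seed=base_seed),
        reduce=_reduce,
    ):
        if res.error is not None:
            raise RuntimeError(f"{res.level} replicate {res.replicate}: {res.error}")
        et, mt = res.trace
        ets.append(et)
        mts.append(mt)
        if progress is not None:
            progress(res.level, res.replicate)
    return pd.concat(ets, ignore_index=True), pd.concat(mts, ignore_index=True)


def _type_samples(energy: pd.DataFrame, metrics: pd.DataFrame):
    """Per-(level, replicate) same-type-averaged samples for every metric.

    Per-type energies and per-spike energies are the average over the type's
    member neurons (20 Pyra, 3 mPFC PV, 2 mPFC CB; singletons in the NAc);
    regional and network energies are sums over their members.
    """
    samples: dict[str, list] = {}

    neuron_rows = energy[energy.scope_kind == "neuron"]
    for (ntype, region) in TYPE_SCOPES:
        tag = f"{ntype}_{region}"
        sub = neuron_rows[(neuron_rows.type == ntype) & (neuron_rows.region == region)]
        for (lv, rep), grp in sub.groupby(["level", "replicate"]):
            for metric, col in [
                (f"actual_energy_{tag}", "actual_nJ"),
                (f"ionic_energy_{tag}", "ionic_nJ"),
                (f"synaptic_energy_{tag}", "synaptic_nJ"),
                (f"epsc_energy_{tag}", "epsc_nJ"),
                (f"ipsc_energy_{tag}", "ipsc_nJ"),
                (f"energy_per_spike_{tag}", "energy_per_spike_nJ"),
            ]:
                samples.setdefault(metric, []).append(
                    average_same_type(grp[col].to_numpy(), metric=metric,
                                      level=lv, replicate=rep, scope=tag)
                )

        msub = metrics[(metrics.type == ntype) & (metrics.region == region)]
        for (lv, rep), grp in msub.groupby(["level", "replicate"]):
            for metric, col in [
                (f"pv_correlation_{tag}", "pv_r"),
                (f"firing_rate_{tag}", "rate_Hz"),
            ]:
                samples.setdefault(metric, []).append(
                    average_same_type(grp[col].to_numpy(), metric=metric,
                                      level=lv, replicate=rep, scope=tag)
                )

    for kind, scopes in [("region", ("NAc", "mPFC")), ("network", ("network",))]:
        sub = energy[energy.scope_kind == kind]
        for scope in scopes:
            ssub = sub[sub.scope == scope]
            for (lv, rep), grp in ssub.groupby(["level", "replicate"]):
                for metric, col in [
                    (f"actual_energy_{scope}", "actual_nJ"),
                    (f"ionic_energy_{scope}", "ionic_nJ"),
                    (f"external_energy_{scope}", "external_nJ"),
                ]:
                    samples.setdefault(metric, []).append(
                        average_same_type(grp[col].to_numpy(), metric=metric,
                                          level=lv, replicate=rep, scope=scope)
                    )
    return samples


def study_statistics(energy: pd.DataFrame, metrics: pd.DataFrame) -> dict[str, GroupComparison]:
    """Apply the test-selection pipeline to every study metric."""
    out = {}
    for metric, samp in _type_samples(energy, metrics).items():
        levels = {s.level for s in samp}
        counts = [sum(1 for s in samp if s.level == lv and np.isfinite(s.value))
                  for lv in levels]
        if len(levels) < 2 or min(counts) < 3:
            continue
        out[metric] = select_and_run_tests(samp, metric=metric)
    return out


def comparison_table(comparisons: dict[str, GroupComparison]) -> pd.DataFrame:
    """Flat summary: one row per metric with the omnibus result, the
    Low-vs-Full post-hoc p and the per-level means."""
    from .stats import significance_stars

    rows = []
    for metric, gc in comparisons.items():
        row = dict(metric=metric, omnibus=gc.omnibus, omnibus_p=gc.omnibus_p,
                   posthoc=gc.posthoc, p_low_vs_full=gc.pair_p("Low", "Full"),
                   stars_low_vs_full=significance_stars(gc.pair_p("Low", "Full")))
        for lv in LEVEL_ORDER:
            if lv in gc.summary:
                mean, sem, n = gc.summary[lv]
                row[f"mean_{lv}"] = mean
                row[f"sem_{lv}"] = sem
        rows.append(row)
    return pd.DataFrame(rows)
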