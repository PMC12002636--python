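"""Spike detection, energy efficiency and the P-V correlation.

The P-V correlation is the Pearson correlation coefficient between a
neuron's somatic membrane-potential trace and its actual-power trace over
the analysis window; it quantifies how far the classical potential-based
neural code and the energy code agree (1 = fully redundant, 0 =
independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "PVCorrelation",
    "detect_spikes",
    "energy_per_spike",
    "pv_correlation",
    "firing_rate",
    "metrics_table",
]


@dataclass
class SpikeTrain:
    """Somatic spike times detected by upward threshold crossing."""

    neuron: str
    times: np.ndarray  # ms, strictly increasing
    threshold: float = 0.0  # mV
    refractory: float = 2.0  # ms

    def __post_init__(self) -> None:
        d = np.diff(self.times)
        if d.size and (d <= 0).any():
            raise ValueError("spike times must be strictly increasing")
        if d.size and (d < self.refractory - 1e-9).any():
            raise ValueError("inter-spike interval below the refractory window")

    @property
    def count(self) -> int:
        return int(self.times.size)


def detect_spikes(
    V: np.ndarray,
    t: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 2.0,
    neuron: str = "",
) -> SpikeTrain:
    """Detect spikes as upward crossings of ``threshold``, suppressing any
    crossing within ``refractory`` ms of the previous accepted spike."""
    V = np.asarray(V)
    t = np.asarray(t)
    if V.shape != t.shape:
        raise ValueError("V and t must share the grid")
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refractory:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(neuron=neuron, times=np.asarray(times, dtype=float),
                      threshold=threshold, refractory=refractory)


def energy_per_spike(E: float, train_or_count) -> float:
    """Actual energy (nJ) divided by the spike count; NaN when the neuron
    never spiked (the value is then excluded from statistics)."""
    count = train_or_count.count if isinstance(train_or_count, SpikeTrain) else int(train_or_count)
    if count <= 0:
        return float("nan")
    return float(E) / count


@dataclass
class PVCorrelation:
    neuron: str
    level: str
    replicate: int
    r: float

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


def pv_correlation(V: np.ndarray, H: np.ndarray, neuron: str = "",
                   level: str = "", replicate: int = 0) -> PVCorrelation:
    """Pearson correlation between the membrane-potential and actual-power
    curves; NaN when either series has zero variance.  Invariant under
    affine rescaling of either series."""
    V = np.asarray(V, dtype=float)
    H = np.asarray(H, dtype=float)
    if V.shape != H.shape:
        raise ValueError("series must share the grid")
    if V.size < 2 or np.std(V) == 0.0 or np.std(H) == 0.0:
        return PVCorrelation(neuron, level, replicate, float("nan"))
    r = float(np.corrcoef(V, H)[0, 1])
    return PVCorrelation(neuron, level, replicate, r)


def firing_rate(train: SpikeTrain, duration_ms: float) -> float:
    """Mean firing rate in Hz over the window."""
    if duration_ms <= 0:
        return float("nan")
    return train.count / (duration_ms / 1000.0)


def metrics_table(trace, threshold: float = 0.0, refractory: float = 2.0) -> pd.DataFrame:
    """Per-neuron spike count, firing rate and P-V correlation for a trace.

    For multi-compartment neurons the correlation uses the somatic membrane
    potential against the whole neuron's actual power.
    """
    h_all = trace.h_all
    rows = []
    for i, name in enumerate(trace.neuron_names):
        v = trace.soma_V(i)
        train = detect_spikes(v, trace.t, threshold, refractory, neuron=name)
        pv = pv_correlation(v, h_all[:, i], name, trace.level, trace.replicate)
        rows.append(
            dict(
                neuron=name,
                type=trace.neuron_types[i],
                region=trace.neuron_regions[i],
                level=trace.level,
                replicate=trace.replicate,
                spikes=train.count,
                rate_Hz=firing_rate(train, trace.duration),
                pv_r=pv.r,
            )
        )
    return pd.DataFrame(rows)
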