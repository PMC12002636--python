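"""Replicate-based group statistics over the 4-level x 9-replicate design.

The test-selection protocol:

* normality per group by Shapiro-Wilk (alpha = 0.05; "non-normal" means any
  group fails);
* variance homogeneity by the Brown-Forsythe test (Levene centred on the
  median);
* normal + equal variances  -> one-way ANOVA with Tukey's multiple
  comparison test;
* normal + unequal variances -> Welch ANOVA with the Games-Howell multiple
  comparison test;
* non-normal -> Kruskal-Wallis with Dunn's multiple comparison test
  (Bonferroni-adjusted).

All tests are two-tailed; significance at p < 0.05.  Group summaries are
mean +/- SEM.  Same-type neuron values within one replicate are averaged
before any test (20 pyramidal cells, 3 mPFC PV, 2 mPFC CB; the NAc types
are singletons), which removes the within-replicate pseudo-replication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetricSample",
    "GroupComparison",
    "average_same_type",
    "summarize",
    "select_and_run_tests",
    "dunn_test",
    "significance_stars",
    "regression_vs_dopamine",
]

ALPHA = 0.05


@dataclass(frozen=True)
class MetricSample:
    """One value of one metric at one (level, replicate) after averaging."""

    metric: str
    level: str
    replicate: int
    value: float
    scope: str = ""
    members_averaged: int = 1


def average_same_type(values, metric: str = "", level: str = "", replicate: int = 0,
                      scope: str = "") -> MetricSample:
    """Arithmetic mean across same-type neurons for one replicate.

    Missing values (e.g. the undefined energy-per-spike of a silent neuron)
    are excluded; the count of contributing members is recorded.
    """
    arr = np.asarray(list(values), dtype=float)
    ok = np.isfinite(arr)
    if not ok.any():
        value = float("nan")
    else:
        value = float(arr[ok].mean())
    return MetricSample(metric=metric, level=level, replicate=replicate,
                        value=value, scope=scope, members_averaged=int(ok.sum()))


def summarize(values) -> tuple[float, float, int]:
    """(mean, SEM, n); SEM = sample SD / sqrt(n), NaN for n < 2."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return mean, sem, n


@dataclass
class GroupComparison:
    """Result of the full test-selection pipeline for one metric."""

    metric: str
    omnibus: str  # "anova" | "welch-anova" | "kruskal-wallis" | "none"
    omnibus_p: float
    posthoc: str  # "tukey" | "games-howell" | "dunn" | "none"
    normality_p: dict = field(default_factory=dict)
    variance_p: float = float("nan")
    pairwise_p: dict = field(default_factory=dict)  # (level_a, level_b) -> p
    summary: dict = field(default_factory=dict)  # level -> (mean, sem, n)

    @property
    def significant(self) -> bool:
        return np.isfinite(self.omnibus_p) and self.omnibus_p < ALPHA

    def pair_p(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.pairwise_p else (b, a)
        return self.pairwise_p.get(key, float("nan"))


def dunn_test(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based multiple comparison with tie correction and
    Bonferroni adjustment over all pairs."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = sps.rankdata(pooled)
    N = pooled.size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (np.sum(counts**3 - counts) / (N**3 - N)) if N > 1 else 1.0
    mean_ranks = {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    m = len(names) * (len(names) - 1) // 2
    out = {}
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(tie * (N * (N + 1) / 12.0) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out[(a, b)] = min(1.0, p * m)
    return out


def _games_howell(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    import pingouin as pg

    long = pd.DataFrame(
        [(g, v) for g, arr in groups.items() for v in arr], columns=["group", "y"]
    )
    res = pg.pairwise_gameshowell(data=long, dv="y", between="group")
    return {(row["A"], row["B"]): float(row["pval"]) for _, row in res.iterrows()}


def _tukey(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    names = list(groups)
    res = sps.tukey_hsd(*[np.asarray(groups[g], dtype=float) for g in names])
    out = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            out[(a, names[j])] = float(res.pvalue[i, j])
    return out


def select_and_run_tests(samples, metric: str | None = None) -> GroupComparison:
    """Run the full decision tree on a set of :class:`MetricSample` (or a
    mapping level -> values) spanning >= 2 levels with >= 3 replicates."""
    if isinstance(samples, dict):
        groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
        metric = metric or ""
    else:
        samples = list(samples)
        metric = metric or (samples[0].metric if samples else "")
        groups = {}
        for s in samples:
            groups.setdefault(s.level, []).append(s.value)
        groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2 or any(v.size < 3 for v in groups.values()):
        raise ValueError("need >= 2 levels with >= 3 replicates each")

    summary = {k: summarize(v) for k, v in groups.items()}

    if any(np.ptp(v) == 0.0 for v in groups.values()):
        # degenerate zero-variance group: report summaries without p-values
        return GroupComparison(metric=metric, omnibus="none", omnibus_p=float("nan"),
                               posthoc="none", summary=summary)

    normality = {k: float(sps.shapiro(v).pvalue) for k, v in groups.items()}
    all_normal = all(p >= ALPHA for p in normality.values())
    bf_p = float(sps.levene(*groups.values(), center="median").pvalue)

    arrays = list(groups.values())
    if not all_normal:
        omnibus = "kruskal-wallis"
        p = float(sps.kruskal(*arrays).pvalue)
        posthoc = "dunn"
        pairs = dunn_test(groups)
    elif bf_p >= ALPHA:
        omnibus = "anova"
        p = float(sps.f_oneway(*arrays).pvalue)
        posthoc = "tukey"
        pairs = _tukey(groups)
    else:
        omnibus = "welch-anova"
        import pingouin as pg

        long = pd.DataFrame(
            [(g, v) for g, arr in groups.items() for v in arr],
            columns=["group", "y"],
        )
        p = float(pg.welch_anova(data=long, dv="y", between="group")["p_unc"].iloc[0])
        posthoc = "games-howell"
        pairs = _games_howell(groups)

    return GroupComparison(
        metric=metric,
        omnibus=omnibus,
        omnibus_p=p,
        posthoc=posthoc,
        normality_p=normality,
        variance_p=bf_p,
        pairwise_p=pairs,
        summary=summary,
    )


def significance_stars(p: float) -> str:
    """Conventional significance stars: **** p<1e-4, *** p<1e-3, ** p<0.01,
    * p<0.05, ns otherwise."""
    if not np.isfinite(p):
        return "na"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return "ns"


def regression_vs_dopamine(samples, midpoints: dict[str, float] | None = None):
    """Ordinary least-squares regression of a metric on the dopamine level
    midpoints (Low 0.125, Medium 0.375, High 0.625, Full 0.875); p-value
    uncorrected.  Returns (slope, intercept, r, p)."""
    from .network import LEVELS

    if midpoints is None:
        midpoints = {name: lv.midpoint for name, lv in LEVELS.items()}
    xs, ys = [], []
    for s in samples:
        if np.isfinite(s.value):
            xs.append(midpoints[s.level])
            ys.append(s.value)
    res = sps.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)
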