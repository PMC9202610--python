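"""Statistical comparisons and summary tables of the benchmark results.

One-way ANOVA tests the effect of a factor (SNR level, channel count,
classifier) on a metric; post-hoc pairwise comparisons use either two-sample
t-tests (the VAF-by-setting analysis) or the Tukey-Kramer procedure
(similarity and classification analyses; valid for unequal group sizes).
The significance level of the benchmark is 0.05.  Summary tables report the
mean and the standard error over trials, pooled across datasets within a
setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALPHA",
    "GroupedObservations",
    "anova_one_way",
    "posthoc",
    "summarize_grid",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupedObservations:
    """Metric values labelled by the level of one factor."""

    values: np.ndarray
    groups: np.ndarray
    factor: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        g = np.asarray(self.groups)
        if v.shape != g.shape:
            raise ValueError("values and groups must align")
        labels, counts = np.unique(g, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need at least 2 groups")
        if np.any(counts < 2):
            raise ValueError("every group needs at least 2 values")

    def samples(self) -> list[np.ndarray]:
        v = np.asarray(self.values, dtype=float)
        g = np.asarray(self.groups)
        return [v[g == lab] for lab in np.unique(g)]

    def labels(self) -> np.ndarray:
        return np.unique(np.asarray(self.groups))


def anova_one_way(obs: GroupedObservations) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    The degenerate case of identical constant groups (no variance anywhere)
    returns (0.0, 1.0).
    """
    samples = obs.samples()
    allv = np.concatenate(samples)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def posthoc(obs: GroupedObservations, kind: str = "tukey_kramer") -> pd.DataFrame:
    """All pairwise comparisons after ANOVA.

    ``kind="ttest"`` runs pairwise two-sample t-tests; ``kind="tukey_kramer"``
    uses the studentized-range distribution with unequal group sizes.
    Returns a tidy frame with columns group1, group2, p_value, significant.
    """
    samples = obs.samples()
    labels = obs.labels()
    rows = []
    if kind == "ttest":
        for (i, a), (j, b) in combinations(enumerate(samples), 2):
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
            rows.append((labels[i], labels[j], p))
    elif kind == "tukey_kramer":
        if max(np.ptp(s) for s in samples) == 0 and np.ptp(np.concatenate(samples)) == 0:
            pmat = np.ones((len(samples), len(samples)))
        else:
            pmat = stats.tukey_hsd(*samples).pvalue
        for i, j in combinations(range(len(samples)), 2):
            rows.append((labels[i], labels[j], float(pmat[i, j])))
    else:
        raise ValueError(f"unknown post-hoc kind {kind!r}")
    df = pd.DataFrame(rows, columns=["group1", "group2", "p_value"])
    df["significant"] = df["p_value"] < ALPHA
    return df


def _summary(df: pd.DataFrame, metric: str, by: list[str]) -> pd.DataFrame:
    g = df.groupby(by)[metric]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["degenerate"] = out["n"] < 2  # single-trial groups: se undefined
    return out


def summarize_grid(results: pd.DataFrame,
                   metrics: tuple[str, ...] = ("vaf", "svs", "acs", "pa_deg"),
                   require_methods: tuple[str, ...] | None = None) -> dict[str, pd.DataFrame]:
    """Per-(method, setting) mean +/- standard-error tables for each metric.

    Standard errors are computed over trials pooled across datasets within a
    setting.  FA rows are naturally absent for settings below its
    degrees-of-freedom bound.  Missing requested methods raise.
    """
    if require_methods is not None:
        missing = set(require_methods) - set(results["method"].unique())
        if missing:
            raise ValueError(f"results table is missing methods: {sorted(missing)}")
    tables: dict[str, pd.DataFrame] = {}
    for metric in metrics:
        if metric not in results.columns:
            continue
        tables[f"{metric}_by_snr"] = _summary(results, metric, ["method", "snr_db"])
        tables[f"{metric}_by_noc"] = _summary(results, metric, ["method", "noc"])
        tables[f"{metric}_overall"] = _summary(results, metric, ["method"])
    return tables
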