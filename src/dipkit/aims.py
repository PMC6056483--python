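"""Ancestry-informative-marker (AIM) selection by the delta criterion.

For each locus, population insertion frequencies are averaged within each
continental cluster (unweighted — every population counts once regardless
of its sample size) and delta is the largest absolute difference between
cluster means (equivalently max - min).  Loci with delta strictly above the
threshold (0.29 by default, the cutoff used for this panel) are selected;
the complement is reported too, for contrast re-clustering analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AlleleFreqTable


@dataclass
class AimReport:
    table: pd.DataFrame  # locus, per-cluster mean columns, delta, selected
    threshold: float
    selected: list[str]  # sorted by delta descending
    eliminated: list[str]


def cluster_mean_freqs(
    table: AlleleFreqTable, cluster_assignment: dict[str, str]
) -> pd.DataFrame:
    """Unweighted cluster x locus mean insertion frequencies."""
    missing = [p for p in table.populations if p not in cluster_assignment]
    if missing:
        raise ValueError(f"populations without a cluster: {missing}")
    clusters: dict[str, list[int]] = {}
    for i, pop in enumerate(table.populations):
        clusters.setdefault(cluster_assignment[pop], []).append(i)
    for name, rows in clusters.items():
        if not rows:
            raise ValueError(f"empty cluster {name!r}")
    means = {name: np.nanmean(table.p[rows], axis=0) for name, rows in clusters.items()}
    return pd.DataFrame(means, index=table.locus_ids).T


def delta_statistic(cluster_means: np.ndarray) -> float:
    """delta = max pairwise |difference| of cluster means (= max - min)."""
    m = np.asarray(cluster_means, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 cluster means")
    return float(np.nanmax(m) - np.nanmin(m))


def select_aims(
    table: AlleleFreqTable,
    cluster_assignment: dict[str, str],
    threshold: float = 0.29,
) -> AimReport:
    """Rank loci by delta and select those with delta > threshold (strict)."""
    means = cluster_mean_freqs(table, cluster_assignment)
    deltas = means.max(axis=0) - means.min(axis=0)
    out = means.T.copy()
    out.insert(0, "locus", out.index)
    out["delta"] = deltas
    out["selected"] = deltas > threshold
    out = out.sort_values("delta", ascending=False, ignore_index=True)
    return AimReport(
        table=out,
        threshold=threshold,
        selected=list(out.loc[out["selected"], "locus"]),
        eliminated=list(out.loc[~out["selected"], "locus"]),
    )
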