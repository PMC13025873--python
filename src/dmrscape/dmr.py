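"""Clustering direction-consistent DMS into differentially methylated regions.

A single greedy pass joins consecutive same-chromosome, same-direction DMS
whose inter-site gap is at most ``max_gap``; a direction change or larger
gap closes the cluster. Cluster significance combines member p-values by
Stouffer's method oriented along the cluster direction, and clusters are
then filtered on combined significance and mean methylation difference
(|diff| >= 0.25 by default, with 0.35 as the stricter alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterPolicy",
    "cluster_dms",
    "score_cluster",
    "filter_dmrs",
    "call_dmrs",
    "threshold_subset_check",
]

_MIN_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class ClusterPolicy:
    max_gap: int = 1000
    min_dms: int = 3
    cluster_alpha: float = 0.05
    min_abs_diff: float = 0.25

    def __post_init__(self):
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.min_dms < 2:
            raise ValueError("min_dms must be >= 2")
        if not 0 <= self.cluster_alpha <= 1:
            raise ValueError("cluster_alpha must be in [0, 1]")
        if not 0 < self.min_abs_diff <= 1:
            raise ValueError("min_abs_diff must be in (0, 1]")


def cluster_dms(dms: pd.DataFrame, policy: ClusterPolicy = ClusterPolicy()) -> list[pd.DataFrame]:
    """Greedy single-pass clustering of sorted DMS into candidate clusters.

    Clusters separated by exactly ``max_gap`` are merged (inclusive rule);
    clusters with fewer than ``min_dms`` members are discarded.
    """
    if dms.empty:
        return []
    chrom = dms["chrom"].to_numpy()
    pos = dms["pos"].to_numpy()
    order_ok = all(
        (chrom[i] < chrom[i + 1]) or (chrom[i] == chrom[i + 1] and pos[i] < pos[i + 1])
        for i in range(len(dms) - 1)
    )
    if not order_ok:
        raise ValueError("DMS must be sorted by (chrom, pos) and unique")
    direction = dms["direction"].to_numpy()
    breaks = [0]
    for i in range(1, len(dms)):
        if (chrom[i] != chrom[i - 1] or direction[i] != direction[i - 1]
                or pos[i] - pos[i - 1] > policy.max_gap):
            breaks.append(i)
    breaks.append(len(dms))
    clusters = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi - lo >= policy.min_dms:
            clusters.append(dms.iloc[lo:hi].reset_index(drop=True))
    return clusters


def score_cluster(cluster: pd.DataFrame) -> float:
    """Stouffer combination of member p-values, equal weights.

    Member p-values are mapped to z-scores oriented along the shared
    cluster direction (``z = Phi^-1(1 - p)``); the combined p-value is the
    two-sided tail of ``Z = sum(z) / sqrt(n)``. Zero p-values are clamped
    to the smallest positive float.
    """
    p = cluster["p_value"].to_numpy(dtype=float)
    if len(p) < 2:
        raise ValueError("cluster must have >= 2 members with p-values")
    p = np.clip(p, _MIN_P, 1.0)
    z = stats.norm.isf(p)
    Z = z.sum() / np.sqrt(len(z))
    return float(min(2.0 * stats.norm.sf(abs(Z)), 1.0))


def filter_dmrs(clusters: list[pd.DataFrame],
                policy: ClusterPolicy = ClusterPolicy()) -> pd.DataFrame:
    """Score clusters and keep those passing significance and |diff| filters.

    The DMR interval is half-open: first member position to last member
    position + 2 (covering the final CpG dyad). The |mean diff| filter is
    inclusive at the threshold.
    """
    rows = []
    for cluster in clusters:
        combined_p = score_cluster(cluster)
        mean_diff = float(cluster["meth_diff"].mean())
        if combined_p > policy.cluster_alpha:
            continue
        if abs(mean_diff) < policy.min_abs_diff - 1e-12:
            continue
        pos = cluster["pos"].to_numpy()
        rows.append({
            "chrom": cluster["chrom"].iloc[0],
            "start": int(pos[0]),
            "end": int(pos[-1]) + 2,
            "direction": cluster["direction"].iloc[0],
            "n_dms": len(cluster),
            "mean_diff": mean_diff,
            "combined_p": combined_p,
        })
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                     "n_dms", "mean_diff", "combined_p"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    df.insert(0, "dmr_id", [f"DMR_{i + 1:04d}" for i in range(len(df))])
    return df


def call_dmrs(dms: pd.DataFrame, policy: ClusterPolicy = ClusterPolicy()) -> pd.DataFrame:
    """Cluster, score and filter in one call."""
    return filter_dmrs(cluster_dms(dms, policy), policy)


def threshold_subset_check(dmrs_lenient: pd.DataFrame, dmrs_strict: pd.DataFrame) -> bool:
    """True iff every DMR called at the stricter |diff| threshold also appears,
    with identical coordinates and direction, in the lenient-threshold set.

    Both sets must come from the same upstream DMS with only ``min_abs_diff``
    differing; relaxing the filter can only add DMRs.
    """
    key_cols = ["chrom", "start", "end", "direction", "n_dms"]
    if dmrs_strict.empty:
        return True
    lenient = set(map(tuple, dmrs_lenient[key_cols].itertuples(index=False)))
    strict = set(map(tuple, dmrs_strict[key_cols].itertuples(index=False)))
    return strict <= lenient
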