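"""Two-sided proportion tests and BH-adjusted category enrichment tables.

Distributions of chromatin groups or positional categories in a DMR subset
are compared against the full DMR set with a pooled two-proportion z-test,
falling back to Fisher's exact test whenever any expected cell count drops
below 5 (where the normal approximation is unreliable). All p-values from
one table call form a single Benjamini-Hochberg family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import REGION_ORDER
from .dms import bh_adjust
from .overlap import STATE_GROUPS

__all__ = [
    "two_proportion_test",
    "enrichment_table",
    "positional_distribution",
]

POSITIONAL_CATEGORIES = REGION_ORDER + ["intergenic"]


def two_proportion_test(k1: int, n1: int, k2: int, n2: int,
                        min_expected: float = 5.0) -> tuple[float, str]:
    """Two-sided test of equal proportions; returns (p_value, method).

    Uses the pooled two-proportion z-test without continuity correction;
    if any expected count ``n_i * p_pooled`` or ``n_i * (1 - p_pooled)``
    is below ``min_expected``, Fisher's exact test is used instead.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("k must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    expected = [n1 * pooled, n1 * (1 - pooled), n2 * pooled, n2 * (1 - pooled)]
    if min(expected) < min_expected:
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(sps.fisher_exact(table, alternative="two-sided")[1]), "fisher"
    if pooled in (0.0, 1.0):
        return 1.0, "z"
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return float(2 * sps.norm.sf(abs(z))), "z"


def _category_table(subset: pd.Series, universe: pd.Series, categories,
                    min_expected: float) -> pd.DataFrame:
    n_sub, n_all = len(subset), len(universe)
    rows = []
    for cat in categories:
        k_sub = int((subset == cat).sum())
        k_all = int((universe == cat).sum())
        if k_sub == 0 and k_all == 0:
            rows.append({"category": cat, "k_subset": 0, "n_subset": n_sub,
                         "k_all": 0, "n_all": n_all,
                         "prop_subset": 0.0, "prop_all": 0.0,
                         "p_value": np.nan, "method": "NA"})
            continue
        p, method = two_proportion_test(k_sub, n_sub, k_all, n_all,
                                        min_expected=min_expected)
        rows.append({"category": cat, "k_subset": k_sub, "n_subset": n_sub,
                     "k_all": k_all, "n_all": n_all,
                     "prop_subset": k_sub / n_sub, "prop_all": k_all / n_all,
                     "p_value": p, "method": method})
    return pd.DataFrame(rows)


def enrichment_table(subset_profiles: pd.DataFrame, all_profiles: pd.DataFrame,
                     min_expected: float = 5.0) -> pd.DataFrame:
    """Chromatin-group enrichment of a DMR subset vs the full DMR set.

    Inputs are feature-profile frames with ``dominant_group`` and
    ``direction`` columns. One test per group per direction; BH is applied
    across every test in the table; rows sorted by q then category.
    """
    if subset_profiles.empty:
        raise ValueError("subset is empty")
    parts = []
    for direction in ("hypo", "hyper"):
        sub = subset_profiles[subset_profiles["direction"] == direction]
        uni = all_profiles[all_profiles["direction"] == direction]
        if len(sub) == 0 or len(uni) == 0:
            continue
        tab = _category_table(sub["dominant_group"], uni["dominant_group"],
                              STATE_GROUPS, min_expected)
        tab.insert(0, "direction", direction)
        parts.append(tab)
    out = pd.concat(parts, ignore_index=True)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["q_value", "direction", "category"],
                           kind="stable", na_position="last").reset_index(drop=True)


def positional_distribution(subset_assignments: pd.DataFrame,
                            all_assignments: pd.DataFrame,
                            min_expected: float = 5.0) -> pd.DataFrame:
    """Region-category proportions of a DMR subset vs all DMRs, with tests."""
    if subset_assignments.empty:
        raise ValueError("subset is empty")
    tab = _category_table(subset_assignments["region"],
                          all_assignments["region"],
                          POSITIONAL_CATEGORIES, min_expected)
    tab["q_value"] = bh_adjust(tab["p_value"].to_numpy())
    return tab.sort_values(["q_value", "category"], kind="stable",
                           na_position="last").reset_index(drop=True)
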