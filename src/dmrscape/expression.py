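"""Selecting case-preferential and tissue-preferential genes from expression.

Case-preferential genes must be both highly expressed in the case sample
(FPKM >= 20 by default) and selective for it (case over the mean of the
heterologous reference cultures >= 20-fold). Tissue-preferential selection
uses a tissue value against the median of a large tissue panel (TPM >= 5
and ratio >= 5). A small epsilon in every denominator keeps ratios defined
when references are entirely silent, which is the typical situation for
lineage-restricted genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "select_case_preferential",
    "select_tissue_preferential",
    "flag_downmodulated",
]

EPSILON = 0.01


def _check_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")


def select_case_preferential(table: pd.DataFrame, case_col: str,
                             ref_cols: list[str], min_level: float = 20.0,
                             min_ratio: float = 20.0,
                             epsilon: float = EPSILON) -> pd.DataFrame:
    """Call genes highly and preferentially expressed in the case sample.

    A gene passes iff ``case >= min_level`` and
    ``case / (mean(refs) + epsilon) >= min_ratio`` (both inclusive).
    """
    if not ref_cols:
        raise ValueError("at least one heterologous reference column required")
    _check_columns(table, [case_col, *ref_cols])
    case = table[case_col].to_numpy(dtype=float)
    ref_mean = table[ref_cols].to_numpy(dtype=float).mean(axis=1)
    ratio = case / (ref_mean + epsilon)
    return pd.DataFrame({
        "gene_id": table.index if table.index.name == "gene_id" else table.get("gene_id", table.index),
        "case_level": case,
        "ref_mean": ref_mean,
        "ratio": ratio,
        "passes": (case >= min_level) & (ratio >= min_ratio),
        "rule": "case_pref",
    }).reset_index(drop=True)


def select_tissue_preferential(table: pd.DataFrame, tissue_col: str,
                               panel_cols: list[str], min_tpm: float = 5.0,
                               min_ratio: float = 5.0,
                               epsilon: float = EPSILON) -> pd.DataFrame:
    """Call genes preferentially expressed in one tissue vs a tissue panel.

    A gene passes iff ``tissue >= min_tpm`` and
    ``tissue / (median(panel) + epsilon) >= min_ratio``.
    """
    if not panel_cols:
        raise ValueError("tissue panel must be non-empty")
    _check_columns(table, [tissue_col, *panel_cols])
    tissue = table[tissue_col].to_numpy(dtype=float)
    panel_median = np.median(table[panel_cols].to_numpy(dtype=float), axis=1)
    ratio = tissue / (panel_median + epsilon)
    return pd.DataFrame({
        "gene_id": table.index if table.index.name == "gene_id" else table.get("gene_id", table.index),
        "case_level": tissue,
        "ref_mean": panel_median,
        "ratio": ratio,
        "passes": (tissue >= min_tpm) & (ratio >= min_ratio),
        "rule": "tissue_pref",
    }).reset_index(drop=True)


def flag_downmodulated(case_fpkm, tissue_tpm, min_ratio: float = 10.0,
                       epsilon: float = EPSILON):
    """Flag genes whose tissue expression dwarfs their case-culture expression.

    True iff ``tissue / (case + epsilon) >= min_ratio``. The tissue value
    is in TPM and the culture value in FPKM, as the selection is defined;
    the cross-unit ratio is deliberate (a coarse, threshold-style contrast,
    not a normalised effect size).
    """
    case = np.asarray(case_fpkm, dtype=float)
    tissue = np.asarray(tissue_tpm, dtype=float)
    return tissue / (case + epsilon) >= min_ratio
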