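"""Classifying DMRs against chromatin states, CpG islands/shores and TF sites.

The 18-state chromatin segmentation is collapsed into nine reporting
groups: Prom (state 1), WkProm (2, 4), PromEnh (3), Txn (5, 6), EnhG
(7, 8), EnhA (9, 10), WkEnh (11), Repr (12-17) and Low (18). Genome not
covered by any segment counts as Low (the "no mark" state). Each DMR gets
per-group base fractions and a dominant group; ties break by a fixed
precedence. CGI overlap is measured relative to DMR length with a 30%
flagging rule; shores are the 2 kb flanks of a CGI excluding island bases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._intervals import any_overlap, merge_intervals, overlap_bp, subtract_intervals

__all__ = [
    "STATE_TO_GROUP",
    "STATE_GROUPS",
    "TIE_PRECEDENCE",
    "group_states",
    "dominant_state",
    "cgi_overlap",
    "shore_overlap",
    "tf_overlap",
    "prom_chrom_width",
    "profile_dmrs",
]

STATE_TO_GROUP = {
    1: "Prom", 2: "WkProm", 3: "PromEnh", 4: "WkProm",
    5: "Txn", 6: "Txn", 7: "EnhG", 8: "EnhG",
    9: "EnhA", 10: "EnhA", 11: "WkEnh",
    12: "Repr", 13: "Repr", 14: "Repr", 15: "Repr", 16: "Repr", 17: "Repr",
    18: "Low",
}

STATE_GROUPS = ["Prom", "WkProm", "PromEnh", "EnhG", "EnhA", "WkEnh",
                "Txn", "Repr", "Low"]

# Fixed tie-break order when two groups cover an equal number of DMR bases.
TIE_PRECEDENCE = ["Prom", "PromEnh", "EnhA", "EnhG", "WkProm", "WkEnh",
                  "Txn", "Repr", "Low"]


def group_states(segments: pd.DataFrame) -> pd.DataFrame:
    """Label 18-state segments with their group; merge adjacent same-group runs.

    ``segments`` needs columns ``chrom, start, end, state`` (state 1..18).
    """
    states = segments["state"].to_numpy()
    bad = ~np.isin(states, list(STATE_TO_GROUP))
    if bad.any():
        raise ValueError(f"states outside 1..18: {sorted(set(states[bad]))}")
    df = segments.sort_values(["chrom", "start"], kind="stable").copy()
    df["group"] = df["state"].map(STATE_TO_GROUP)
    rows = []
    for row in df.itertuples(index=False):
        if (rows and rows[-1]["chrom"] == row.chrom
                and rows[-1]["group"] == row.group
                and row.start <= rows[-1]["end"]):
            rows[-1]["end"] = max(rows[-1]["end"], row.end)
        else:
            rows.append({"chrom": row.chrom, "start": int(row.start),
                         "end": int(row.end), "group": row.group})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "group"])


def dominant_state(dmr, grouped: pd.DataFrame) -> tuple[str, dict[str, float]]:
    """Dominant chromatin group and per-group base fractions for one DMR.

    Uncovered bases are counted as Low; fractions sum to exactly 1. The
    dominant group maximises the covered base count, with ties resolved
    by :data:`TIE_PRECEDENCE`.
    """
    length = int(dmr.end) - int(dmr.start)
    if length <= 0:
        raise ValueError("DMR interval must be non-empty")
    sub = grouped[(grouped["chrom"] == dmr.chrom)
                  & (grouped["end"] > dmr.start) & (grouped["start"] < dmr.end)]
    bp = {g: 0 for g in STATE_GROUPS}
    for row in sub.itertuples(index=False):
        bp[row.group] += min(row.end, dmr.end) - max(row.start, dmr.start)
    covered = sum(bp.values())
    bp["Low"] += length - covered
    best = max(TIE_PRECEDENCE, key=lambda g: (bp[g], -TIE_PRECEDENCE.index(g)))
    fractions = {g: bp[g] / length for g in STATE_GROUPS}
    return best, fractions


def cgi_overlap(dmr, cgis: pd.DataFrame, flag_fraction: float = 0.30) -> tuple[float, bool]:
    """DMR-relative CGI overlap fraction and the >= 30% flag.

    CGIs are merged on the fly, so the fraction is invariant to splitting
    an island into abutting pieces. The flag comparison is exact in base
    pairs (overlap_bp / length >= flag_fraction, inclusive).
    """
    length = int(dmr.end) - int(dmr.start)
    sub = cgis[cgis["chrom"] == dmr.chrom]
    starts, ends = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    bp = overlap_bp(int(dmr.start), int(dmr.end), starts, ends)
    fraction = bp / length
    # exact rational comparison avoids float-boundary misflags at e.g. 0.30
    flag = bp * 100 >= round(flag_fraction * 100) * length
    return fraction, bool(flag)


def shore_overlap(dmr, cgis: pd.DataFrame, shore_width: int = 2000) -> bool:
    """True iff the DMR overlaps a CGI shore (2 kb flank minus island bases)."""
    sub = cgis[cgis["chrom"] == dmr.chrom]
    cs, ce = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    if cs.size == 0:
        return False
    flank_s = np.concatenate([np.maximum(cs - shore_width, 0), ce])
    flank_e = np.concatenate([cs, ce + shore_width])
    ss, se = subtract_intervals(flank_s, flank_e, cs, ce)
    return any_overlap(int(dmr.start), int(dmr.end), ss, se)


def tf_overlap(dmr, tf_sites: dict[str, pd.DataFrame]) -> dict[str, bool]:
    """Per-factor flag: any >= 1 bp overlap with that factor's occupied sites."""
    flags = {}
    for factor, sites in tf_sites.items():
        sub = sites[sites["chrom"] == dmr.chrom]
        flags[factor] = bool(((sub["end"] > dmr.start) & (sub["start"] < dmr.end)).any())
    return flags


def prom_chrom_width(gene, grouped: pd.DataFrame, bridge_gap: int = 200,
                     window: int = 2000) -> tuple[int, str]:
    """Width of the promoter-chromatin run over a gene's TSS, and its class.

    Prom and PromEnh segments with gaps <= bridge_gap are bridged into
    runs; the widest run overlapping TSS +/- window is measured (bridged
    gaps count toward the width). Classes: 'standard' (<= 2.5 kb), 'broad'
    (> 2.5 kb), 'very_broad' (4-8 kb); 'none' when no run touches the
    promoter window.
    """
    sub = grouped[(grouped["chrom"] == gene.chrom)
                  & grouped["group"].isin(["Prom", "PromEnh"])]
    sub = sub.sort_values("start", kind="stable")
    runs = []
    for row in sub.itertuples(index=False):
        if runs and row.start - runs[-1][1] <= bridge_gap:
            runs[-1][1] = max(runs[-1][1], int(row.end))
        else:
            runs.append([int(row.start), int(row.end)])
    w_start, w_end = gene.tss - window, gene.tss + window
    widths = [e - s for s, e in runs if s < w_end and w_start < e]
    if not widths:
        return 0, "none"
    width = max(widths)
    if 4000 <= width <= 8000:
        cls = "very_broad"
    elif width > 2500:
        cls = "broad"
    else:
        cls = "standard"
    return width, cls


def profile_dmrs(dmrs: pd.DataFrame, grouped: pd.DataFrame, cgis: pd.DataFrame,
                 tf_sites: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Per-DMR feature profile: dominant group, group fractions, CGI/shore/TF flags."""
    tf_sites = tf_sites or {}
    rows = []
    for dmr in dmrs.itertuples(index=False):
        dom, fracs = dominant_state(dmr, grouped)
        cgi_frac, cgi_flag = cgi_overlap(dmr, cgis)
        rec = {
            "dmr_id": dmr.dmr_id,
            "direction": dmr.direction,
            "dominant_group": dom,
            "cgi_overlap_frac": cgi_frac,
            "cgi_flag": cgi_flag,
            "shore_flag": shore_overlap(dmr, cgis),
        }
        for g in STATE_GROUPS:
            rec[f"frac_{g}"] = fracs[g]
        for factor, flag in tf_overlap(dmr, tf_sites).items():
            rec[f"tf_{factor}"] = flag
        rows.append(rec)
    return pd.DataFrame(rows)
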