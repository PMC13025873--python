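"""Low-methylation region (LMR) segmentation within a single methylome.

LMRs are contiguous runs of lowly methylated CpGs in one sample, computed
without reference to any group comparison: per-CpG methylation fractions
are smoothed with a centred running mean, maximal runs of consecutive CpGs
at or below the threshold become LMRs, and nearby LMRs are merged. A
threshold/run-length segmentation with declared parameters, deterministic
and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, overlap_bp

__all__ = ["LMRPolicy", "segment_lmrs", "promoter_lmr_extension"]


@dataclass(frozen=True)
class LMRPolicy:
    meth_threshold: float = 0.5
    min_cpgs: int = 4
    smooth_window: int = 3   # CpGs, centred; must be odd
    merge_gap: int = 200     # bp; LMRs separated by < merge_gap are merged

    def __post_init__(self):
        if self.smooth_window % 2 != 1:
            raise ValueError("smooth_window must be odd")
        if not 0 <= self.meth_threshold <= 1:
            raise ValueError("meth_threshold must be in [0, 1]")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")


def _smooth(frac: np.ndarray, window: int) -> np.ndarray:
    # centred running mean, truncated at chromosome ends
    s = pd.Series(frac)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def segment_lmrs(sites: pd.DataFrame, policy: LMRPolicy = LMRPolicy()) -> pd.DataFrame:
    """Segment LMRs from per-CpG fractions of one sample.

    ``sites`` needs columns ``chrom, pos, frac`` (zero-coverage sites
    should already be dropped). Returns ``chrom, start, end, n_cpgs,
    mean_meth`` where ``mean_meth`` averages the smoothed fractions of
    member CpGs (hence always <= the threshold).
    """
    out = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        frac = grp["frac"].to_numpy(dtype=float)
        sm = _smooth(frac, policy.smooth_window)
        low = sm <= policy.meth_threshold
        # maximal runs of low CpGs
        runs = []
        i = 0
        n = len(pos)
        while i < n:
            if low[i]:
                j = i
                while j + 1 < n and low[j + 1]:
                    j += 1
                if j - i + 1 >= policy.min_cpgs:
                    runs.append((i, j))
                i = j + 1
            else:
                i += 1
        # merge runs whose genomic separation is < merge_gap
        merged = []
        for i0, j0 in runs:
            if merged and pos[i0] - (pos[merged[-1][1]] + 2) < policy.merge_gap:
                merged[-1] = (merged[-1][0], j0)
            else:
                merged.append((i0, j0))
        for i0, j0 in merged:
            member = np.concatenate([
                sm[a:b + 1] for (a, b) in runs if i0 <= a and b <= j0
            ])
            out.append({
                "chrom": chrom,
                "start": int(pos[i0]),
                "end": int(pos[j0]) + 2,
                "n_cpgs": int(sum(b - a + 1 for (a, b) in runs if i0 <= a and b <= j0)),
                "mean_meth": float(member.mean()),
            })
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_cpgs", "mean_meth"])


def _window_lmr_union(lmrs: pd.DataFrame, chrom: str, w_start: int, w_end: int):
    sub = lmrs[(lmrs["chrom"] == chrom) & (lmrs["end"] > w_start) & (lmrs["start"] < w_end)]
    return merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())


def promoter_lmr_extension(case_lmrs: pd.DataFrame,
                           reference_lmr_sets: list[pd.DataFrame],
                           genes: pd.DataFrame,
                           window: tuple[int, int] = (-2000, 2000),
                           min_extension: int = 500) -> pd.DataFrame:
    """Detect case-associated extensions of constitutive promoter LMRs.

    For each gene whose promoter window holds an LMR in the case sample and
    in every reference sample, the constitutive core is the intersection of
    the reference promoter LMRs; the extension is the span of the case LMR
    outside that core. Genes with no case promoter LMR are omitted; genes
    whose core is empty are reported as non-constitutive.
    """
    rows = []
    for g in genes.itertuples(index=False):
        w_start = g.tss + window[0]
        w_end = g.tss + window[1]
        cs, ce = _window_lmr_union(case_lmrs, g.chrom, w_start, w_end)
        if cs.size == 0:
            continue
        # widest case promoter LMR is the one measured
        widths = ce - cs
        k = int(np.argmax(widths))
        case_start, case_end = int(cs[k]), int(ce[k])
        # constitutive core = intersection over reference sets
        core_s, core_e = None, None
        constitutive = True
        for ref in reference_lmr_sets:
            rs, re_ = _window_lmr_union(ref, g.chrom, w_start, w_end)
            if rs.size == 0:
                constitutive = False
                break
            if core_s is None:
                core_s, core_e = rs, re_
            else:
                # intersect two disjoint unions
                out_s, out_e = [], []
                for a, b in zip(core_s, core_e):
                    for c, d in zip(rs, re_):
                        lo, hi = max(a, c), min(b, d)
                        if lo < hi:
                            out_s.append(lo)
                            out_e.append(hi)
                core_s = np.array(out_s, dtype=np.int64)
                core_e = np.array(out_e, dtype=np.int64)
                if core_s.size == 0:
                    constitutive = False
                    break
        if not constitutive or core_s is None or core_s.size == 0:
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom,
                "case_start": case_start, "case_end": case_end,
                "core_start": -1, "core_end": -1,
                "constitutive": False, "extension_bp": 0, "extended": False,
            })
            continue
        inside = overlap_bp(case_start, case_end, core_s, core_e)
        extension = (case_end - case_start) - inside
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom,
            "case_start": case_start, "case_end": case_end,
            "core_start": int(core_s[0]), "core_end": int(core_e[-1]),
            "constitutive": True,
            "extension_bp": int(extension),
            "extended": bool(extension >= min_extension),
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "case_start", "case_end", "core_start", "core_end",
        "constitutive", "extension_bp", "extended"])
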