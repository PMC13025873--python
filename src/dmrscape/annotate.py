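"""Exclusive DMR-to-gene assignment with precedence-ordered region categories.

Every DMR is assigned to exactly one gene and one region category. The
categories, in order of precedence, are the promoter core (TSS -2 kb to
+0.5 kb), promoter downstream (TSS +0.5 to +2 kb), far upstream (TSS -5 to
-2 kb), intragenic (TSS +2 kb to TES), gene downstream (TES to TES +2 kb),
and intergenic. All windows are strand-aware: distances are measured along
the direction of transcription, so "downstream of the TSS" means lower
genomic coordinates for minus-strand genes.

Candidate genes are those with any window overlapping the DMR by >= 1 bp;
coding genes are preferred over non-coding, then the gene whose TSS is
nearest the DMR midpoint wins (ties broken lexicographically by gene id).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REGION_ORDER",
    "region_windows",
    "assign_dmr_to_gene",
    "assign_dmrs",
    "tss_window_fraction",
]

REGION_ORDER = ["prom_core", "prom_down", "prom_up", "intragenic", "downstream"]

# (category, start, end) in transcription coordinates relative to the TSS;
# None marks the TES.
_TX_WINDOWS = [
    ("prom_core", -2000, 500),
    ("prom_down", 500, 2000),
    ("prom_up", -5000, -2000),
    ("intragenic", 2000, None),
    ("downstream", None, 2000),
]


def region_windows(gene) -> list[tuple[str, tuple[int, int]]]:
    """Genomic (category, [start, end)) windows for one gene, precedence order.

    ``gene`` is any object with ``strand, tss, tes`` attributes. Windows
    that are empty for short genes (TES before TSS + 2 kb) are dropped;
    windows are clipped at coordinate 0.
    """
    tss, tes, strand = int(gene.tss), int(gene.tes), gene.strand
    length = abs(tes - tss)
    out = []
    for cat, a, b in _TX_WINDOWS:
        if cat == "intragenic":
            a, b = 2000, length
        elif cat == "downstream":
            a, b = length, length + 2000
        if b <= a:
            continue
        if strand == "+":
            g_start, g_end = tss + a, tss + b
        else:
            g_start, g_end = tss - b, tss - a
        g_start = max(g_start, 0)
        if g_start < g_end:
            out.append((cat, (g_start, g_end)))
    return out


def _tss_distance(mid: float, gene) -> float:
    """Signed transcription-direction distance of a point from the TSS."""
    if gene.strand == "+":
        return mid - gene.tss
    return gene.tss - mid


def _collapse_isoforms(genes: pd.DataFrame, mid: float) -> pd.DataFrame:
    """Keep, per gene_id, the isoform whose TSS is nearest the DMR midpoint."""
    if genes["gene_id"].is_unique:
        return genes
    idx = (genes.assign(_d=(genes["tss"] - mid).abs())
           .sort_values(["_d", "tss"], kind="stable")
           .drop_duplicates("gene_id"))
    return idx.drop(columns="_d")


def assign_dmr_to_gene(dmr, genes: pd.DataFrame) -> dict:
    """Assign one DMR (object with chrom/start/end) to a gene and category."""
    mid = (int(dmr.start) + int(dmr.end)) / 2.0
    if genes.empty:
        return {"gene_id": None, "region": "intergenic", "tss_distance": np.nan}
    chrom_genes = genes[genes["chrom"] == dmr.chrom]
    chrom_genes = _collapse_isoforms(chrom_genes, mid)
    candidates = []
    for g in chrom_genes.itertuples(index=False):
        windows = region_windows(g)
        hit = None
        for cat, (ws, we) in windows:
            if ws < dmr.end and dmr.start < we:
                hit = cat
                break
        if hit is not None:
            candidates.append((g, hit))
    if candidates:
        coding = [c for c in candidates if c[0].is_coding]
        pool = coding if coding else candidates
        pool.sort(key=lambda c: (abs(mid - c[0].tss), c[0].gene_id))
        gene, region = pool[0]
        return {
            "gene_id": gene.gene_id,
            "region": region,
            "tss_distance": float(_tss_distance(mid, gene)),
        }
    # intergenic: nearest gene by |midpoint - TSS|
    if chrom_genes.empty:
        chrom_genes = _collapse_isoforms(genes, mid)
    if chrom_genes.empty:
        return {"gene_id": None, "region": "intergenic", "tss_distance": np.nan}
    ordered = sorted(chrom_genes.itertuples(index=False),
                     key=lambda g: (abs(mid - g.tss), g.gene_id))
    gene = ordered[0]
    return {
        "gene_id": gene.gene_id,
        "region": "intergenic",
        "tss_distance": float(_tss_distance(mid, gene)),
    }


def assign_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign every DMR; returns dmr_id, gene_id, region, tss_distance."""
    rows = []
    for dmr in dmrs.itertuples(index=False):
        rec = assign_dmr_to_gene(dmr, genes)
        rec["dmr_id"] = dmr.dmr_id
        rows.append(rec)
    return pd.DataFrame(rows, columns=["dmr_id", "gene_id", "region", "tss_distance"])


def tss_window_fraction(assignments: pd.DataFrame, dmrs: pd.DataFrame,
                        genes: pd.DataFrame, half_width: int = 2000) -> float:
    """Fraction of DMRs overlapping [TSS - hw, TSS + hw) of their assigned gene."""
    if dmrs.empty:
        return float("nan")
    gene_by_id = {}
    for g in genes.itertuples(index=False):
        # first isoform per id is representative here; callers with isoform
        # tables should pre-collapse
        gene_by_id.setdefault(g.gene_id, g)
    merged = dmrs.merge(assignments, on="dmr_id", how="left")
    n_hit = 0
    for row in merged.itertuples(index=False):
        g = gene_by_id.get(row.gene_id)
        if g is None:
            continue
        w_start, w_end = g.tss - half_width, g.tss + half_width
        if w_start < row.end and row.start < w_end:
            n_hit += 1
    return n_hit / len(dmrs)
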