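"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval helpers: everything is
computed per base over explicit numpy masks, or by exhaustive enumeration,
so they can disagree with the implementation if it is wrong.
"""

import numpy as np


def paint_mask(length, intervals):
    """Boolean per-base mask for a list of (start, end) half-open intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0):max(e, 0)] = True
    return mask


def per_base_group_counts(length, segments):
    """Per-base chromatin group labels ('' where uncovered)."""
    labels = np.full(length, "", dtype=object)
    for s, e, group in segments:
        labels[max(s, 0):e] = group
    return labels


def brute_dominant(dmr_start, dmr_end, labels, tie_order):
    window = labels[dmr_start:dmr_end]
    counts = {g: 0 for g in tie_order}
    for base in window:
        counts[base if base else "Low"] += 1
    best = None
    for g in tie_order:
        if best is None or counts[g] > counts[best]:
            best = g
    return best, {g: counts[g] / (dmr_end - dmr_start) for g in counts}


def brute_cgi_fraction(dmr_start, dmr_end, cgi_intervals, length):
    mask = paint_mask(length, cgi_intervals)
    bp = int(mask[dmr_start:dmr_end].sum())
    return bp / (dmr_end - dmr_start)


def brute_shore_mask(cgi_intervals, length, width=2000):
    cgi = paint_mask(length, cgi_intervals)
    flank = paint_mask(length, [(s - width, s) for s, _ in cgi_intervals]
                       + [(e, e + width) for _, e in cgi_intervals])
    return flank & ~cgi


def brute_assign(dmr_start, dmr_end, genes, region_windows_fn):
    """Exhaustive gene-assignment oracle: enumerate every (gene, window) pair."""
    mid = (dmr_start + dmr_end) / 2.0
    candidates = []
    for g in genes:
        for cat, (ws, we) in region_windows_fn(g):
            if ws < dmr_end and dmr_start < we:
                candidates.append(g)
                break
    if candidates:
        coding = [g for g in candidates if g.is_coding]
        pool = coding if coding else candidates
        pool = sorted(pool, key=lambda g: (abs(mid - g.tss), g.gene_id))
        winner = pool[0]
        for cat, (ws, we) in region_windows_fn(winner):
            if ws < dmr_end and dmr_start < we:
                return winner.gene_id, cat
    if not genes:
        return None, "intergenic"
    nearest = sorted(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))[0]
    return nearest.gene_id, "intergenic"


def bh_oracle(p):
    """Hand-rolled BH step-up: p * m / rank with a trailing cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(p[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def fisher_two_sided_oracle(k1, n1, k2, n2):
    """Exhaustive two-sided Fisher p: sum hypergeometric masses <= observed mass."""
    from math import comb
    total_k = k1 + k2
    n = n1 + n2
    denom = comb(n, total_k)
    def mass(x):
        if x < 0 or x > n1 or total_k - x > n2 or total_k - x < 0:
            return 0.0
        return comb(n1, x) * comb(n2, total_k - x) / denom
    observed = mass(k1)
    return sum(mass(x) for x in range(0, total_k + 1)
               if mass(x) <= observed * (1 + 1e-12))
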