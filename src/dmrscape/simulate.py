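"""Fully consistent synthetic dataset with a machine-readable ground truth.

The generator emulates the statistical structure the differential-
methylation analysis assumes: a small set of case methylomes (default 3)
against a larger heterologous reference panel (default 6), per-CpG counts
drawn beta-binomially around baseline methylation that is high in bulk
genome (0.85) and low at CpG islands (0.05), with CpG density increased
eightfold inside islands. Differential regions of known coordinates and
effect size are planted: hypomethylated DMRs shift the case methylation
down from the high background; hypermethylated DMRs sit on constitutively
low-methylation footprints (island-like, as at 3'-CGI and shore
hypermethylation in real data) and shift the case methylation up. Gene
models, a CpG-island track, an 18-state chromatin track, TF-occupancy
sites and an expression matrix are generated jointly so every pipeline
stage has consistent inputs, and every planted feature is recorded in a
truth table.

All outputs are pure functions of :class:`SyntheticConfig` (seeded
generators per stage, no wall-clock dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._intervals import merge_intervals, subtract_intervals
from .io import MethylomeMatrix, SampleMeta

__all__ = [
    "SyntheticConfig",
    "Annotation",
    "SyntheticTruth",
    "simulate_annotation",
    "simulate_methylomes",
    "simulate_expression",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 2_000_000),)
    # methylome design
    n_case: int = 3
    n_ref: int = 6
    mean_coverage: float = 20.0
    cpg_spacing: float = 80.0       # mean bp between CpGs (geometric)
    cgi_density_factor: float = 8.0  # CpG density multiplier inside CGIs
    baseline_meth_background: float = 0.85
    baseline_meth_cgi: float = 0.05
    dispersion: float = 0.05        # beta-binomial rho across samples
    # planted differential regions
    n_planted_hypo: int = 0
    n_planted_hyper: int = 0
    planted_delta: float = 0.4
    planted_width: tuple[int, int] = (1000, 3000)
    # fraction of hypo DMRs anchored just upstream of preferential-gene
    # promoters (at most one per preferential gene), so the expression and
    # annotation stages see gene-linked differential methylation
    p_dmr_near_gene: float = 0.3
    # annotation layout
    n_genes: int = 40
    p_cgi: float = 0.4              # probability of a promoter CGI per gene
    p_coding: float = 0.85
    gene_length: tuple[int, int] = (5000, 15000)
    gene_gap: tuple[int, int] = (20000, 30000)
    tf_fraction: float = 0.6        # fraction of hypo DMRs with a MYOD site
    n_ctcf: int = 30
    # expression design
    n_preferential: int = 8
    n_heterologous_ref: int = 5
    n_tissue_panel: int = 54
    pref_case_level: float = 120.0
    background_level: float = 15.0
    expression_sigma: float = 0.4

    def __post_init__(self):
        if not 0 < self.planted_delta <= 1:
            raise ValueError("planted_delta must be in (0, 1]")
        for p in (self.baseline_meth_background, self.baseline_meth_cgi):
            if not 0 <= p <= 1:
                raise ValueError("baselines must be in [0, 1]")
        if self.baseline_meth_background - self.planted_delta < 0 and self.n_planted_hypo:
            raise ValueError("hypo delta would push methylation below 0")
        if self.baseline_meth_cgi + self.planted_delta > 1 and self.n_planted_hyper:
            raise ValueError("hyper delta would push methylation above 1")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must be in [0, 1)")


@dataclass
class Annotation:
    genes: pd.DataFrame
    cgis: pd.DataFrame
    chromatin: pd.DataFrame          # chrom, start, end, state (1..18)
    tf_sites: dict[str, pd.DataFrame]
    planted_dmrs: pd.DataFrame       # chrom, start, end, direction, delta
    pref_genes: list[str] = field(default_factory=list)
    tissue_pref_genes: list[str] = field(default_factory=list)
    downmod_genes: list[str] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    planted_dmrs: pd.DataFrame
    pref_genes: list[str]
    tissue_pref_genes: list[str]
    downmod_genes: list[str]
    cgis: pd.DataFrame


def _place_genes(config: SyntheticConfig, rng: np.random.Generator):
    genes, cgis = [], []
    gid = 0
    for chrom, length in config.genome:
        cursor = 10_000
        share = config.n_genes * length / sum(l for _, l in config.genome)
        n_here = int(round(share))
        for _ in range(n_here):
            glen = int(rng.uniform(*config.gene_length))
            if cursor + glen + 7_000 > length:
                raise ValueError("genome too small for requested gene layout")
            strand = "+" if rng.random() < 0.5 else "-"
            tx_start, tx_end = cursor, cursor + glen
            tss = tx_start if strand == "+" else tx_end
            gid += 1
            genes.append({
                "gene_id": f"G{gid:04d}", "name": f"GENE{gid:04d}",
                "chrom": chrom, "strand": strand,
                "tx_start": tx_start, "tx_end": tx_end,
                "tss": tss, "tes": tx_end if strand == "+" else tx_start,
                "is_coding": bool(rng.random() < config.p_coding),
            })
            if rng.random() < config.p_cgi:
                cgis.append({"chrom": chrom, "start": max(tss - 500, 0),
                             "end": tss + 500, "name": f"CGI_{gid:04d}"})
            cursor = tx_end + int(rng.uniform(*config.gene_gap))
    gene_cols = ["gene_id", "name", "chrom", "strand", "tx_start", "tx_end",
                 "tss", "tes", "is_coding"]
    genes_df = pd.DataFrame(genes, columns=gene_cols)
    cgis_df = pd.DataFrame(cgis, columns=["chrom", "start", "end", "name"])
    return genes_df, cgis_df


def _place_planted(config: SyntheticConfig, genes: pd.DataFrame,
                   cgis: pd.DataFrame, pref_genes: list[str],
                   rng: np.random.Generator) -> pd.DataFrame:
    n_total = config.n_planted_hypo + config.n_planted_hyper
    if n_total == 0:
        return pd.DataFrame(columns=["truth_id", "chrom", "start", "end",
                                     "direction", "delta"])
    rows = []
    # anchor a share of the hypo DMRs just upstream of preferential-gene
    # promoters (clear of the promoter CGI, inside the TSS -2 kb window)
    n_near = min(int(round(config.p_dmr_near_gene * config.n_planted_hypo)),
                 len(pref_genes))
    near = genes[genes["gene_id"].isin(pref_genes[:n_near])]
    for g in near.itertuples(index=False):
        w = int(rng.integers(*config.planted_width))
        if g.strand == "+":
            start, end = g.tss - 600 - w, g.tss - 600
        else:
            start, end = g.tss + 600, g.tss + 600 + w
        rows.append({"chrom": g.chrom, "start": int(start), "end": int(end),
                     "direction": "hypo", "delta": config.planted_delta})
    n_rest = n_total - len(rows)
    directions = np.array(["hypo"] * (config.n_planted_hypo - len(rows))
                          + ["hyper"] * config.n_planted_hyper)
    rng.shuffle(directions)
    widths = rng.integers(config.planted_width[0], config.planted_width[1] + 1,
                          size=n_rest)
    i = 0
    for chrom, length in config.genome:
        # free space: genome minus genes +/- 5 kb and CGIs +/- 2 kb
        occ_s, occ_e = [], []
        for g in genes[genes["chrom"] == chrom].itertuples(index=False):
            occ_s.append(max(g.tx_start - 5000, 0))
            occ_e.append(g.tx_end + 5000)
        for c in cgis[cgis["chrom"] == chrom].itertuples(index=False):
            occ_s.append(max(c.start - 2000, 0))
            occ_e.append(c.end + 2000)
        free_s, free_e = subtract_intervals(
            np.array([1000], dtype=np.int64),
            np.array([length - 1000], dtype=np.int64),
            np.array(occ_s, dtype=np.int64), np.array(occ_e, dtype=np.int64))
        for fs, fe in zip(free_s, free_e):
            cur = int(fs)
            while i < n_rest and cur + widths[i] + 1000 <= fe:
                rows.append({"chrom": chrom, "start": cur,
                             "end": cur + int(widths[i]),
                             "direction": directions[i],
                             "delta": config.planted_delta})
                cur += int(widths[i]) + 1000
                i += 1
            if i == n_rest:
                break
        if i == n_rest:
            break
    if i < n_rest:
        raise ValueError("genome too small for requested planted DMRs")
    df = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    df.insert(0, "truth_id", [f"T{k + 1:04d}" for k in range(len(df))])
    return df.reset_index(drop=True)


def _paint_chromatin(config: SyntheticConfig, genes: pd.DataFrame,
                     planted: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    segments = []
    for chrom, length in config.genome:
        layers = []  # (start, end, state), earlier = higher priority
        for g in genes[genes["chrom"] == chrom].itertuples(index=False):
            expressed = rng.random() < 0.7
            prom_state = 1 if expressed else 2
            layers.append((max(g.tss - 1000, 0), g.tss + 1000, prom_state))
            if expressed:
                lo, hi = sorted((g.tss, g.tes))
                body_lo = lo + 2000 if g.strand == "+" else lo
                body_hi = hi if g.strand == "+" else hi - 2000
                if body_lo < body_hi:
                    layers.append((body_lo, body_hi, 5))
        for d in planted[(planted["chrom"] == chrom)
                         & (planted["direction"] == "hypo")].itertuples(index=False):
            if rng.random() < 0.5:
                layers.append((d.start, d.end, 9))
        for _ in range(5):
            s = int(rng.integers(0, max(length - 5000, 1)))
            layers.append((s, s + 5000, 13))
        # resolve overlaps: earlier layers win
        occ_s = np.array([], dtype=np.int64)
        occ_e = np.array([], dtype=np.int64)
        painted = []
        for s, e, state in layers:
            ns, ne = subtract_intervals(np.array([s]), np.array([e]), occ_s, occ_e)
            for a, b in zip(ns, ne):
                painted.append((int(a), int(b), state))
            occ_s, occ_e = merge_intervals(np.concatenate([occ_s, ns]),
                                           np.concatenate([occ_e, ne]))
        # fill the rest with Low signal (state 18)
        gap_s, gap_e = subtract_intervals(np.array([0]), np.array([length]),
                                          occ_s, occ_e)
        for a, b in zip(gap_s, gap_e):
            painted.append((int(a), int(b), 18))
        painted.sort()
        segments.extend({"chrom": chrom, "start": s, "end": e, "state": st}
                        for s, e, st in painted)
    return pd.DataFrame(segments, columns=["chrom", "start", "end", "state"])


def _place_tf(config: SyntheticConfig, planted: pd.DataFrame,
              rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    myod = []
    for d in planted[planted["direction"] == "hypo"].itertuples(index=False):
        if rng.random() < config.tf_fraction:
            mid = (d.start + d.end) // 2
            myod.append({"chrom": d.chrom, "start": mid - 100, "end": mid + 100,
                         "name": f"MYOD_{len(myod) + 1}"})
    ctcf = []
    for chrom, length in config.genome:
        for _ in range(config.n_ctcf):
            s = int(rng.integers(1000, length - 1000))
            ctcf.append({"chrom": chrom, "start": s, "end": s + 200,
                         "name": f"CTCF_{len(ctcf) + 1}"})
    cols = ["chrom", "start", "end", "name"]
    return {
        "MYOD": pd.DataFrame(myod, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True),
        "CTCF": pd.DataFrame(ctcf, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True),
    }


def simulate_annotation(config: SyntheticConfig) -> Annotation:
    """Generate genes, CGIs, chromatin, TF sites and planted-DMR coordinates."""
    rng = np.random.default_rng([config.seed, 1])
    genes, cgis = _place_genes(config, rng)
    coding = genes[genes["is_coding"]]["gene_id"].tolist() if len(genes) else []
    n_pref = min(config.n_preferential, len(coding))
    pref = sorted(rng.choice(coding, size=n_pref, replace=False)) if n_pref else []
    tissue_pref = pref[: (len(pref) + 1) // 2]
    downmod = tissue_pref[: max(len(tissue_pref) // 2, 1)] if tissue_pref else []
    planted = _place_planted(config, genes, cgis, pref, rng)
    chromatin = _paint_chromatin(config, genes, planted, rng)
    tf_sites = _place_tf(config, planted, rng)
    return Annotation(genes=genes, cgis=cgis, chromatin=chromatin,
                      tf_sites=tf_sites, planted_dmrs=planted,
                      pref_genes=list(pref), tissue_pref_genes=list(tissue_pref),
                      downmod_genes=list(downmod))


def _cpg_positions(config: SyntheticConfig, chrom: str, length: int,
                   cgis: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    # background walk
    spacing = config.cpg_spacing
    n_approx = int(length / spacing * 1.3) + 10
    steps = rng.geometric(1.0 / spacing, size=n_approx)
    pos = 2 + np.cumsum(steps)
    pos = pos[pos < length - 2]
    sub = cgis[cgis["chrom"] == chrom]
    if len(sub):
        cs, ce = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        # drop background positions inside CGIs, then densify islands
        inside = np.zeros(pos.shape, dtype=bool)
        for a, b in zip(cs, ce):
            inside |= (pos >= a) & (pos < b)
        pos = pos[~inside]
        dense_spacing = max(spacing / config.cgi_density_factor, 2.0)
        extra = []
        for a, b in zip(cs, ce):
            p = int(a)
            while p < b - 2:
                extra.append(p)
                p += int(rng.geometric(1.0 / dense_spacing))
            extra.append(int(b) - 2)  # anchor the island's far edge
        pos = np.concatenate([pos, np.array(extra, dtype=np.int64)])
    return np.unique(pos.astype(np.int64))


def _truth_profile(config: SyntheticConfig, chrom: str, pos: np.ndarray,
                   cgis: pd.DataFrame, planted: pd.DataFrame):
    """Per-site baseline and per-site case shift for one chromosome."""
    base = np.full(pos.shape, config.baseline_meth_background)
    for c in cgis[cgis["chrom"] == chrom].itertuples(index=False):
        base[(pos >= c.start) & (pos < c.end)] = config.baseline_meth_cgi
    shift = np.zeros(pos.shape)
    for d in planted[planted["chrom"] == chrom].itertuples(index=False):
        m = (pos >= d.start) & (pos < d.end)
        if d.direction == "hyper":
            # hyper footprints are constitutively low-methylation regions
            base[m] = config.baseline_meth_cgi
            shift[m] = d.delta
        else:
            shift[m] = -d.delta
    return base, shift


def simulate_methylomes(config: SyntheticConfig,
                        annotation: Annotation) -> tuple[MethylomeMatrix, SyntheticTruth]:
    """Draw beta-binomial counts for every sample at every simulated CpG."""
    rng = np.random.default_rng([config.seed, 2])
    samples = ([SampleMeta(f"case_{i + 1}", "case") for i in range(config.n_case)]
               + [SampleMeta(f"ref_{i + 1}", "reference") for i in range(config.n_ref)])
    chroms, poss, bases, shifts = [], [], [], []
    for chrom, length in config.genome:
        pos = _cpg_positions(config, chrom, length, annotation.cgis, rng)
        base, shift = _truth_profile(config, chrom, pos, annotation.cgis,
                                     annotation.planted_dmrs)
        chroms.append(np.full(pos.shape, chrom, dtype=object))
        poss.append(pos)
        bases.append(base)
        shifts.append(shift)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(poss)
    base_arr = np.concatenate(bases)
    shift_arr = np.concatenate(shifts)
    n_sites = pos_arr.size
    n_samples = len(samples)
    p_target = np.repeat(base_arr[:, None], n_samples, axis=1)
    p_target[:, : config.n_case] += shift_arr[:, None]
    p_target = np.clip(p_target, 0.01, 0.99)
    total = rng.poisson(config.mean_coverage, size=(n_sites, n_samples))
    rho = config.dispersion
    if rho > 0:
        a = p_target * (1 - rho) / rho
        b = (1 - p_target) * (1 - rho) / rho
        p_sample = rng.beta(a, b)
    else:
        p_sample = p_target
    meth = rng.binomial(total, p_sample)
    matrix = MethylomeMatrix(chrom_arr, pos_arr, meth, total, samples)
    truth = SyntheticTruth(
        planted_dmrs=annotation.planted_dmrs.copy(),
        pref_genes=list(annotation.pref_genes),
        tissue_pref_genes=list(annotation.tissue_pref_genes),
        downmod_genes=list(annotation.downmod_genes),
        cgis=annotation.cgis.copy(),
    )
    return matrix, truth


def simulate_expression(config: SyntheticConfig, annotation: Annotation) -> pd.DataFrame:
    """Expression matrix: case FPKM, heterologous refs, tissue TPM and panel.

    Planted case-preferential genes get high case levels with near-silent
    references; tissue-preferential genes additionally get a strong tissue
    value over a quiet panel; downmodulated genes get a tissue value far
    above their case level. Background genes fluctuate log-normally around
    a common level in every column.
    """
    rng = np.random.default_rng([config.seed, 3])
    genes = annotation.genes["gene_id"].tolist()
    n = len(genes)
    sig = config.expression_sigma
    pref = set(annotation.pref_genes)
    tpref = set(annotation.tissue_pref_genes)
    downmod = set(annotation.downmod_genes)

    def logn(mean, size):
        return np.exp(np.log(mean) + sig * rng.standard_normal(size))

    bg = config.background_level
    case = logn(bg, n)
    refs = logn(bg, (n, config.n_heterologous_ref))
    skm = logn(bg, n)
    panel = logn(bg, (n, config.n_tissue_panel))
    for i, g in enumerate(genes):
        if g in pref:
            case[i] = logn(config.pref_case_level, 1)[0]
            refs[i] = logn(0.3, config.n_heterologous_ref)
        if g in tpref:
            skm[i] = logn(300.0, 1)[0]
            panel[i] = logn(1.0, config.n_tissue_panel)
        if g in downmod:
            case[i] = logn(40.0, 1)[0]
            skm[i] = logn(1200.0, 1)[0]
    data = {"gene_id": genes, "case_fpkm": case}
    for j in range(config.n_heterologous_ref):
        data[f"ref{j + 1}_fpkm"] = refs[:, j]
    data["tissue_tpm"] = skm
    for j in range(config.n_tissue_panel):
        data[f"panel{j + 1:02d}_tpm"] = panel[:, j]
    return pd.DataFrame(data)


def _split_strands(meth: np.ndarray, total: np.ndarray, rng: np.random.Generator):
    """Partition dyad counts into plus/minus strand observations."""
    m_plus = rng.binomial(meth, 0.5)
    u_plus = rng.binomial(total - meth, 0.5)
    return m_plus, m_plus + u_plus


def write_fixture_bundle(config: SyntheticConfig, out_dir, force: bool = False) -> Path:
    """Run all simulators and write a complete on-disk input bundle.

    Coverage tables are written in the 5-column strand dialect with dyad
    counts split across the two strands, so ingestion exercises strand
    merging. A truth TSV and the echoed config accompany the data.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    matrix, truth = simulate_methylomes(config, annotation)
    expression = simulate_expression(config, annotation)
    rng = np.random.default_rng([config.seed, 4])

    sample_rows = []
    for j, s in enumerate(matrix.samples):
        m_plus, t_plus = _split_strands(matrix.meth[:, j], matrix.total[:, j], rng)
        m_minus = matrix.meth[:, j] - m_plus
        t_minus = matrix.total[:, j] - t_plus
        fname = f"{s.sample_id}.cov.tsv"
        with open(out / fname, "w") as fh:
            for i in range(matrix.n_sites):
                c, p = matrix.chrom[i], matrix.pos[i]
                if t_plus[i] > 0:
                    fh.write(f"{c}\t{p}\t+\t{m_plus[i]}\t{t_plus[i] - m_plus[i]}\n")
                if t_minus[i] > 0:
                    fh.write(f"{c}\t{p + 1}\t-\t{m_minus[i]}\t{t_minus[i] - m_minus[i]}\n")
        sample_rows.append({"sample_id": s.sample_id, "group": s.group,
                            "file": fname})
    pd.DataFrame(sample_rows).to_csv(out / "samples.tsv", sep="\t", index=False)

    annotation.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    annotation.cgis.to_csv(out / "cgi.bed", sep="\t", index=False, header=False)
    annotation.chromatin.to_csv(out / "chromatin.bed", sep="\t", index=False,
                                header=False)
    for factor, sites in annotation.tf_sites.items():
        sites.to_csv(out / f"tf_{factor}.bed", sep="\t", index=False, header=False)
    expression.to_csv(out / "expression.tsv", sep="\t", index=False,
                      float_format="%.6g")
    roles = [{"column": "case_fpkm", "role": "case"}]
    roles += [{"column": f"ref{j + 1}_fpkm", "role": "heterologous_ref"}
              for j in range(config.n_heterologous_ref)]
    roles += [{"column": "tissue_tpm", "role": "tissue"}]
    roles += [{"column": f"panel{j + 1:02d}_tpm", "role": "tissue_panel"}
              for j in range(config.n_tissue_panel)]
    pd.DataFrame(roles).to_csv(out / "expression_roles.tsv", sep="\t", index=False)

    truth.planted_dmrs.to_csv(out / "truth_dmrs.tsv", sep="\t", index=False)
    pd.DataFrame({
        "gene_id": truth.pref_genes,
        "tissue_pref": [g in truth.tissue_pref_genes for g in truth.pref_genes],
        "downmodulated": [g in truth.downmod_genes for g in truth.pref_genes],
    }).to_csv(out / "truth_genes.tsv", sep="\t", index=False)

    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in config.__dict__.items()}
    cfg["genome"] = [[c, int(l)] for c, l in config.genome]
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out
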