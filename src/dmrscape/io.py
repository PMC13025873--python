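"""Reading and writing per-CpG count tables, interval files and gene models.

Internal coordinate convention is 0-based, half-open everywhere. 1-based
on-disk dialects (Bismark coverage) are converted at the boundary. A CpG
dyad is keyed by the position of the C on the plus strand; the paired
minus-strand C sits at ``pos + 1``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGCountRecord",
    "SampleMeta",
    "MethylomeMatrix",
    "read_coverage_table",
    "merge_strands",
    "pool_technical_replicates",
    "read_bed_intervals",
    "read_gene_models",
    "build_matrix",
]

COVERAGE_DIALECTS = ("bismark", "strand")


@dataclass(frozen=True)
class CpGCountRecord:
    """Raw per-site methylation counts for one sample.

    ``pos`` is the 0-based position of the cytosine on the plus strand
    (for minus-strand records, the position of the minus-strand C itself,
    before strand merging re-keys it onto the dyad's plus position).
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_total: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.n_meth < 0 or self.n_total < self.n_meth:
            raise ValueError(
                f"invalid counts n_meth={self.n_meth}, n_total={self.n_total}"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str  # "case" | "reference"
    replicate_of: str | None = None

    def __post_init__(self):
        if self.group not in ("case", "reference"):
            raise ValueError(f"invalid group {self.group!r}")


@dataclass
class MethylomeMatrix:
    """Per-CpG (methylated, total) counts across named samples.

    ``chrom``/``pos`` give the sorted unique site list; ``meth`` and
    ``total`` are ``(n_sites, n_samples)`` integer arrays, column order
    matching ``samples``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        n_sites, n_samples = self.meth.shape
        if self.total.shape != (n_sites, n_samples):
            raise ValueError("meth/total shape mismatch")
        if len(self.samples) != n_samples:
            raise ValueError("sample metadata does not match column count")
        if (self.meth < 0).any() or (self.meth > self.total).any():
            raise ValueError("counts must satisfy 0 <= n_meth <= n_total")

    @property
    def n_sites(self) -> int:
        return self.meth.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.group == group])

    def to_frame(self) -> pd.DataFrame:
        data = {"chrom": self.chrom, "pos": self.pos}
        for j, s in enumerate(self.samples):
            data[f"{s.sample_id}.meth"] = self.meth[:, j]
            data[f"{s.sample_id}.total"] = self.total[:, j]
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, samples: Sequence[SampleMeta]) -> "MethylomeMatrix":
        df = pd.read_csv(path, sep="\t")
        meth = np.column_stack([df[f"{s.sample_id}.meth"] for s in samples])
        total = np.column_stack([df[f"{s.sample_id}.total"] for s in samples])
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(), meth, total,
                   list(samples))


def _parse_line(fields: list[str], dialect: str, lineno: int) -> CpGCountRecord:
    try:
        if dialect == "bismark":
            # chrom, start(1-based), end, meth%, count_meth, count_unmeth
            chrom = fields[0]
            pos = int(fields[1]) - 1
            n_meth = int(fields[4])
            n_unmeth = int(fields[5])
            strand = "+"
        else:  # "strand": chrom, pos(0-based), strand, count_meth, count_unmeth
            chrom = fields[0]
            pos = int(fields[1])
            strand = fields[2]
            n_meth = int(fields[3])
            n_unmeth = int(fields[4])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed coverage line {lineno}: {fields!r}") from exc
    if n_meth < 0 or n_unmeth < 0:
        raise ValueError(f"negative count on line {lineno}")
    return CpGCountRecord(chrom, pos, strand, n_meth, n_meth + n_unmeth)


def read_coverage_table(path, sample_id: str, dialect: str = "bismark") -> list[CpGCountRecord]:
    """Read a per-CpG coverage table into sorted :class:`CpGCountRecord` s.

    Dialects: ``bismark`` — the 6-column Bismark coverage output (1-based
    positions, percent column ignored); ``strand`` — 5 columns
    ``chrom pos strand n_meth n_unmeth`` with 0-based positions.
    """
    if dialect not in COVERAGE_DIALECTS:
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            records.append(_parse_line(line.split(), dialect, lineno))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def merge_strands(records: Iterable[CpGCountRecord]) -> list[CpGCountRecord]:
    """Sum CpG-dyad counts onto the plus-strand position.

    A minus-strand record at ``p`` belongs to the dyad keyed at ``p - 1``;
    unpaired sites are kept (re-keyed for minus strand). Idempotent, and
    conserves total methylated and total read counts.
    """
    agg: dict[tuple[str, int], list[int]] = {}
    for r in records:
        key_pos = r.pos - 1 if r.strand == "-" else r.pos
        if key_pos < 0:
            key_pos = 0
        key = (r.chrom, key_pos)
        if key in agg:
            agg[key][0] += r.n_meth
            agg[key][1] += r.n_total
        else:
            agg[key] = [r.n_meth, r.n_total]
    return [
        CpGCountRecord(chrom, pos, "+", m, t)
        for (chrom, pos), (m, t) in sorted(agg.items())
    ]


def build_matrix(per_sample_records: dict[str, list[CpGCountRecord]],
                 samples: Sequence[SampleMeta]) -> MethylomeMatrix:
    """Align per-sample record lists on the union of sites (missing -> 0/0)."""
    ids = [s.sample_id for s in samples]
    missing = set(per_sample_records) - set(ids)
    if missing:
        raise ValueError(f"records for unknown samples: {sorted(missing)}")
    site_set: set[tuple[str, int]] = set()
    for recs in per_sample_records.values():
        site_set.update((r.chrom, r.pos) for r in recs)
    sites = sorted(site_set)
    index = {site: i for i, site in enumerate(sites)}
    n = len(sites)
    meth = np.zeros((n, len(ids)), dtype=np.int64)
    total = np.zeros((n, len(ids)), dtype=np.int64)
    for j, sid in enumerate(ids):
        for r in per_sample_records.get(sid, []):
            i = index[(r.chrom, r.pos)]
            meth[i, j] += r.n_meth
            total[i, j] += r.n_total
    chrom = np.array([s[0] for s in sites], dtype=object)
    pos = np.array([s[1] for s in sites], dtype=np.int64)
    return MethylomeMatrix(chrom, pos, meth, total, list(samples))


def _root_parent(sample_id: str, parent_of: dict[str, str]) -> str:
    seen = {sample_id}
    cur = sample_id
    while cur in parent_of:
        cur = parent_of[cur]
        if cur in seen:
            raise ValueError(f"replicate cycle involving {sample_id!r}")
        seen.add(cur)
    return cur


def pool_technical_replicates(matrix: MethylomeMatrix) -> MethylomeMatrix:
    """Sum technical-replicate counts per site into their root parent sample.

    Replicate-of-replicate chains collapse to the root. Counts are
    conserved; samples with no replicate links pass through unchanged.
    """
    parent_of = {
        s.sample_id: s.replicate_of for s in matrix.samples if s.replicate_of
    }
    if not parent_of:
        return matrix
    known = set(matrix.sample_ids)
    unknown = set(parent_of.values()) - known
    if unknown:
        raise ValueError(f"replicate_of points to unknown samples: {sorted(unknown)}")
    roots = {sid: _root_parent(sid, parent_of) for sid in matrix.sample_ids}
    kept = [s for s in matrix.samples if s.sample_id not in parent_of]
    kept_ids = [s.sample_id for s in kept]
    meth = np.zeros((matrix.n_sites, len(kept)), dtype=np.int64)
    total = np.zeros_like(meth)
    col = {sid: j for j, sid in enumerate(kept_ids)}
    for j_src, sid in enumerate(matrix.sample_ids):
        j_dst = col[roots[sid]]
        meth[:, j_dst] += matrix.meth[:, j_src]
        total[:, j_dst] += matrix.total[:, j_src]
    kept = [replace(s, replicate_of=None) for s in kept]
    return MethylomeMatrix(matrix.chrom, matrix.pos, meth, total, kept)


def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open) into a sorted DataFrame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno} has fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"BED line {lineno}: empty/inverted interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else f"iv_{lineno}"
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def read_gene_models(path) -> pd.DataFrame:
    """Read gene models from a minimal TSV or a BED6-style file.

    The TSV needs columns ``gene_id, name, chrom, strand, tx_start, tx_end,
    is_coding``. A headerless BED6 (chrom start end name score strand) is
    accepted with all genes treated as coding. TSS/TES are derived
    strand-aware: TSS = tx_start for '+', tx_end for '-'.
    """
    with open(path) as fh:
        head = fh.readline()
    if "gene_id" in head:
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "strand", "tx_start", "tx_end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene TSV missing columns: {sorted(missing)}")
        if "name" not in df.columns:
            df["name"] = df["gene_id"]
        if "is_coding" not in df.columns:
            df["is_coding"] = True
    else:
        df = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["chrom", "tx_start", "tx_end", "gene_id", "score", "strand"],
        )
        df["name"] = df["gene_id"]
        df["is_coding"] = True
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbol(s): {df.loc[bad, 'strand'].unique()}")
    df["is_coding"] = df["is_coding"].astype(bool)
    df["tss"] = np.where(df["strand"] == "+", df["tx_start"], df["tx_end"])
    df["tes"] = np.where(df["strand"] == "+", df["tx_end"], df["tx_start"])
    cols = ["gene_id", "name", "chrom", "strand", "tx_start", "tx_end",
            "tss", "tes", "is_coding"]
    return df[cols].sort_values(["chrom", "tx_start"], kind="stable").reset_index(drop=True)
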