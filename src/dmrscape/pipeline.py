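"""End-to-end orchestration: ingest -> DMS -> DMRs -> LMRs -> annotation ->
feature overlap -> expression selection -> enrichment, from one config.

Every stage writes its TSV/BED outputs into the run directory and the run
closes with a manifest recording package version, parameters and input
checksums — enough to re-execute the identical run. DMRs are called at
both |diff| thresholds (0.25 and 0.35) in one pass and the strict set is
asserted to be a subset of the lenient one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import assign_dmrs, tss_window_fraction
from .dmr import ClusterPolicy, call_dmrs, threshold_subset_check
from .dms import CoveragePolicy, call_dms, test_sites
from .expression import select_case_preferential, select_tissue_preferential
from .io import (MethylomeMatrix, SampleMeta, build_matrix, merge_strands,
                 pool_technical_replicates, read_coverage_table,
                 read_gene_models)
from .lmr import LMRPolicy, promoter_lmr_extension, segment_lmrs
from .overlap import group_states, profile_dmrs
from .stats import enrichment_table, positional_distribution

__all__ = ["PipelineConfig", "validate_config", "run_all", "STAGES"]

STAGES = ["ingest", "dms", "dmrs", "lmrs", "annotate", "overlay",
          "select_genes", "enrich"]


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    seed: int = 0
    coverage_dialect: str = "strand"
    dms_q_threshold: float = 0.05
    dms_dispersion: str = "binned"
    coverage: CoveragePolicy = field(default_factory=CoveragePolicy)
    cluster: ClusterPolicy = field(default_factory=ClusterPolicy)
    cluster_strict_diff: float = 0.35
    lmr: LMRPolicy = field(default_factory=LMRPolicy)
    expr_min_level: float = 20.0
    expr_min_ratio: float = 20.0
    expr_tissue_min_tpm: float = 5.0
    expr_tissue_min_ratio: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, klass in (("coverage", CoveragePolicy), ("cluster", ClusterPolicy),
                           ("lmr", LMRPolicy)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


_REQUIRED_FILES = ["samples.tsv", "genes.tsv", "cgi.bed", "chromatin.bed",
                   "expression.tsv", "expression_roles.tsv"]


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """Check paths, ranges and group cardinalities; returns (level, message) entries."""
    report: list[tuple[str, str]] = []
    in_dir = Path(config.input_dir)
    if not in_dir.is_dir():
        report.append(("error", f"input directory {in_dir} does not exist"))
        return report
    for fname in _REQUIRED_FILES:
        if not (in_dir / fname).exists():
            report.append(("error", f"missing input file {fname}"))
    if not 0 <= config.dms_q_threshold <= 1:
        report.append(("error", "dms_q_threshold outside [0, 1]"))
    for name, value in (("min_abs_diff", config.cluster.min_abs_diff),
                        ("cluster_strict_diff", config.cluster_strict_diff)):
        if not 0 < value <= 1:
            report.append(("error", f"{name}={value} outside (0, 1]"))
    if (in_dir / "samples.tsv").exists():
        samples = pd.read_csv(in_dir / "samples.tsv", sep="\t")
        n_case = int((samples["group"] == "case").sum())
        n_ref = int((samples["group"] == "reference").sum())
        if n_case < config.coverage.min_case_samples:
            report.append(("error",
                           f"{n_case} case sample(s) but coverage policy needs "
                           f">= {config.coverage.min_case_samples}"))
        if n_ref < config.coverage.min_ref_samples:
            report.append(("error",
                           f"{n_ref} reference sample(s) but coverage policy needs "
                           f">= {config.coverage.min_ref_samples}"))
        for fname in samples.get("file", pd.Series(dtype=str)):
            if not (in_dir / fname).exists():
                report.append(("error", f"missing coverage file {fname}"))
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _load_matrix(config: PipelineConfig) -> MethylomeMatrix:
    in_dir = Path(config.input_dir)
    samples_df = pd.read_csv(in_dir / "samples.tsv", sep="\t")
    metas, per_sample = [], {}
    for row in samples_df.itertuples(index=False):
        rep = getattr(row, "replicate_of", None)
        rep = None if (rep is None or pd.isna(rep)) else str(rep)
        metas.append(SampleMeta(row.sample_id, row.group, rep))
        records = read_coverage_table(in_dir / row.file, row.sample_id,
                                      dialect=config.coverage_dialect)
        per_sample[row.sample_id] = merge_strands(records)
    matrix = build_matrix(per_sample, metas)
    return pool_technical_replicates(matrix)


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns a summary dict (also written as manifest)."""
    errors = validate_config(config)
    hard = [msg for level, msg in errors if level == "error"]
    if hard:
        raise ValueError("config validation failed: " + "; ".join(hard))
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "ingest"
    try:
        matrix = _load_matrix(config)
        matrix.write_tsv(out_dir / "matrix.tsv")

        stage = "dms"
        site_results = test_sites(matrix, config.coverage,
                                  dispersion=config.dms_dispersion)
        _write(site_results, out_dir / "dms_sites.tsv")
        dms = call_dms(site_results, config.dms_q_threshold)
        _write(dms, out_dir / "dms.tsv")

        stage = "dmrs"
        dmrs = call_dmrs(dms, config.cluster)
        strict_policy = ClusterPolicy(
            max_gap=config.cluster.max_gap, min_dms=config.cluster.min_dms,
            cluster_alpha=config.cluster.cluster_alpha,
            min_abs_diff=config.cluster_strict_diff)
        dmrs_strict = call_dmrs(dms, strict_policy)
        if not threshold_subset_check(dmrs, dmrs_strict):
            raise AssertionError("strict-threshold DMRs are not a subset of lenient set")
        _write(dmrs, out_dir / f"dmrs_{config.cluster.min_abs_diff:.2f}.tsv")
        _write(dmrs_strict, out_dir / f"dmrs_{config.cluster_strict_diff:.2f}.tsv")

        stage = "lmrs"
        genes = read_gene_models(in_dir / "genes.tsv")
        lmr_sets = {}
        for j, s in enumerate(matrix.samples):
            covered = matrix.total[:, j] > 0
            sites = pd.DataFrame({
                "chrom": matrix.chrom[covered],
                "pos": matrix.pos[covered],
                "frac": matrix.meth[covered, j] / matrix.total[covered, j],
            })
            lmrs = segment_lmrs(sites, config.lmr)
            lmr_sets[s.sample_id] = lmrs
            _write(lmrs, out_dir / f"lmrs_{s.sample_id}.tsv")
        case_ids = [s.sample_id for s in matrix.samples if s.group == "case"]
        ref_ids = [s.sample_id for s in matrix.samples if s.group == "reference"]
        extension = promoter_lmr_extension(
            lmr_sets[case_ids[0]], [lmr_sets[r] for r in ref_ids], genes)
        _write(extension, out_dir / "lmr_extension.tsv")

        stage = "annotate"
        assignments = assign_dmrs(dmrs, genes)
        _write(assignments, out_dir / "annotation.tsv")
        tss_frac = tss_window_fraction(assignments, dmrs, genes)

        stage = "overlay"
        from .io import read_bed_intervals
        chromatin = pd.read_csv(in_dir / "chromatin.bed", sep="\t", header=None,
                                names=["chrom", "start", "end", "state"])
        grouped = group_states(chromatin)
        cgis = read_bed_intervals(in_dir / "cgi.bed")
        tf_sites = {}
        for bed in sorted(in_dir.glob("tf_*.bed")):
            factor = bed.stem.removeprefix("tf_")
            tf_sites[factor] = read_bed_intervals(bed)
        profiles = profile_dmrs(dmrs, grouped, cgis, tf_sites)
        _write(profiles, out_dir / "profiles.tsv")

        stage = "select_genes"
        expression = pd.read_csv(in_dir / "expression.tsv", sep="\t")
        roles = pd.read_csv(in_dir / "expression_roles.tsv", sep="\t")
        case_col = roles.loc[roles["role"] == "case", "column"].iloc[0]
        ref_cols = roles.loc[roles["role"] == "heterologous_ref", "column"].tolist()
        calls = select_case_preferential(
            expression, case_col, ref_cols,
            min_level=config.expr_min_level, min_ratio=config.expr_min_ratio)
        tissue_rows = roles.loc[roles["role"] == "tissue", "column"]
        if len(tissue_rows):
            panel_cols = roles.loc[roles["role"] == "tissue_panel", "column"].tolist()
            tissue_calls = select_tissue_preferential(
                expression, tissue_rows.iloc[0], panel_cols,
                min_tpm=config.expr_tissue_min_tpm,
                min_ratio=config.expr_tissue_min_ratio)
            calls = pd.concat([calls, tissue_calls], ignore_index=True)
        _write(calls, out_dir / "expression_calls.tsv")

        stage = "enrich"
        selected = set(calls.loc[(calls["rule"] == "case_pref") & calls["passes"],
                                 "gene_id"])
        subset_ids = assignments.loc[assignments["gene_id"].isin(selected), "dmr_id"]
        subset_profiles = profiles[profiles["dmr_id"].isin(subset_ids)]
        enrichment = pd.DataFrame()
        positional = pd.DataFrame()
        if len(subset_profiles) and len(profiles):
            enrichment = enrichment_table(subset_profiles, profiles)
            positional = positional_distribution(
                assignments[assignments["dmr_id"].isin(subset_ids)], assignments)
        _write(enrichment, out_dir / "enrichment.tsv")
        _write(positional, out_dir / "positional.tsv")
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    input_files = sorted(p.name for p in in_dir.iterdir() if p.is_file())
    manifest = {
        "version": __version__,
        "stages": STAGES,
        "parameters": config.to_dict(),
        "inputs": {name: _sha256(in_dir / name) for name in input_files},
        "summary": {
            "n_sites": int(matrix.n_sites),
            "n_sites_tested": int(site_results["passes_coverage"].sum()),
            "n_dms": int(len(dms)),
            "n_dmrs_lenient": int(len(dmrs)),
            "n_dmrs_strict": int(len(dmrs_strict)),
            "tss_window_fraction": tss_frac if tss_frac == tss_frac else None,
            "n_selected_genes": int(len(selected)),
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
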