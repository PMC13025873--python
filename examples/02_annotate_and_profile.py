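"""Annotate DMRs against genes, chromatin states, CpG islands and TF sites.

Every DMR gets exactly one gene and one region category (promoter core,
promoter downstream, far upstream, intragenic, downstream, intergenic, in
that precedence order), a dominant chromatin group out of the nine
collapsed 18-state groups, a DMR-relative CGI overlap fraction with the
30% flag, a CGI-shore flag, and per-factor TF occupancy flags.
"""

from dmrscape import (ClusterPolicy, SyntheticConfig, assign_dmrs, call_dms,
                      call_dmrs, group_states, profile_dmrs,
                      simulate_annotation, simulate_methylomes, test_sites,
                      tss_window_fraction)

config = SyntheticConfig(seed=11, n_planted_hypo=10, n_planted_hyper=10)
annotation = simulate_annotation(config)
matrix, truth = simulate_methylomes(config, annotation)
dmrs = call_dmrs(call_dms(test_sites(matrix)), ClusterPolicy())

assignments = assign_dmrs(dmrs, annotation.genes)
print("region category counts (each DMR assigned exclusively once):")
print(assignments["region"].value_counts().to_string())
frac = tss_window_fraction(assignments, dmrs, annotation.genes)
print(f"fraction of DMRs within TSS +/- 2 kb of their gene: {frac:.3f}")

grouped = group_states(annotation.chromatin)
profiles = profile_dmrs(dmrs, grouped, annotation.cgis, annotation.tf_sites)
print("\ndominant chromatin group counts:")
print(profiles["dominant_group"].value_counts().to_string())
print(f"\nCGI >= 30% overlap flags: {int(profiles['cgi_flag'].sum())}; "
      f"shore hits: {int(profiles['shore_flag'].sum())}; "
      f"MYOD+ DMRs: {int(profiles['tf_MYOD'].sum())} "
      "(MYOD sites were planted inside a fraction of the hypo DMRs)")
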