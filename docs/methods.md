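# Methods

`dmrscape` implements a group-wise differential DNA-methylation analysis of
the kind used to characterise cell-type-preferential genes from WGBS/EM-seq
methylomes: a small panel of case methylomes (e.g. a cultured progenitor
cell type) is compared against a larger panel of heterologous reference
methylomes, differential CpGs are clustered into directed regions, and the
regions are interpreted against gene models, chromatin-state segmentations,
CpG islands and shores, TF occupancy and expression-based gene selection.
This note records the model, its free parameters, the numerical choices, and
what the bundled synthetic benchmark does and does not demonstrate.

## Per-site differential test

Each CpG is summarised per sample as a (methylated, total) read-count pair
after pooling technical replicates and merging the two strands of the CpG
dyad onto its plus-strand coordinate. Sites enter testing only if covered at
>= `min_depth` (default 5x) in at least `min_case_samples` (2) case samples
and `min_ref_samples` (4) reference samples.

The test is a binomial logistic regression of methylation state on a group
indicator. With a single binary covariate the MLE is closed form — the
fitted proportions are the coverage-pooled group fractions — so the
likelihood-ratio deviance

    G = 2 [ ll(p_case) + ll(p_ref) − ll(p_pooled) ]

is computed directly and vectorised over sites. The reported effect size
`meth_diff` is the pooled case fraction minus the pooled reference fraction
(coverage-weighted, matching the likelihood; a per-sample-mean alternative
would weight shallow samples equally, which the binomial model does not).

Replicated bisulfite data are overdispersed relative to the binomial:
between-sample variation in the true methylation level inflates G, and a
plain chi-square(1) reference is anti-conservative (about threefold at a
nominal 0.05 under the benchmark's generative model). Three dispersion
treatments are provided; the default used by the pipeline is the
simulation-calibrated quasi-likelihood (`dispersion="binned"`):

1. A genome-wide beta-binomial overdispersion `rho` is estimated by moments
   from within-group Pearson residuals under the group model. These
   residuals are blind to between-group differences, so genuinely
   differential sites cannot inflate the estimate. Samples whose fitted
   group proportion is exactly 0 or 1 are deterministic under the model
   and are excluded from both the residual sum and its degrees of freedom.
2. Sites are stratified into ten bins of pooled methylation fraction, and
   for each bin the null distribution of G is simulated parametrically at
   the bin's own observed depth vectors and fractions with the estimated
   `rho` (a fixed internal RNG stream keeps this a pure function of the
   input counts). The bin's dispersion factor matches the simulated null
   median of G to the chi-square(1) median, floored at 1.
3. The p-value is the chi-square(1) tail of `G / phi(bin)`.

The stratification matters because the effective dispersion of G is not
constant in the methylation level: near-boundary baselines (unmethylated
CpG islands) behave differently from the high-methylation bulk genome due
to count discreteness. Matching a robust central quantile rather than the
mean keeps the calibration insensitive to any residual signal, and the
chi-square tail (unlike a per-site F reference with ~7 denominator df)
retains the small p-values that survive FDR control over tens of thousands
of sites. Two alternatives remain available: `"pearson"`, a per-site
quasi-binomial F-test — well calibrated but with polynomial tails, hence
little power after BH — and `"none"`, the plain LRT, appropriate for
strictly binomial data and used by the closed-form unit oracles.

BH adjustment runs over all coverage-passing sites; DMS are sites with
q <= 0.05 (configurable) and a nonzero difference, signed hypo/hyper.

## DMS clustering into DMRs

The region caller is a transparent gap-and-direction rule with every
parameter exposed: consecutive DMS on one chromosome with the same
direction join one cluster while inter-site gaps stay <= `max_gap`
(default 1000 bp, inclusive at the boundary); clusters need `min_dms` >= 3
members. Cluster significance combines member p-values by Stouffer's
method (`z = Phi^-1(1 - p)`, oriented by the shared direction;
`Z = sum(z)/sqrt(n)`; two-sided tail), with zero p-values clamped to the
smallest positive float. Surviving clusters need combined p <= 0.05 and
|mean member difference| >= `min_abs_diff`; the pipeline evaluates both
0.25 and 0.35 in one pass and asserts the strict set is nested in the
lenient one (a pure filter relaxation). The DMR interval runs from the
first member CpG to the last member CpG + 2, covering the final dyad.
Note that Stouffer combination is not monotone under appending weak
members: a member barely below 0.5 dilutes `Z` through the sqrt(n)
denominator; only members at least as strong as the current evidence are
guaranteed to sharpen it.

## LMR segmentation

Low-methylation regions are single-sample features, independent of any
group contrast: per-CpG fractions are smoothed with a centred running mean
over `smooth_window` = 3 CpGs (truncated at chromosome ends), maximal runs
of >= `min_cpgs` = 4 consecutive CpGs with smoothed fraction <= 0.5 become
LMRs, and LMRs separated by < 200 bp merge. This is a threshold/run-length
segmentation, chosen over an HMM for determinism and testability; its
parameters are declared in `LMRPolicy`. Promoter-LMR extension takes the
widest case LMR overlapping a gene's TSS +/- 2 kb window, intersects the
corresponding reference LMRs into a constitutive core (intersection, not
union: "constitutive" means present in every reference), and reports the
case base pairs outside the core, flagged at >= 500 bp (half the window
granularity; no field standard exists for this cut-off).

## Gene and feature annotation

Region categories are strand-aware windows in transcription coordinates,
assigned exclusively in precedence order: promoter core (TSS −2 kb..+0.5
kb), promoter downstream (+0.5..+2 kb), far upstream (−5..−2 kb),
intragenic (+2 kb..TES), gene downstream (TES..TES+2 kb), else intergenic.
Candidate genes are those with any window overlapping the DMR by >= 1 bp;
coding genes beat non-coding, then the minimal |DMR midpoint − TSS| wins,
with lexicographic gene-id tie-breaks; isoform tables are collapsed to the
nearest-TSS isoform per gene before assignment. Intergenic DMRs carry the
nearest TSS and its signed distance.

Chromatin states 1–18 collapse onto nine groups (Prom=1; WkProm=2,4;
PromEnh=3; Txn=5,6; EnhG=7,8; EnhA=9,10; WkEnh=11; Repr=12–17; Low=18).
Genome not covered by any segment counts as Low, the "no mark" state, so
per-DMR group fractions always sum to one. The dominant group maximises
covered bases with a fixed tie precedence (Prom > PromEnh > EnhA > EnhG >
WkProm > WkEnh > Txn > Repr > Low). CGI overlap is measured relative to
DMR length (the 30% flag is evaluated exactly in base pairs, not floats);
shores are the 2 kb flanks of the merged CGI union minus island bases, so
an inter-island gap shore is counted once. TF occupancy is any >= 1 bp
overlap per factor. Promoter-chromatin width bridges Prom/PromEnh runs
across gaps <= 200 bp, measures the widest run touching TSS +/- 2 kb
(bridged gaps included), and classes it as standard (<= 2.5 kb), broad
(> 2.5 kb) or very broad (4–8 kb).

## Expression selection and enrichment statistics

Case-preferential genes require case abundance >= 20 (FPKM) and a >= 20x
ratio over the mean of the heterologous reference cultures;
tissue-preferential genes require tissue TPM >= 5 and >= 5x over the
median of the tissue panel; down-modulated genes have tissue TPM >= 10x
the case FPKM. All inequalities are inclusive. An epsilon of 0.01 in every
denominator keeps ratios total when references are exactly zero — the
typical case for lineage-restricted genes, which must remain selectable.
The tissue/case ratio deliberately mixes TPM and FPKM: it is a coarse
threshold-style contrast, not a normalised effect size.

Category enrichment compares a DMR subset against the full DMR set with
the pooled two-proportion z-test (no continuity correction), falling back
to Fisher's exact test whenever any expected cell count is below 5, where
the normal approximation fails; all tests emitted by one table call form a
single BH family. Categories absent from both sets are reported NA.

## Synthetic data generator

The generator is the package's study design, not a convenience fixture.
Defaults emulate a desk-scale version of the intended assay: one 2 Mb
chromosome; 3 case + 6 reference methylomes; CpGs at mean 80 bp geometric
spacing, densified 8-fold inside CGIs; per-site depth Poisson(20); counts
beta-binomial with `rho` = 0.05 across samples (biological
overdispersion); background methylation 0.85, CGIs 0.05; 40 genes with a
promoter CGI at probability 0.4 and ~85% coding; an 18-state chromatin
track tiling the genome (promoter states over TSSs, transcription states
over expressed gene bodies, enhancer blocks over half the hypo DMRs,
scattered repressed blocks, Low elsewhere); MYOD-like sites inside 60% of
hypo DMRs and background CTCF-like sites; and an expression table with one
case column, five heterologous references, one tissue column and a
54-tissue panel. Planted hypomethylated DMRs (width 1–3 kb, effect 0.4)
shift case methylation down from the 0.85 background; planted
hypermethylated DMRs sit on constitutively low-methylation footprints
(baseline 0.05 in all samples, mirroring hypermethylation at
constitutively unmethylated CGI-edge/shore DNA) and shift the case up —
placing them on the 0.85 background would clip at 1 and produce an effect
below the 0.25 region filter, i.e. an unrecoverable truth. A configurable
share of hypo DMRs (default 30%) is anchored just upstream of
preferential-gene promoters, clear of the promoter CGI, so gene linkage,
TSS-window fractions and subset enrichment have non-trivial truth.
Coverage tables are emitted with dyad counts split across strands so
ingestion exercises strand merging. Every output is a pure function of
`SyntheticConfig` (per-stage seeded streams).

What passing the synthetic benchmark shows: calibration and power of the
testing chain under beta-binomial noise with the stated design, exactness
of the interval/statistics primitives, and end-to-end determinism. What it
does not show: robustness to mappability artefacts, coverage biases,
strand asymmetries, copy-number variation, cell-composition heterogeneity
or non-CpG methylation, none of which the generator emulates; real-data
thresholds (e.g. the 0.25/0.35 pair) are inherited as configuration, not
re-derived.

## Benchmark designs and problem sizes

`dmrscape.benchmark` fixes two designs used by the tests and the
acceptance script: a null design (default config, no planted DMRs; 20
seeds) checking that the raw-p fraction below 0.05 stays within three
Monte-Carlo standard errors of 0.05 at the fixture's ~26k tested sites and
that no DMRs are emitted, and a recovery design (50 hypo + 50 hyper
planted DMRs; 5 seeds) requiring >= 90% sensitivity at >= 50% reciprocal
overlap with <= 5% false-discovery proportion. These problem sizes mirror
the default fixture; they run in seconds per seed while leaving the
Monte-Carlo bands meaningfully tight.

## Known limitations

- The clustering surrogate is deliberately simple; HMM- or
  smoothing-based callers may outperform it on diffuse effects.
- The dispersion model assumes a single genome-wide `rho`; locus-specific
  overdispersion is only partially absorbed by the fraction-binned
  calibration.
- Promoter-LMR extension measures the widest case LMR only and does not
  attribute extension to a specific flank.
- Expression selection is threshold-based by design; it performs no
  normalisation or differential testing.
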