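# Methods

## Problem and model

In cohorts without parental genotypes or matched normal tissue, imprinting
cannot be observed directly; what can be observed is whether both alleles
of a gene reach the RNA. A heterozygous SNV called in WES gives a marker
site: if RNA-seq reads show both bases, the feature is biallelically
expressed in that cell line; if WES supports heterozygosity but the RNA
shows a single base, expression is monoallelic. Two confounders must be
removed first: loss of a gene copy (one allele physically absent) and lack
of expression (no reads to witness either allele). The classifier encodes
exactly this reasoning as a first-match cascade over five evidence values
per feature × cell line: gene-level linear copy number, het-SNV counts in
WES and RNA, and log10 length-normalized read counts in both assays.

Branch order matters and is fixed: copy-number loss → no SNV data →
not expressed → biallelic → monoallelic → unresolved. Copy number is
evaluated on the gene, so a copy-loss gene forces the same call on all of
its isoforms and exons. Monoallelic calls additionally require WES
coverage at or above the expression cutoff: without WES reads over the
feature, the absence of RNA het SNVs is not evidence of a silenced allele.
All inference is per cell line; no information crosses samples.

## Thresholds and parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `cn_loss_threshold` | 1.5 | copies (linear) | below 1.5 copies at least one allele is lost; compared against the *unrounded* linear estimate, otherwise the threshold would be vacuous after integer rounding |
| `expr_cutoff` | −0.5 | log10(reads/bp) | separates noise from signal in het-SNV detection; the diagnostic `expression_cutoff_curve` (proportion of features with zero het SNVs vs expression, LOWESS-smoothed) shows the inflection this operating point sits on |
| `wes_cov_cutoff` | −0.5 | log10(reads/bp) | same normalization applied to WES reads |
| `min_cells` (flip test) | 6 | cell lines | an exact binomial test at n = 5, even fully one-sided, gives p = 0.0625 > 0.05; 6 is the smallest informative count that can reach significance (2·(½)⁶ = 0.03125) |
| `min_per_arm` (t-tests) | 3 | cell lines | smallest arms with a defined pooled variance worth testing |
| `min_corr_n` (Spearman) | 10 | cell lines | rank correlation below ten pairs is dominated by ties and noise |
| FDR report levels | 0.05, 0.125 | — | a stringent and a relaxed reporting cutoff; filtering is strict (`p_fdr < level`) |

Copy-number input: DepMap-style tables store v = log2(c/2 + 1) relative to
a diploid baseline. We invert with c = 2·(2^v − 1), so v = 1 ↔ 2 copies,
consistent with a 1.5-copy loss threshold; an `input_scale` switch accepts
already-linear tables. The discrete copy number (round half away from
zero) is reported but not used by the loss rule. Whether public
"log2(x+1)" tables are relative-to-diploid or absolute is a convention
choice, declared here, not inferred.

Length normalization uses base pairs (not kb) and natural counts:
expr = log10(Σ exon counts / merged exonic length). Zero counts map to a
−∞ sentinel rather than a pseudocount — such features are "not expressed"
and the sentinel loses every ≥ comparison, which is the intended behavior.
Exons shared between isoforms carry one count record and are never double
counted; gene exonic length is the union of its exon intervals.

## Statistical procedures

- **Flip test.** Exact two-sided binomial, null 0.5, on (n_ref, n_alt) =
  cell lines monoallelically expressing the reference vs the alternative
  base. With a symmetric null, doubling the smaller tail and the
  minimum-likelihood definition coincide; p is capped at 1. Reference-base
  expression is *inferred* when WES calls a site heterozygous and the RNA
  recorded no alternative-base variant there — monoallelic reference
  expression is invisible to variant callers, so this inference is what
  makes the counts complete. Sites with no WES het support in any cell
  line are dropped (they are homozygous: two copies of one base, not
  monoallelic expression). At multi-allelic sites the most frequent WES
  alternative base is primary; other alternatives are tallied separately.
  No multiple-testing correction is applied to per-SNV flip tests; the
  imprinted-vs-other contrast is a 2×2 test (Pearson chi-square without
  continuity correction and Fisher's exact, both reported, since the
  choice between them on a 2×2 table is a matter of taste).
- **Tissue-specificity of isoform patterns.** Pearson chi-square test of
  independence on a G×2 table of per-histology counts of purely
  monoallelic vs purely biallelic isoforms (isoforms mixing both patterns
  within a histology are excluded there); histologies with no informative
  isoform are dropped; no continuity correction; df = G−1.
- **Associations.** Student's (pooled-variance, not Welch) two-sample t on
  log10(IC50); Spearman rho with tie-corrected ranks and the two-sided t
  approximation for p. Eligibility filters run before FDR so skipped
  pairs never enter a family; each of the three families is adjusted with
  Benjamini–Hochberg separately; drug datasets (PRISM/GDSC1/GDSC2) are
  never pooled into one test, and duplicate GDSC1 measurements are
  averaged on the log scale at load. Degenerate t-tests (zero variance in
  both arms, equal means) record t = 0, p = 1 with a flag.
- **Additional monoallelic genes.** Beyond a curated imprinted list, genes
  with more than `min_mono_calls` monoallelic calls and ≥ 50% monoallelic
  among all calls are selected as the "other monoallelic" set. The
  default count threshold (50) is calibrated to a 108-cell-line cohort and
  should be scaled with cohort size (the CLI exposes it).
- **Subsampling.** Background genes are drawn without replacement per
  replicate (seeded generator, deterministic); stratification is by
  summarizing each replicate per histology. The reference-set proportion
  is reported alongside the replicate mean ± SD.

## Synthetic cohorts

The generator emits every input the pipeline reads — GTF, per-sample VCFs
for both assays, exon-count tables, a copy-number table on the
log2(c/2+1) scale, drug-response tables with planted GDSC1 replicate rows,
a curated gene list, and sample→histology groups — with truth labels for
every feature × sample and a mechanism label per SNV site.

What it emulates: shared polymorphic sites with per-line genotypes (so one
SNV is informative in several lines, as the flip test needs); imprinting
as a per-line coin for the expressed haplotype, with loss of imprinting
(LOI) flipping a gene × line to biallelic with probability `fraction_loi`
(default 0.781, so informative imprinted calls are monoallelic ~21.9% of
the time — pervasive LOI is the realistic cancer-line regime);
sequence-driven monoallelic expression as a fixed preferred allele
expressed with probability `base_bias_probability` (default 0.95) in a
`fraction_background_mono` (default 0.135) share of background genes;
copy-loss genes drawn below 1.5 copies; silent genes with zero RNA reads;
negative-binomial exon counts (dispersion 0.1; 0 switches to deterministic
means, the "noise-free" mode used for exact truth-recovery tests).
Monoallelic reference-base expression is represented the way real variant
calling sees it: no RNA variant record at the site.

What it does not emulate: read-level errors and mapping bias, phasing
errors, copy-neutral LOH (which mimics monoallelic expression and is out
of scope for resolution), RNA editing beyond the QC flag's reach,
histology-specific biology, and dose–response curve fitting (IC50s are
consumed, not estimated). Passing tests therefore demonstrate the
*logic* of the pipeline — category assignment, filtering, inference and
error control under the stated mechanisms — not robustness to alignment
or calling artifacts in real BAMs.

Diploid copy-number noise is clipped at 1.6 copies so that noise alone
cannot cross the 1.5 loss threshold and silently contradict truth labels;
copy-loss genes draw from 0.6–1.35.

## Numerical choices and degenerate inputs

Percentages print with two decimals, rounding half away from zero.
Features missing evidence classify as unresolved with a warning. NaN copy
number (gene absent from the CN table) can never satisfy the loss rule.
Constant expression vectors make Spearman's rho undefined and are skipped;
single-bin inputs to the cutoff diagnostic return raw proportions with an
empty smoothed column. Isoform-group ids are a deterministic hash of the
full call-plus-QC-flag pattern vector, so reruns are stable. VCFs must be
coordinate-sorted (checked; violation is an error); multi-allelic records
are split per alternative base and only single-base substitutions are
used. Features annotated on more than one autosome are kept but flagged,
since their copy-number attribution is unreliable; features wholly outside
chr1–chr22 are dropped at load.

## Known limitations

Biallelic calls do not distinguish 2-allele from multi-allelic expression
under copy gain. The unresolved category is a catch-all for evidence
combinations failing every positive rule, including the QC-flagged
RNA-only het case. Gene-level copy number cannot capture partial
(exon-level) deletions. The additional-monoallelic-gene rule and the flip
test inherit the classifier's calls, so misclassification propagates. The
association families use pancancer pooling; per-histology association is
deliberately not offered because arm sizes within a histology are too
small to test honestly.

## Problem sizes used in the checks

The test suite exercises cohorts of 12–48 cell lines and 10–150 genes
(1–3 isoforms per gene, 2–5 exons per isoform), flip-test calibration on
3,000 simulated SNVs, and association-null uniformity on two cohorts of 40
cell lines × 50 genes × 40 agents — sizes at which every statistical check
(binomial tolerances, KS uniformity, oracle agreement at 1e-10) is already
decisive while the whole suite stays fast.
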