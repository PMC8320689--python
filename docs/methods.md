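# Methods

`mitosoma` discovers somatic mitochondrial-DNA (mtDNA) mutations in
tumor/normal pairs from per-position allele-count tables (pileups) and
summarizes them at cohort level. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Reference model

All coordinates are 1-based inclusive on the revised Cambridge Reference
Sequence (rCRS, NC_012920.1, 16,569 bp), matching `m.` variant notation.
The sequence is vendored as a FASTA fixture together with a feature
table of the 13 protein genes, 22 tRNAs, 2 rRNAs, and the control region
(D-loop). The D-loop wraps the circular origin and is stored as two
intervals (16,024–16,569 and 1–576) under one label; this is the only
place circularity matters for annotation. Positions covered by no
feature are an explicit `intergenic` class, so region lookup is total.
Gene overlaps (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, MT-ATP6/MT-CO3) are all
reported; downstream annotation takes the most severe consequence as
primary and keeps the rest as secondary. References of any other length
(e.g. the 16,571-bp hg19 chrM) are rejected outright rather than
lifted over.

Translation uses the vertebrate mitochondrial code (NCBI table 2):
TGA→Trp, AGA/AGG→stop, ATA→Met. Seven protein genes end in an
incomplete codon completed to TAA by polyadenylation; variants striking
those codons are classified against the polyA-completed codon and
flagged. A model-level validation (exercised in the test suite)
translates all 13 genes and requires no internal stop codons, which
checks the coordinates, strand handling, and code table jointly.

## Variant calling

The caller consumes a per-strand, quality-annotated allele-count table
(the MACT TSV dialect; plain `samtools mpileup` text is an alternate
reader) and scores every non-reference allele:

1. **Quality adjustment.** Reads below a Phred cutoff (default Q20) are
   dropped; each surviving read contributes weight `1 − 10^(−Q/10)`.
   VAF (heteroplasmy) is weighted alternate count over weighted total
   count, which makes the estimator insensitive to the weighting when
   qualities are homogeneous.
2. **Per-site error test.** One-sided upper-tail binomial test of the
   raw alternate read count against the site's mean per-read error rate
   `10^(−Q̄/10)`, floored at `base_error_rate` (default 10⁻³). The test
   form is a deliberate design choice — the filter regime it feeds
   (below) is standard for low-frequency mtDNA calling, but no single
   canonical per-site test exists; `site_test` is a documented swap-in
   point for, e.g., a Fisher ref/alt-vs-error variant.
3. **FDR control.** Benjamini–Hochberg across all alleles tested in the
   sample (delegated to `statsmodels.stats.multitest`), at α = 0.05.
   Correction is per sample, not cohort-wide, because calling is a
   per-sample operation.
4. **Filters.** A call is PASS iff q ≤ α, depth ≥ 100, VAF ≥ 2%, and
   the strand filter passes: at least one alternate read on each strand
   and a two-sided Fisher's exact test on the (ref, alt) × (fwd, rev)
   table at p ≥ 10⁻³. Non-PASS calls are retained with their flags
   (`low_cov`, `low_vaf`, `strand_bias`, `fdr_fail`) so every decision
   is auditable. The Fisher component is evaluated lazily for calls
   that survive the other gates; calls already failed elsewhere carry
   the cheap representation check only.

Multi-allelic sites are tested and reported per allele. Indel alleles
(`+SEQ` insertion after the row position, `−SEQ` deletion starting at
the next base) are weighted at the site's mean base quality because the
table does not carry indel-specific qualities.

## Somatic derivation

A tumor PASS call graduates to a somatic mutation only if (a) the same
allele is not a PASS call in the matched normal **and** the raw
(unweighted) alternate fraction in the normal pileup is below 1% — raw
rather than weighted to be conservative against germline leakage; (b)
the allele is not present in strictly more than 10% of the run's
subjects (denominator: all subjects with a tumor sample, not just those
with candidates; a config switch counts samples instead); and (c) the
allele is not on the common-polymorphism blacklist (exact
position/ref/alt match). The bundled blacklist is a small illustrative
fixture of well-known common mtDNA polymorphisms; a full MitoMap-style
export can be supplied in the same four-column format. Every removal is
attributed, and the per-sample ledger
`tumor_PASS = somatic + germline + recurrent + blacklisted` is enforced
exactly at pipeline level.

## Consequence annotation

Variants are parsed from left-anchored `m.<pos><REF>><ALT>` strings and
validated against rCRS. Coding substitutions are classified by
re-translating the affected codon (light-strand genes via reverse
complement); a new stop (including AGA/AGG) is `stop_gain`, loss of
function (LoF) = stop-gain or frameshift. Coding indels are frameshift
unless their length is a multiple of three (`in_frame`, not LoF).
Multi-base substitutions are classified per codon, most severe wins.
The annotation path computes only the affected codon; the test suite
holds it against an independent oracle that rebuilds the entire gene
sequence with the variant applied and diffs the two translations
(exhaustively for MT-ATP8, sampled at 1,000 random coding SNVs across
the rest).

## Haplogroup classification

A simplified k-mer scheme: each haplogroup contributes the set of all
circular k-mers (k = 12) of its consensus genome; a sample is classified
by containment, `score = |sample ∩ library| / |library|`, ties broken
lexicographically. The sample's k-mers come from its germline consensus
(rCRS plus the subject's PASS germline substitutions), not from reads —
a deliberate simplification, since this pipeline has no read-level
access. The published tool this emulates combines two measures into a
composite score; the single containment fraction is used here and
behaves identically on the bundled library. The bundled library is
**synthetic**: twelve divergent consensus sequences derived from rCRS by
fixed substitution sets under real haplogroup label names (H, V, J, T,
U, K → macrogroup R; I, W, X → N; C, D → M; L2 → L). It is not
Phylotree data, and no real-cohort haplogroup composition should be read
off it; a real library can be supplied in the same serialized format.
K-mers containing the rCRS placeholder N (position 3,107) are dropped on
both the library and sample sides, so self-classification still scores
exactly 1.0.

## Cohort statistics

Burden is mutations per sample over initial tumor specimens only;
subjects with multiple distinct diagnoses are excluded from categorical
summaries, and subtypes below 15 samples are split into a small-n
table. 95% confidence intervals are t-based on per-sample counts (the
one-sample t machinery, as in R's `t.test`). Mean heteroplasmy per
subtype averages over mutations by default (over samples via a switch;
the two readings differ when burden varies). Two-group contrasts build
the samples-with/without-mutation 2×2 table and use a two-sided
Fisher's exact test; an exact Poisson two-sample rate test on mutation
counts is available as an alternative because the 2×2 reduction
discards multiplicity. Hotspots are alleles carried by ≥2 distinct
subjects (below the recurrence-removal threshold by construction).
Multi-specimen comparisons are set algebra on (position, ref, alt) keys
between consecutive timepoints; same-day specimens are compared
symmetrically as intratumoral heterogeneity.

## Synthetic cohort generator

The generator emulates the statistical structure of high-coverage
tumor/normal mtDNA data so that every downstream stage has a
recoverable truth:

- depth ~ Poisson per position (defaults 2,000× tumor / 1,500× normal,
  matching the >1,000× regime of mtDNA in standard whole-genome data;
  ≥95% of positions exceed 1,000×);
- per-read base quality ~ Normal(30, 5) clipped to [2, 45]; each read
  errs with probability `10^(−Q/10)` (uniform over the three alternate
  bases), so the per-site error rate is the analytic mean of that
  quantity (≈1.9 × 10⁻³ at the defaults) and the recorded per-allele
  mean quality concentrates at 30 with standard error `5/√reads`.
  Qualities are per-read attributes: an earlier one-quality-per-site
  draft let entire sites fall below the caller's Q20 cutoff, which is
  not a property of aggregated high-depth pileups;
- a germline haplogroup backbone from the synthetic library at
  0.985–1.0 VAF in both pair members;
- somatic heteroplasmies in the tumor only: count ~ Poisson with
  subtype-specific means (LGG 0.27, EPN 0.46, MB 0.57, HGG 0.60;
  cohort-wide default 0.41), VAF uniform on 2–30% (the observed span of
  the motivating cohort; its true VAF distribution is unpublished, so
  uniform is a modeling choice), 10% of injections single-base
  insertions/deletions;
- strand artifacts (~1 site/sample, 2–10% VAF, all alternate reads on
  one strand) and NuMT-like contamination (~3 sites/subject at
  haplogroup-discordant positions, VAF capped at 1.5%, below the 2%
  calling floor);
- determinism: one global seed drives a per-subject derived stream
  (`default_rng([seed, subject_index])`), so cohorts are reproducible
  under parallel generation and byte-identical on re-runs.

What passing tests on this generator establish: calibration of the
error test and FDR under the stated error model, recovery of injected
signals, and exact bookkeeping of the filter cascade. What they do not
establish: robustness to alignment artifacts, context-dependent or
asymmetric error spectra, mapping-quality pathologies around NuMT
homology, or real phylogenetic structure — none of which the generator
models.

## Problem sizes used in verification

The calibration checks run at 200 reference-only samples (empirical FDR
among PASS calls) and 500 tumors with injections at a rate of 2
somatic mutations per tumor (recall for VAF ≥ 5% at ≥1,000× and VAF
mean absolute error); ledger conservation runs on a 12-pair cohort and
haplogroup recovery on 100 subjects. The demonstration analysis under
`analysis/` uses a 30-pair cohort (seed 7). With ≤12 subjects a
singleton allele already exceeds the 10% recurrence threshold, so
cohort-level demonstrations use ≥12 pairs.

## Known limitations

- The pipeline starts from allele counts; read-level evidence (mapping
  quality, read position, duplicates) is unavailable to the filters.
- The per-site test treats reads as independent Bernoulli errors at a
  single site-level rate; overdispersion (e.g. from alignment error)
  would inflate low-VAF calls and is only partially absorbed by the 2%
  VAF floor and the strand filter.
- Germline subtraction is per-allele; it does not model tumor-in-normal
  contamination beyond the 1% raw-fraction threshold.
- The blacklist and haplogroup library fixtures are small synthetic
  stand-ins suitable for testing mechanics, not population inference.
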