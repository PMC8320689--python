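# Output table schemas

All outputs are tab-separated with a header row. Coordinates are
1-based rCRS positions; alleles use the caller's spec (`A/C/G/T` for
substitutions, `+SEQ` insertion after the position, `-SEQ` deletion
starting at the next base).

## Pileup (MACT dialect)

`pos  ref  A_f C_f G_f T_f  A_r C_r G_r T_r  indels  mq_A mq_C mq_G mq_T`
— per-strand read counts per base, `indels` as comma-separated
`+SEQ:fwd:rev` / `-SEQ:fwd:rev` items (`.` when none), `mq_X` the mean
Phred quality of reads supporting X (0 when absent).

## Call table / VCF

Columns `position ref alt vaf depth alt_fwd alt_rev ref_fwd ref_rev
p_value q_value filters`; `filters` is `PASS` or a comma-joined subset
of `low_cov,low_vaf,strand_bias,fdr_fail`. The VCF rendering uses
contig `chrM` (length 16,569), the same FILTER ids, and INFO keys
`VAF,DP,ADF,ADR,PQ,QQ` (+ `SOMATIC` flag on somatic output).

## somatic.tsv

`sample_id subject_id subtype position ref alt vaf normal_vaf depth
p_value q_value filter_trail` — one row per tumor-only mutation;
`normal_vaf` is the raw alternate fraction observed in the matched
normal; `filter_trail` records the stages the call survived.

## somatic_audit.tsv

`sample_id tumor_pass germline_subtracted recurrence_removed
blacklist_removed somatic` — per-sample conservation ledger; the last
four columns sum to `tumor_pass` exactly.

## somatic_annotated.tsv

somatic.tsv plus `m_notation gene class is_lof complex protein_change`;
`class` ∈ {missense, synonymous, stop_gain, frameshift, in_frame, tRNA,
rRNA, dloop, intergenic}; `protein_change` like `Q161*` for coding SNVs.

## lof_summary.tsv

`region gene n_lof subtypes` — one row per protein gene in OXPHOS
complex order (zero counts included), `subtypes` the comma-joined tumor
subtypes contributing LoF mutations (`-` when none).

## haplogroups.tsv / haplogroup_composition.tsv

`subject_id haplogroup macro score` per subject;
`level label n percent` for the composition (levels `macro`, `major`).

## subtype_summary.tsv (and the small-n variant)

`subtype n_samples n_mutations mutations_per_sample mean_vaf
vaf_ci_low vaf_ci_high burden_ci_low burden_ci_high n_lof n_<class>...`
— burden and t-based 95% CIs over initial tumor specimens; CI fields
are blank when undefined (fewer than two samples or zero variance).

## hotspots.tsv

`position ref alt n_subjects subjects subtypes is_lof` — alleles
carried by ≥2 distinct subjects, sorted by carrier count then position.

## longitudinal.tsv

`subject_id comparison timepoint_a timepoint_b kind shared lost gained`
— `kind` is `longitudinal` (consecutive timepoints) or `same_day`
(symmetric intratumoral comparison); allele sets render as
`pos:REF>ALT` joined by `;` (`.` when empty).

## manifest.tsv

`stage artifact sha256 seconds` — one row per pipeline artifact;
deterministic stages reproduce identical hashes under the same
configuration and seed.
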