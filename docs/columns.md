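# Result-table column dictionary

## Per-VO result table (`query` output, `filter` input/output)

One row per variant occurrence. Empty cells mean "not available" (e.g. the
variant is absent from the control population or has no score), never zero.

### Variant information

| column | type | meaning |
|---|---|---|
| `chrom` | string | contig name |
| `pos` | int | 1-based position of the first reference base (trim-normalized) |
| `ref` | string | reference allele |
| `alt` | string | alternate allele |

### Variant annotations

| column | type | meaning |
|---|---|---|
| `consequence` | enum | `EXONIC`, `SPLICE_SITE`, `LOW_IMPACT` or `INCONCLUSIVE`, from the gene model |
| `control_af` | float | allele frequency in the control population |
| `control_n_het` | int | heterozygous carriers in controls |
| `control_n_hom` | int | homozygous carriers in controls |
| `control_n_hemi` | int | hemizygous carriers in controls |
| `splice_score` | float 0–1 | precomputed splice-impact score |
| `cadd` | float | precomputed deleteriousness score |

### Participant-level details and cohort statistics

| column | type | meaning |
|---|---|---|
| `participant_id` | string | carrier of this occurrence |
| `zygosity` | enum | `HET`, `HOM` or `HEMI` |
| `cohort_af` | float | allele frequency within the queried cohort |
| `n_het_cohort` | int | heterozygous carriers of this variant among returned rows |
| `n_hom_cohort` | int | homozygous carriers among returned rows |
| `n_hemi_cohort` | int | hemizygous carriers among returned rows |
| `burden` | int | VOs this participant carries across the query gene |
| `affected` | enum | `AFFECTED`, `UNAFFECTED` or `UNKNOWN` |
| `sex` | enum | `MALE`, `FEMALE` or `UNKNOWN` |
| `hpo_terms` | `;`-list | participant's phenotype terms |
| `candidate_genes` | `;`-list | genes flagged with inconclusive role |
| `causal_genes` | `;`-list | genes flagged as likely explanation |

## Consolidated result table (`query --consolidate`)

One row per unique variant: the variant and annotation columns above, plus
`n_occurrences` (total VOs for the variant) and `participants`
(`;`-list of carrier ids).

## Filter audit report (JSON)

`schema_version`; `steps` — ordered list of
`{name, n_in, n_removed, n_out, removed_fraction}` with
`n_in = n_removed + n_out` and consecutive steps chaining; `n_prioritized`,
`n_participants`, `n_variants` — terminal counts; `terminal_note` — marker
that surviving VOs still require manual review against external sources.

## Truth manifest (`truth.tsv`, synthetic bundles)

`chrom, pos, ref, alt, participant, gene, class, expected_removal_step`
where `class` is `TRUE_POSITIVE`, a decoy class, or `INCIDENTAL`
(background), and `expected_removal_step` names the cascade step a decoy is
engineered to fail (empty for true positives and background).
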