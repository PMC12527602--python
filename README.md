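# cohortmatch

Gene-level **one-sided matchmaking** for rare-disease cohorts: query a gene of
interest across the genome-wide sequencing data of a whole cohort of
(mostly undiagnosed) participants, and prioritize the returned variants with
an inheritance-aware filter cascade.

Classic two-sided matchmaking connects two parties only when both have
independently flagged the same candidate gene. That excludes every family
whose data has never been (re)analyzed. One-sided matchmaking removes that
requirement: a researcher with a disease-gene hypothesis queries the gene
directly against a cohort database and receives every **variant occurrence**
(VO — a given SNV or small indel in a given participant) in that gene,
together with the participant-level context needed to judge each one. The
price of the approach is volume: a gene query over thousands of participants
returns far more VOs than a human can review, so almost all of the work is in
filtering.

## What the package computes

**Query engine.** For a gene `G` and a cohort allele-frequency cap
`f ≤ 0.05`, the query returns all VOs whose variant lies in the span of `G`
and whose cohort-internal allele frequency

```
AF(v) = (n_het + 2·n_hom + n_hemi) / (2·N_diploid + N_hemizygous)
```

does not exceed `f`. Each row carries on-the-fly statistics: per-variant
heterozygous/homozygous/hemizygous carrier counts, and each participant's
**burden** (number of VOs in the gene; burden ≥ 2 heterozygous VOs flags a
potential compound heterozygote). Results can be consolidated to one unique
variant per row and merged across multiple cohort stores.

**Annotation.** Each VO gets a structural consequence class from the gene
model (`EXONIC`, `SPLICE_SITE`, `LOW_IMPACT`, `INCONCLUSIVE`),
control-population frequency and zygosity counts from a gnomAD-like side
table, and precomputed SpliceAI-like / CADD-like scores. All lookups are
keyed on trim-normalized variants.

**Filter cascade.** Six executable filters applied in order, under one of
three inheritance streams (AD / AR / XLR):

1. *consequence* — drop `LOW_IMPACT` VOs unless splice score ≥ 0.5;
2. *gnomAD hom* — drop VOs ever seen homozygous in controls;
3. *zygosity* — AD keeps het; AR keeps hom and compound-het sets; XLR keeps
   male hemizygous, female homozygous and female compound-het sets;
4. *gnomAD het* — for severe pediatric-onset AD hypotheses only, drop VOs
   present in controls in any zygosity (optionally relaxed to admit control
   AF ≤ 1e-4);
5. *affected status* — the cohort as its own control: a VO carried with the
   expected inheritance by an unaffected participant is dropped for all
   carriers;
6. *phenotype* — drop VOs of participants whose HPO-closure recall against
   the queried disease profile, `|C_p ∩ C_d| / |C_d|`, falls below a
   threshold (default 0.2).

A seventh review step against external sources (ClinVar-style
classifications, segregation in relatives outside the database, clinical
notes) is manual by nature; the audit report marks the surviving VOs as
requiring it. Every run produces a `FilterReport` with per-step
input/removed/kept counts.

**Synthetic cohorts.** `cohortmatch.synthetic` generates complete,
download-free cohort bundles (participants, multi-sample VCF, gene models,
control and score tables, a mini phenotype ontology, per-gene hypotheses)
with planted true positives and per-filter decoys, plus a truth manifest —
including a 140-gene workflow-validation bundle in which exactly 124 genes
are constructed to survive the cascade.

## Worked example

```bash
cohortmatch simulate --out demo --seed 7
cohortmatch query --gene GENE002 --max-af 0.01 --store demo -o result.tsv
cohortmatch filter --result result.tsv --inheritance AR \
    --disease-hpo HP:0000010,HP:0000011,HP:0000012,HP:0000013,HP:0000014,HP:0000015 \
    --ontology demo/ontology.obo -o prioritized.tsv --report report.json
cohortmatch report report.json
```

prints

```
step                  in  removed     out  removed%
consequence           55       48       7     87.3%
gnomad_hom             7        2       5     28.6%
zygosity               5        1       4     20.0%
gnomad_het             4        0       4      0.0%
affected_status        4        2       2     50.0%
phenotype              2        1       1     50.0%
prioritized: 1 VOs across 1 participants and 1 variants
note: surviving VOs require manual external review (variant classification
databases, family segregation, clinical notes)
```

The query on `GENE002` (an AR hypothesis) returned 55 VOs across the
317-participant demo cohort; the cascade removed deep-intronic VOs without
splice support, control-population homozygotes, a lone heterozygote that
cannot fit a recessive model, variants carried by unaffected participants,
and a carrier with non-matching phenotype — leaving exactly one VO, the
homozygous variant the simulator planted in an affected, phenotype-matched
participant (`prioritized.tsv`). The library API mirrors the CLI:
`load_bundle(...)` then `run_gene(bundle, "GENE002")`.

## Layout

- `src/cohortmatch/models.py` — domain types (VOs, participants, gene
  models, frequency/score tables, ontology, reports)
- `src/cohortmatch/io.py` — readers/writers for VCF, TSV, OBO and JSON
  formats (column dictionary in `docs/columns.md`)
- `src/cohortmatch/query.py`, `annotation.py` — query engine and annotation
- `src/cohortmatch/workflow.py`, `phenotype.py` — the filter cascade and
  ontology reasoning
- `src/cohortmatch/synthetic.py` — cohort simulator with truth manifests
- `src/cohortmatch/pipeline.py`, `cli.py` — orchestration and the
  `cohortmatch` command

Design notes, parameter meanings and known limitations are in
`docs/methods.md`.
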