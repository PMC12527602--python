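# Methods

## The matchmaking model

The unit of analysis is the variant occurrence (VO): one SNV or small indel
observed in one participant, with a zygosity in {HET, HOM, HEMI}. A
gene-level one-sided matchmaking query returns every VO in a gene of
interest across a cohort, subject to a cohort-internal allele-frequency cap,
and the filter cascade then encodes the genetic reasoning a reviewer would
apply: does the variant plausibly damage the gene, is it too common in
population controls, does its zygosity fit the hypothesized inheritance, do
unaffected members of the same cohort carry it in the disease-causing
configuration, and does the carrier's phenotype resemble the queried
disease?

### Query semantics

A VO belongs to a gene when its trim-normalized start position falls within
the gene's full genomic span, not just its exons; intronic relevance is the
consequence filter's job, not the query's. The allele-frequency cap is
computed *within the queried cohort*: alternate alleles are counted once per
HET or HEMI occurrence and twice per HOM occurrence, over a denominator of
two chromosome copies per diploid participant and one per hemizygous male
(X queries). Hemizygous alleles are deliberately counted once — a choice,
documented here, since either convention is defensible. The cap has a hard
ceiling of 0.05 at the interface; the conventional working value is 0.01.
Control-population (gnomAD-like) frequencies play no role at query time;
they are annotations consumed later by the cascade, so the two frequency
notions never mix.

Genes of 200,000 bp or more trigger a warning rather than a refusal. The
size guard reflects annotation cost on large spans, not a semantic limit, so
the query proceeds.

### Zygosity from genotypes

Phase separators are ignored (no filter here reasons about cis/trans —
family-based phasing is out of scope), and genotypes containing a missing
allele (`./1`) yield no VO: a half-call is not evidence of a confident
non-reference genotype. Multi-allelic records are decomposed per alternate
allele before zygosity assignment, and each alternate is normalized
independently. On the X chromosome a male's non-reference call — haploid or
diploid-homozygous — is HEMI. Participants of UNKNOWN sex are treated as
diploid on X (no HEMI), the conservative reading. A haploid non-reference
call in any other context is treated as homozygous, matching common
genotype-dialect handling.

### Variant normalization

Keys for the frequency and score tables are produced by parsimony trimming:
shared trailing bases are removed first, then shared leading bases (position
advances accordingly), always retaining at least one base per allele. This
makes the VCF, frequency-table and score-table representations of the same
event agree without requiring a reference genome. The known limitation is
repetitive indels: two representations anchored at different positions of a
repeat tract are not unified, which full left-alignment against a FASTA
would achieve. The synthetic generator never produces such pairs, so tests
do not certify that case; real deployments with indel-heavy tables should
pre-normalize with a reference-aware tool.

### Consequence classification

The classifier is purely structural: EXONIC when the variant's reference
span `[pos, pos + len(ref) − 1]` intersects any exon, SPLICE_SITE when it
intersects the `splice_site_width` intronic bases flanking an exon boundary
(default 2, the canonical donor/acceptor dinucleotides; configurable because
near-splice variants are a known failure class of low-impact filtering),
LOW_IMPACT otherwise, and INCONCLUSIVE when the gene model carries no exons
at all. UTR and coding exons are not distinguished — the cascade only needs
the low-impact-versus-not distinction. This is an explicit approximation of
a transcript-aware effect predictor, not an equivalent: it knows nothing of
reading frames, stop codons or transcript selection. INCONCLUSIVE rows
bypass the consequence filter rather than being judged on absent
information.

## The cascade

Steps run in a fixed order: consequence → gnomAD hom → zygosity →
gnomAD het → affected status → phenotype. Order matters and is part of the
design: compound-het membership at the zygosity step is recomputed over the
rows that survived steps 1–2, so losing one partner upstream demotes the
remaining single heterozygote. The per-step report always contains all six
steps (the gnomAD het step is an identity outside severe pediatric AD
hypotheses) so report schemas are stable across streams.

Parameter defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `splice_rescue_threshold` | 0.5 | minimum splice-impact score (0–1 scale) that rescues a LOW_IMPACT VO |
| `missing_splice_policy` | TREAT_AS_ZERO | an absent splice prediction cannot rescue; BYPASS available for sensitivity analyses |
| `severe_pediatric` | false | AD only: enables the control-het filter, on the premise that adult control cohorts are largely free of severe pediatric-onset disease |
| `gnomad_het_relax_af` | disabled | when set (conventionally 1e-4), VOs at or below this control AF pass the control-het filter; trades review burden for sensitivity |
| `phenotype_threshold` | 0.2 | minimum closure recall of the disease profile |
| `ad_unaffected_trigger` | ANY | zygosities in an unaffected participant that disqualify a variant under AD |

The affected-status filter draws its evidence from the full pre-filter query
result (all zygosities, all participants), not from the rows that survived
steps 1–4 — an unaffected homozygote is exculpatory even if their own row
was removed earlier. Two points were genuinely open and are resolved here as
package policy:

- **AD trigger.** Removal fires on *any* non-reference zygosity in an
  unaffected participant, since a homozygous unaffected carrier is at least
  as exculpatory as a heterozygous one; `HET_ONLY` is available for the
  narrower reading.
- **AR compound hets.** A participant's compound-het set is disqualified
  only when some unaffected participant is heterozygous for *two or more of
  the same variants* — a single shared heterozygous variant is an expected
  carrier state under a recessive model and removes nothing. Under XLR the
  hemizygous-male and homozygous-female rules are applied; no compound-het
  analogue is enforced there.
- Participants with UNKNOWN affected status never count as evidence.

The phenotype score is closure recall: both term sets are expanded to their
ancestor closures (ontology root excluded, `min_depth` configurable) and the
score is the fraction of the disease closure covered by the participant
closure. Recall rather than Jaccard because the matchmaking question is
asymmetric — a participant with many unrelated findings should not be
penalized for them. Participants with no recorded terms cannot be assessed;
their rows are removed and flagged with a null score in the emitted
score table so a human can re-adjudicate. The 0.2 threshold is a package
default for an inherently judgment-based step — in practice this comparison
is a clinical review; the full score map is always returned for that reason.

The seventh step of the conceptual workflow — review against external data
sources (variant classification databases, segregation in relatives not in
the cohort, detailed clinical notes) — consumes information that does not
exist inside any cohort bundle, so it is represented only as a terminal
marker in the report, never executed.

## The synthetic generator

The generator emulates the structure of a family-based rare-disease
discovery cohort: 90 families of 2–5 members (≈315 participants), the first
member of each family an affected proband and the remainder affected with a
probability tuned so that just over half the cohort is affected; sexes
uniform; affected participants annotated with between 1 and 79 terms from a
bundled 233-term, four-level mini ontology (root, 8 systems, 4
subcategories each, 6 leaf findings each). Disease profiles are one
subcategory's terms, so profiles from different systems have disjoint
closures — which is what makes the phenotype-mismatch decoy construction
exact. Twenty genes of 5–60 kb with 4–10 exons are queried by default,
X-linked hypotheses on X, others cycling the autosomes.

Planted VOs are placed at reserved exonic (or deliberately deep-intronic)
positions, one planting per affected participant, with background VOs
excluded from planted participant–gene pairs; this isolation is what makes
"removed at exactly the designated step" a testable guarantee rather than a
tendency. Background VOs arrive Poisson per participant–gene (rate 0.15) at
uniform positions, with 70% given control-table records that make them
removable by the hom or het control filters; survivors are expected and
labelled INCIDENTAL in the manifest — real cohorts also surface non-planted
survivors, and the cascade's output is a shortlist, not a verdict. The
generator is deterministic: one seed, one byte-identical bundle.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, mutation-rate heterogeneity, sequencing error,
genotype-quality gradients, or clinically coherent phenotype co-occurrence.
Passing tests on generated data therefore demonstrate the correctness of
the query and filter logic under the stated semantics, not performance on
real cohort data.

The validation bundle reconstructs a 140-gene workflow check: 124 genes
carry one VO built to pass every executable filter, 6 carry a near-splice
intronic VO without splice support (consequence failure), 9 are severe
pediatric AD genes whose VO appears at control AF ≤ 1e-4 (control-het
failure, recovered when the relaxation is enabled: 133 genes survive), and
1 carries a VO also present in an unaffected relative (affected-status
failure). The 124/140 and 133/140 outcomes are properties of the
construction, verified end-to-end by running the cascade — the suite
checks that the pipeline reproduces the designed anatomy exactly, not that
it estimates it.

## Numerical and engineering choices

- Coordinates are 1-based and inclusive everywhere (VCF convention);
  equality of variants is on `(chrom, pos, ref, alt)` after trimming.
- All row orderings are lexicographic on `(chrom, pos, ref, alt,
  participant_id)`, so outputs are byte-stable for a given input and seed.
- Threshold comparisons are inclusive on the "keep" side: splice score
  exactly at the rescue threshold rescues; phenotype score exactly at the
  threshold keeps; control AF exactly at the relaxation cutoff passes.
- Missing data is never defaulted: absence from the control table means
  "not observed in controls" (kept by control filters), absence of a splice
  prediction means "no rescue available" under the default policy.
- Degenerate inputs: an empty query result produces a report whose six
  steps all carry zero counts; an empty cohort is an error for
  allele-frequency computation; an empty disease profile is an error for
  the phenotype filter.
- Problem sizes in the test and acceptance runs (≈300-participant cohorts,
  20–140 genes, ≤60 kb spans) are chosen to exercise every code path at
  desk scale; cohort-scale figures from real deployments (tens of
  thousands of VOs per query set) are not reproduced here.

## Known limitations

- No reference-aware left-alignment (see normalization above).
- The structural consequence classifier is interval arithmetic, not effect
  prediction; its LOW_IMPACT class is broader than a transcript-aware
  "low impact" call.
- Compound-het logic treats a participant's surviving heterozygous set as a
  unit; no phasing, so *cis* pairs are indistinguishable from *trans*.
- Phenotype scoring is unweighted set recall; information-content weighting
  (Resnik/Lin-style) is an extension point, not implemented.
- Multi-cohort merging namespaces participants and recomputes counts, but
  assumes the per-store allele-frequency caps were applied upstream; it
  does not recompute a pooled allele frequency across cohorts.
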