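"""Variant-level annotation of query results.

Three annotation groups are attached to each row of a query result:

1. a structural consequence class derived from the gene model (exon overlap,
   splice-site proximity, or neither);
2. control-population frequency and carrier counts from a precomputed
   frequency table;
3. precomputed splice-impact and deleteriousness scores.

The consequence classifier is intentionally structural — it reasons only
about intervals, not transcripts or reading frames. The filter workflow needs
exactly one distinction from it: "plausibly impactful" (exonic or near a
splice junction) versus "low impact" (deep intronic), plus an INCONCLUSIVE
escape hatch for gene models that carry no exon information; rows in that
state bypass the consequence filter rather than being judged on missing data.
"""

from __future__ import annotations

from .models import (
    AnnotatedVO,
    CohortmatchError,
    ConsequenceClass,
    FrequencyTable,
    GeneModel,
    GeneModelSet,
    ScoreTable,
    ValidationError,
    Variant,
)
from .query import QueryResult

__all__ = ["DEFAULT_SPLICE_SITE_WIDTH", "classify_consequence", "annotate"]

# Canonical donor/acceptor dinucleotides flank each exon boundary.
DEFAULT_SPLICE_SITE_WIDTH = 2


def classify_consequence(
    v: Variant, m: GeneModel, splice_site_width: int = DEFAULT_SPLICE_SITE_WIDTH
) -> ConsequenceClass:
    """Classify a variant against a gene model by interval arithmetic.

    The variant's reference span is ``[pos, pos + len(ref) - 1]``. EXONIC if
    it intersects any exon; otherwise SPLICE_SITE if it intersects the
    ``splice_site_width`` intronic bases on either side of any exon boundary;
    otherwise LOW_IMPACT. A model without exons yields INCONCLUSIVE.
    """
    if splice_site_width < 1:
        raise ValidationError(f"splice_site_width must be >= 1, got {splice_site_width}")
    start, end = v.pos, v.end
    if end < m.gene_start or start > m.gene_end:
        raise CohortmatchError(
            f"variant {v} lies outside gene {m.gene_symbol} "
            f"[{m.gene_start}, {m.gene_end}]"
        )
    if not m.exons:
        return ConsequenceClass.INCONCLUSIVE
    for (es, ee) in m.exons:
        if start <= ee and end >= es:
            return ConsequenceClass.EXONIC
    w = splice_site_width
    for (es, ee) in m.exons:
        # acceptor side: [es - w, es - 1]; donor side: [ee + 1, ee + w]
        if start <= es - 1 and end >= es - w:
            return ConsequenceClass.SPLICE_SITE
        if start <= ee + w and end >= ee + 1:
            return ConsequenceClass.SPLICE_SITE
    return ConsequenceClass.LOW_IMPACT


def annotate(
    result: QueryResult,
    freq: FrequencyTable,
    scores: ScoreTable,
    models: GeneModelSet,
    splice_site_width: int = DEFAULT_SPLICE_SITE_WIDTH,
) -> list[AnnotatedVO]:
    """Fill the annotation fields of every row of a query result, in place.

    Lookups are keyed on normalized variants, so a representation mismatch
    between the cohort VCF and a side table (e.g. an untrimmed indel) still
    matches. A variant absent from a table leaves the corresponding fields
    ``None`` — absence from the control population is information, never
    defaulted to zero. Row order and count are preserved.
    """
    gene = models.resolve(result.gene.gene_symbol)
    for row in result.rows:
        row.consequence = classify_consequence(row.variant, gene, splice_site_width)
        frec = freq.lookup(row.variant)
        if frec is not None:
            row.control_af = frec.af
            row.control_n_het = frec.n_het
            row.control_n_hom = frec.n_hom
            row.control_n_hemi = frec.n_hemi
        srec = scores.lookup(row.variant)
        if srec is not None:
            row.splice_score = srec.splice_score
            row.deleteriousness_score = srec.deleteriousness_score
    return result.rows
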