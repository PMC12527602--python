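"""The gene-level one-sided matchmaking query engine.

A query names a gene and a maximum *cohort-internal* allele frequency (hard
cap 0.05) and returns every variant occurrence whose variant falls inside the
gene span and whose allele frequency within the queried cohort does not
exceed the cap. Participant-level statistics are computed on the fly: per
variant, the number of heterozygous / homozygous / hemizygous carriers among
the returned rows; per participant, the number of VOs across the query gene
(the "burden" — burden ≥ 2 heterozygous VOs flags potential compound
heterozygosity).

The frequency cap here is internal to the queried cohort; control-population
(gnomAD-style) frequencies are a separate annotation consumed by the filter
workflow, not by the query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import (
    AnnotatedVO,
    Cohort,
    CohortmatchError,
    GeneModel,
    GeneModelSet,
    ValidationError,
    Variant,
    VOStore,
    Zygosity,
)

__all__ = [
    "MAX_AF_CAP",
    "DEFAULT_GENE_SIZE_WARN_BP",
    "GeneQuery",
    "QueryResult",
    "ConsolidatedRow",
    "check_gene_size",
    "cohort_allele_frequency",
    "query_gene",
    "consolidate",
    "merge_results",
]

MAX_AF_CAP = 0.05
DEFAULT_GENE_SIZE_WARN_BP = 200_000


@dataclass(frozen=True)
class GeneQuery:
    """One queried disease-gene hypothesis."""

    gene_symbol: str
    max_cohort_af: float = 0.01
    consolidate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.max_cohort_af <= MAX_AF_CAP):
            raise ValidationError(
                f"max_cohort_af must be in (0, {MAX_AF_CAP}], got {self.max_cohort_af}"
            )


@dataclass
class QueryResult:
    """Rows plus the on-the-fly statistics for one gene query."""

    gene: GeneModel
    query: GeneQuery
    rows: list[AnnotatedVO] = field(default_factory=list)
    per_variant_counts: dict[Variant, tuple[int, int, int]] = field(default_factory=dict)
    burden: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ConsolidatedRow:
    """One unique variant with aggregate occurrence counts."""

    variant: Variant
    n_het: int
    n_hom: int
    n_hemi: int
    n_occurrences: int
    participants: tuple[str, ...]


def check_gene_size(
    model: GeneModel, limit: int = DEFAULT_GENE_SIZE_WARN_BP
) -> bool:
    """Warn (returning False) when the gene span reaches ``limit`` bp.

    Large genes are allowed — the size guard exists because on-the-fly
    annotation cost grows with span — so this never refuses a query.
    """
    if limit <= 0:
        raise ValidationError(f"gene size limit must be positive, got {limit}")
    if model.span_bp >= limit:
        warnings.warn(
            f"gene {model.gene_symbol} spans {model.span_bp:,} bp "
            f"(>= {limit:,} bp); query may be slow"
        )
        return False
    return True


def cohort_allele_frequency(variant: Variant, store: VOStore, cohort: Cohort) -> float:
    """Allele frequency of ``variant`` within the queried cohort.

    Alternate alleles are counted once per HET or HEMI occurrence and twice
    per HOM occurrence; the denominator is the number of chromosome copies
    the cohort contributes at the locus (males count one copy on X).
    """
    if len(cohort) == 0:
        raise CohortmatchError("cannot compute allele frequency over an empty cohort")
    ac = 0
    for vo in store.occurrences_of(variant):
        if vo.zygosity is Zygosity.HOM:
            ac += 2
        else:
            ac += 1
    return ac / cohort.total_allele_count(variant.chrom)


def query_gene(
    q: GeneQuery,
    store: VOStore,
    cohort: Cohort,
    models: GeneModelSet,
    gene_size_limit: int = DEFAULT_GENE_SIZE_WARN_BP,
) -> QueryResult:
    """Execute a gene query: span overlap, AF cap, per-variant and per-participant stats.

    Rows are ordered by (chrom, pos, ref, alt, participant_id) so that output
    is byte-stable across runs.
    """
    gene = models.resolve(q.gene_symbol)
    check_gene_size(gene, gene_size_limit)

    candidates = store.in_span(gene.chrom, gene.gene_start, gene.gene_end)
    af_cache: dict[Variant, float] = {}
    kept = []
    for vo in candidates:
        if vo.variant not in af_cache:
            af_cache[vo.variant] = cohort_allele_frequency(vo.variant, store, cohort)
        if af_cache[vo.variant] <= q.max_cohort_af:
            kept.append(vo)

    result = QueryResult(gene=gene, query=q)
    counts: dict[Variant, list[int]] = {}
    burden: dict[str, int] = {}
    for vo in kept:
        c = counts.setdefault(vo.variant, [0, 0, 0])
        c[{Zygosity.HET: 0, Zygosity.HOM: 1, Zygosity.HEMI: 2}[vo.zygosity]] += 1
        burden[vo.participant_id] = burden.get(vo.participant_id, 0) + 1
    result.per_variant_counts = {v: tuple(c) for v, c in counts.items()}
    result.burden = burden

    for vo in kept:
        p = cohort[vo.participant_id]
        n_het, n_hom, n_hemi = result.per_variant_counts[vo.variant]
        result.rows.append(
            AnnotatedVO(
                vo=vo,
                cohort_af=af_cache[vo.variant],
                n_het_cohort=n_het,
                n_hom_cohort=n_hom,
                n_hemi_cohort=n_hemi,
                burden=burden[vo.participant_id],
                affected=p.affected,
                sex=p.sex,
                hpo_terms=p.hpo_terms,
                candidate_genes=p.candidate_genes,
                causal_genes=p.causal_genes,
            )
        )
    result.rows.sort(key=lambda r: r.vo.sort_key())
    return result


def consolidate(result: QueryResult) -> list[ConsolidatedRow]:
    """Collapse a query result to one row per unique variant.

    Conservation holds by construction: the sum of ``n_occurrences`` over the
    consolidated rows equals ``len(result.rows)``.
    """
    groups: dict[Variant, list[AnnotatedVO]] = {}
    for r in result.rows:
        groups.setdefault(r.variant, []).append(r)
    out = []
    for v in sorted(groups, key=Variant.key):
        rows = groups[v]
        n_het = sum(1 for r in rows if r.zygosity is Zygosity.HET)
        n_hom = sum(1 for r in rows if r.zygosity is Zygosity.HOM)
        n_hemi = sum(1 for r in rows if r.zygosity is Zygosity.HEMI)
        out.append(
            ConsolidatedRow(
                variant=v,
                n_het=n_het,
                n_hom=n_hom,
                n_hemi=n_hemi,
                n_occurrences=len(rows),
                participants=tuple(sorted(r.participant_id for r in rows)),
            )
        )
    return out


def merge_results(
    results: Sequence[QueryResult], labels: Optional[Sequence[str]] = None
) -> QueryResult:
    """Union query results for the same gene from multiple cohort stores.

    With ``labels``, participant ids are namespaced ``label:participant`` so
    independently numbered cohorts cannot collide; without labels, colliding
    participant ids across results are an error. Per-variant counts and
    burden are recomputed over the union.
    """
    if not results:
        raise CohortmatchError("merge_results needs at least one result")
    if labels is not None and len(labels) != len(results):
        raise CohortmatchError("one label per result is required")
    gene = results[0].gene
    for r in results[1:]:
        if r.gene.gene_symbol != gene.gene_symbol:
            raise CohortmatchError("cannot merge results for different genes")

    merged = QueryResult(gene=gene, query=results[0].query)
    seen: dict[str, int] = {}
    for i, res in enumerate(results):
        prefix = f"{labels[i]}:" if labels is not None else ""
        for row in res.rows:
            pid = prefix + row.participant_id
            if not prefix and pid in seen and seen[pid] != i:
                raise CohortmatchError(
                    f"participant id {pid!r} occurs in multiple stores; "
                    "pass labels to namespace them"
                )
            seen[pid] = i
            new_vo = type(row.vo)(row.vo.variant, pid, row.vo.zygosity)
            merged.rows.append(
                AnnotatedVO(
                    vo=new_vo,
                    consequence=row.consequence,
                    control_af=row.control_af,
                    control_n_het=row.control_n_het,
                    control_n_hom=row.control_n_hom,
                    control_n_hemi=row.control_n_hemi,
                    splice_score=row.splice_score,
                    deleteriousness_score=row.deleteriousness_score,
                    cohort_af=row.cohort_af,
                    affected=row.affected,
                    sex=row.sex,
                    hpo_terms=row.hpo_terms,
                    candidate_genes=row.candidate_genes,
                    causal_genes=row.causal_genes,
                )
            )

    counts: dict[Variant, list[int]] = {}
    burden: dict[str, int] = {}
    for row in merged.rows:
        c = counts.setdefault(row.variant, [0, 0, 0])
        c[{Zygosity.HET: 0, Zygosity.HOM: 1, Zygosity.HEMI: 2}[row.zygosity]] += 1
        burden[row.participant_id] = burden.get(row.participant_id, 0) + 1
    merged.per_variant_counts = {v: tuple(c) for v, c in counts.items()}
    merged.burden = burden
    for row in merged.rows:
        n_het, n_hom, n_hemi = merged.per_variant_counts[row.variant]
        row.n_het_cohort, row.n_hom_cohort, row.n_hemi_cohort = n_het, n_hom, n_hemi
        row.burden = burden[row.participant_id]
    merged.rows.sort(key=lambda r: r.vo.sort_key())
    return merged
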