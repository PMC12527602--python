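"""The seven-step one-sided matchmaking filter cascade.

A gene-level query over a rare-disease cohort returns every rare variant
occurrence (VO) in the gene — far too many for human review. This module
implements the sequential filter cascade that prioritizes the VOs most
likely to be disease-causing under a hypothesized inheritance model:

1. **consequence** — remove low-impact (deep intronic) VOs unless predicted
   to impact splicing (splice score >= 0.5 by default); VOs with an
   inconclusive consequence bypass the filter.
2. **gnomad_hom** — remove VOs seen homozygous at least once in the control
   population, regardless of inheritance model.
3. **zygosity** — stream-specific: AD keeps heterozygous VOs; AR keeps
   homozygous VOs and potential compound heterozygotes (participants with
   >= 2 surviving heterozygous VOs in the gene); XLR keeps male hemizygous,
   female homozygous, and female potential compound-heterozygous VOs.
   Compound-het membership is recomputed over the VOs surviving steps 1-2,
   so a partner removed upstream can demote the remaining single het here.
4. **gnomad_het** — for AD conditions with severe pediatric onset only:
   remove VOs present in the control population in any zygosity (a severe
   pediatric-onset disease should be essentially absent from adult
   controls). An optional relaxation keeps VOs whose control allele
   frequency is at or below a cutoff (0.0001 in relaxed mode).
5. **affected_status** — use the queried cohort itself as an
   inheritance-aware control: a VO carried with the expected inheritance by
   any unaffected participant is removed for every carrier.
6. **phenotype** — remove VOs of participants whose ontology-based phenotype
   overlap with the queried disease profile falls below a threshold.
7. **external review** — not executed here. The surviving, prioritized VOs
   require manual review against sources outside the toolkit (variant
   classification databases, segregation in relatives, clinical notes); the
   audit report carries a terminal marker saying so.

Every step returns (kept, removed) and is recorded in a
:class:`~cohortmatch.models.FilterReport` whose per-step counts always
conserve (n_in = n_removed + n_out).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .models import (
    AffectedStatus,
    AnnotatedVO,
    Cohort,
    CohortmatchError,
    ConsequenceClass,
    FilterReport,
    FilterStep,
    Inheritance,
    Ontology,
    Sex,
    ValidationError,
    Variant,
    Zygosity,
    is_x_contig,
)
from .phenotype import TermSetProfile, build_profile, overlap_score

__all__ = [
    "MissingSplicePolicy",
    "AdUnaffectedTrigger",
    "WorkflowConfig",
    "STEP_NAMES",
    "filter_consequence",
    "filter_gnomad_hom",
    "filter_zygosity",
    "filter_gnomad_het",
    "filter_affected_status",
    "filter_phenotype",
    "run_workflow",
    "WorkflowOutput",
]

DEFAULT_SPLICE_RESCUE_THRESHOLD = 0.5
RELAXED_GNOMAD_HET_AF = 0.0001
DEFAULT_PHENOTYPE_THRESHOLD = 0.2

STEP_NAMES = (
    "consequence",
    "gnomad_hom",
    "zygosity",
    "gnomad_het",
    "affected_status",
    "phenotype",
)


class MissingSplicePolicy(enum.Enum):
    """How a low-impact VO without a splice prediction is treated.

    TREAT_AS_ZERO: an absent prediction cannot rescue (default — the rescue
    requires an affirmative splice-impact score). BYPASS: keep the VO, for
    sensitivity analyses.
    """

    TREAT_AS_ZERO = "TREAT_AS_ZERO"
    BYPASS = "BYPASS"


class AdUnaffectedTrigger(enum.Enum):
    """Which zygosities in an unaffected participant disqualify a variant
    under the AD stream: any non-reference genotype (default; a homozygous
    unaffected carrier is at least as exculpatory as a heterozygous one), or
    heterozygous only."""

    ANY = "ANY"
    HET_ONLY = "HET_ONLY"


@dataclass
class WorkflowConfig:
    """All tunable knobs of one cascade run for one disease-gene hypothesis."""

    inheritance: Inheritance
    disease_hpo_terms: frozenset[str] = frozenset()
    severe_pediatric: bool = False
    splice_rescue_threshold: float = DEFAULT_SPLICE_RESCUE_THRESHOLD
    gnomad_het_relax_af: Optional[float] = None
    phenotype_threshold: float = DEFAULT_PHENOTYPE_THRESHOLD
    missing_splice_policy: MissingSplicePolicy = MissingSplicePolicy.TREAT_AS_ZERO
    ad_unaffected_trigger: AdUnaffectedTrigger = AdUnaffectedTrigger.ANY

    def __post_init__(self) -> None:
        if not (0.0 <= self.splice_rescue_threshold <= 1.0):
            raise ValidationError("splice_rescue_threshold must be in [0, 1]")
        if not (0.0 <= self.phenotype_threshold <= 1.0):
            raise ValidationError("phenotype_threshold must be in [0, 1]")
        if self.gnomad_het_relax_af is not None and not (
            0.0 <= self.gnomad_het_relax_af <= 1.0
        ):
            raise ValidationError("gnomad_het_relax_af must be in [0, 1]")
        if self.severe_pediatric and self.inheritance is not Inheritance.AD:
            raise ValidationError(
                "severe_pediatric is only meaningful for the AD stream"
            )


Rows = list[AnnotatedVO]


def filter_consequence(
    rows: Sequence[AnnotatedVO],
    threshold: float = DEFAULT_SPLICE_RESCUE_THRESHOLD,
    missing_policy: MissingSplicePolicy = MissingSplicePolicy.TREAT_AS_ZERO,
) -> tuple[Rows, Rows]:
    """Remove low-impact VOs unless predicted to impact splicing.

    Only LOW_IMPACT rows are candidates for removal; a row is rescued by a
    splice score >= ``threshold``. INCONCLUSIVE rows always pass.
    """
    kept, removed = [], []
    for r in rows:
        if r.consequence is ConsequenceClass.LOW_IMPACT:
            score = r.splice_score
            if score is None:
                if missing_policy is MissingSplicePolicy.BYPASS:
                    kept.append(r)
                    continue
                score = 0.0
            (kept if score >= threshold else removed).append(r)
        else:
            kept.append(r)
    return kept, removed


def filter_gnomad_hom(rows: Sequence[AnnotatedVO]) -> tuple[Rows, Rows]:
    """Remove VOs homozygous in more than zero control-population samples.

    Absence from the frequency table is not evidence of presence: such rows
    are kept.
    """
    kept, removed = [], []
    for r in rows:
        if r.control_n_hom is not None and r.control_n_hom > 0:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def _het_counts_by_participant(rows: Iterable[AnnotatedVO]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in rows:
        if r.zygosity is Zygosity.HET:
            counts[r.participant_id] = counts.get(r.participant_id, 0) + 1
    return counts


def filter_zygosity(
    rows: Sequence[AnnotatedVO], inheritance: Inheritance
) -> tuple[Rows, Rows]:
    """Keep VOs whose zygosity matches the queried inheritance model.

    AD keeps heterozygous VOs. AR keeps homozygous VOs plus heterozygous VOs
    of participants carrying >= 2 surviving heterozygous VOs in the gene
    (potential compound heterozygotes). XLR keeps hemizygous VOs in males,
    homozygous VOs in females, and heterozygous VOs of females with >= 2
    surviving heterozygous VOs. Compound-het counts are taken over the input
    rows — i.e. over what survived the upstream filters, not the original
    query burden.
    """
    kept, removed = [], []
    if inheritance is Inheritance.AD:
        for r in rows:
            (kept if r.zygosity is Zygosity.HET else removed).append(r)
        return kept, removed

    if inheritance is Inheritance.AR:
        het_counts = _het_counts_by_participant(rows)
        for r in rows:
            if r.zygosity is Zygosity.HOM:
                kept.append(r)
            elif (
                r.zygosity is Zygosity.HET
                and het_counts.get(r.participant_id, 0) >= 2
            ):
                kept.append(r)
            else:
                removed.append(r)
        return kept, removed

    # XLR
    female_het_counts = _het_counts_by_participant(
        r for r in rows if r.sex is Sex.FEMALE
    )
    for r in rows:
        if r.zygosity is Zygosity.HEMI and r.sex is Sex.MALE:
            kept.append(r)
        elif r.zygosity is Zygosity.HOM and r.sex is Sex.FEMALE:
            kept.append(r)
        elif (
            r.zygosity is Zygosity.HET
            and r.sex is Sex.FEMALE
            and female_het_counts.get(r.participant_id, 0) >= 2
        ):
            kept.append(r)
        else:
            removed.append(r)
    return kept, removed


def filter_gnomad_het(
    rows: Sequence[AnnotatedVO], config: WorkflowConfig
) -> tuple[Rows, Rows]:
    """For severe pediatric-onset AD hypotheses, remove VOs present in the
    control population in any zygosity.

    A no-op for every other stream. In relaxed mode, rows whose control
    allele frequency is at or below ``gnomad_het_relax_af`` are kept even if
    present in controls.
    """
    if not (config.inheritance is Inheritance.AD and config.severe_pediatric):
        return list(rows), []
    kept, removed = [], []
    for r in rows:
        if not r.in_control_population():
            kept.append(r)
        elif (
            config.gnomad_het_relax_af is not None
            and r.control_af is not None
            and r.control_af <= config.gnomad_het_relax_af
        ):
            kept.append(r)
        else:
            removed.append(r)
    return kept, removed


def filter_affected_status(
    rows: Sequence[AnnotatedVO],
    cohort: Cohort,
    inheritance: Inheritance,
    reference_rows: Optional[Sequence[AnnotatedVO]] = None,
    ad_trigger: AdUnaffectedTrigger = AdUnaffectedTrigger.ANY,
) -> tuple[Rows, Rows]:
    """Use the queried cohort itself as an inheritance-aware control.

    A variant carried with the expected inheritance by any UNAFFECTED
    participant disqualifies it for every carrier. Evidence is gathered from
    ``reference_rows`` — normally the full, pre-filter query result (all
    zygosities, all participants), not just the rows that survived earlier
    steps. Participants with UNKNOWN affected status never trigger removal.

    Stream rules: AD — any non-reference occurrence in an unaffected removes
    all rows of the variant (``ad_trigger=HET_ONLY`` restricts the evidence
    to heterozygous occurrences). AR — a homozygous unaffected carrier
    removes the homozygous rows of the variant; a participant's surviving
    compound-het set is removed if some unaffected participant is
    heterozygous for >= 2 of the same variants. XLR — a hemizygous
    unaffected male removes hemizygous rows; a homozygous unaffected female
    removes female homozygous rows.
    """
    if reference_rows is None:
        reference_rows = rows

    def is_unaffected(pid: str) -> bool:
        p = cohort.get(pid)
        return p is not None and p.affected is AffectedStatus.UNAFFECTED

    # variant -> zygosities observed in unaffected participants
    unaffected_zyg: dict[Variant, set[Zygosity]] = {}
    # unaffected participant -> set of variants carried heterozygously
    unaffected_hets: dict[str, set[Variant]] = {}
    for r in reference_rows:
        if not is_unaffected(r.participant_id):
            continue
        unaffected_zyg.setdefault(r.variant, set()).add(r.zygosity)
        if r.zygosity is Zygosity.HET:
            unaffected_hets.setdefault(r.participant_id, set()).add(r.variant)

    kept, removed = [], []

    if inheritance is Inheritance.AD:
        for r in rows:
            zygs = unaffected_zyg.get(r.variant, set())
            hit = (
                bool(zygs)
                if ad_trigger is AdUnaffectedTrigger.ANY
                else Zygosity.HET in zygs
            )
            (removed if hit else kept).append(r)
        return kept, removed

    if inheritance is Inheritance.AR:
        # Surviving HET rows at this point belong to compound-het sets.
        het_variants_by_p: dict[str, set[Variant]] = {}
        for r in rows:
            if r.zygosity is Zygosity.HET:
                het_variants_by_p.setdefault(r.participant_id, set()).add(r.variant)
        comphet_disqualified: set[str] = set()
        for pid, variants in het_variants_by_p.items():
            for hets in unaffected_hets.values():
                if len(variants & hets) >= 2:
                    comphet_disqualified.add(pid)
                    break
        for r in rows:
            if r.zygosity is Zygosity.HOM:
                hit = Zygosity.HOM in unaffected_zyg.get(r.variant, set())
            elif r.zygosity is Zygosity.HET:
                hit = r.participant_id in comphet_disqualified
            else:
                hit = False
            (removed if hit else kept).append(r)
        return kept, removed

    # XLR
    unaffected_hemi: set[Variant] = set()
    unaffected_hom_female: set[Variant] = set()
    for r in reference_rows:
        if not is_unaffected(r.participant_id):
            continue
        if r.zygosity is Zygosity.HEMI and r.sex is Sex.MALE:
            unaffected_hemi.add(r.variant)
        elif r.zygosity is Zygosity.HOM and r.sex is Sex.FEMALE:
            unaffected_hom_female.add(r.variant)
    for r in rows:
        if r.zygosity is Zygosity.HEMI and r.variant in unaffected_hemi:
            removed.append(r)
        elif (
            r.zygosity is Zygosity.HOM
            and r.sex is Sex.FEMALE
            and r.variant in unaffected_hom_female
        ):
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def filter_phenotype(
    rows: Sequence[AnnotatedVO],
    cohort: Cohort,
    ontology: Ontology,
    config: WorkflowConfig,
) -> tuple[Rows, Rows, dict[str, Optional[float]]]:
    """Remove VOs of participants with insufficient phenotype overlap.

    Each participant's ontology terms are compared to the queried disease
    profile via closure recall; rows of participants scoring below
    ``phenotype_threshold`` are removed. Participants with no recorded terms
    cannot be assessed and are removed with a ``None`` score, flagged in the
    returned score map so a human can re-adjudicate.
    """
    if not config.disease_hpo_terms:
        raise ValidationError("phenotype filter requires a non-empty disease profile")
    disease = build_profile(config.disease_hpo_terms, ontology)
    scores: dict[str, Optional[float]] = {}
    profiles: dict[str, TermSetProfile] = {}
    for r in rows:
        pid = r.participant_id
        if pid in scores:
            continue
        p = cohort[pid]
        if not p.hpo_terms:
            scores[pid] = None
            continue
        profiles[pid] = build_profile(p.hpo_terms, ontology)
        scores[pid] = overlap_score(profiles[pid], disease)
    kept, removed = [], []
    for r in rows:
        s = scores[r.participant_id]
        if s is not None and s >= config.phenotype_threshold:
            kept.append(r)
        else:
            removed.append(r)
    return kept, removed, scores


@dataclass
class WorkflowOutput:
    """Prioritized rows plus the audit trail of one cascade run.

    ``removal_steps`` maps each removed VO, keyed by
    ``((chrom, pos, ref, alt), participant_id)``, to the name of the step
    that removed it — the per-VO counterpart of the per-step report counts.
    """

    prioritized: Rows
    report: FilterReport
    phenotype_scores: dict[str, Optional[float]] = field(default_factory=dict)
    removal_steps: dict[tuple, str] = field(default_factory=dict)


def run_workflow(
    rows: Sequence[AnnotatedVO],
    config: WorkflowConfig,
    cohort: Cohort,
    ontology: Ontology,
    reference_rows: Optional[Sequence[AnnotatedVO]] = None,
) -> WorkflowOutput:
    """Run the six executable filters in order and build the audit report.

    ``rows`` is an annotated query result for one gene; ``reference_rows``
    is the evidence set for the affected-status filter and defaults to
    ``rows`` itself (the full pre-filter result). The seventh step, review
    against external data sources, is manual by design; the report's
    terminal note marks the surviving rows as requiring it.
    """
    if config.inheritance is Inheritance.XLR:
        non_x = [r for r in rows if not is_x_contig(r.variant.chrom)]
        if non_x:
            raise CohortmatchError(
                "XLR stream requires X-chromosome rows; got variant "
                f"{non_x[0].variant}"
            )

    if reference_rows is None:
        reference_rows = list(rows)

    report = FilterReport()
    removal_steps: dict[tuple, str] = {}
    current: Rows = list(rows)

    def record(name: str, kept: Rows, removed: Rows) -> Rows:
        report.steps.append(FilterStep(name, len(kept) + len(removed), len(removed)))
        for r in removed:
            removal_steps[(r.variant.key(), r.participant_id)] = name
        return kept

    kept, removed = filter_consequence(
        current, config.splice_rescue_threshold, config.missing_splice_policy
    )
    current = record("consequence", kept, removed)

    kept, removed = filter_gnomad_hom(current)
    current = record("gnomad_hom", kept, removed)

    kept, removed = filter_zygosity(current, config.inheritance)
    current = record("zygosity", kept, removed)

    kept, removed = filter_gnomad_het(current, config)
    current = record("gnomad_het", kept, removed)

    kept, removed = filter_affected_status(
        current,
        cohort,
        config.inheritance,
        reference_rows=reference_rows,
        ad_trigger=config.ad_unaffected_trigger,
    )
    current = record("affected_status", kept, removed)

    kept, removed, scores = filter_phenotype(current, cohort, ontology, config)
    current = record("phenotype", kept, removed)

    report.n_prioritized = len(current)
    report.n_participants = len({r.participant_id for r in current})
    report.n_variants = len({r.variant for r in current})
    report.validate()
    return WorkflowOutput(
        prioritized=current,
        report=report,
        phenotype_scores=scores,
        removal_steps=removal_steps,
    )
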