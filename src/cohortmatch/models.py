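"""Core domain types for gene-level one-sided matchmaking.

The atomic unit throughout the toolkit is the *variant occurrence* (VO): a
specific SNV or small indel observed in a specific participant, with its
zygosity. A gene query returns VOs; the filter cascade removes VOs; reports
count VOs. Everything else here (participants, gene models, control-population
frequency records, precomputed score records, the phenotype ontology) exists
to annotate or adjudicate VOs.

Coordinates are 1-based and intervals inclusive, following VCF convention,
for every type in this module.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "Sex",
    "AffectedStatus",
    "Zygosity",
    "ConsequenceClass",
    "Inheritance",
    "Variant",
    "normalize_variant",
    "VariantOccurrence",
    "Participant",
    "Cohort",
    "VOStore",
    "GeneModel",
    "GeneModelSet",
    "FrequencyRecord",
    "FrequencyTable",
    "ScoreRecord",
    "ScoreTable",
    "Ontology",
    "AnnotatedVO",
    "FilterStep",
    "FilterReport",
    "is_x_contig",
    "CohortmatchError",
    "ValidationError",
    "UnknownGeneError",
]


class CohortmatchError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(CohortmatchError):
    """An input violated a documented invariant."""


class UnknownGeneError(CohortmatchError):
    """A queried gene symbol does not resolve in the gene model set."""


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class AffectedStatus(enum.Enum):
    AFFECTED = "AFFECTED"
    UNAFFECTED = "UNAFFECTED"
    UNKNOWN = "UNKNOWN"


class Zygosity(enum.Enum):
    HET = "HET"
    HOM = "HOM"
    HEMI = "HEMI"


class ConsequenceClass(enum.Enum):
    """Structural consequence of a variant relative to a gene model.

    EXONIC        — reference span intersects an exon
    SPLICE_SITE   — intersects the intronic bases flanking an exon boundary
    LOW_IMPACT    — intronic, away from any splice site (candidate for removal)
    INCONCLUSIVE  — the gene model carries no exon list, so no call can be made
    """

    EXONIC = "EXONIC"
    SPLICE_SITE = "SPLICE_SITE"
    LOW_IMPACT = "LOW_IMPACT"
    INCONCLUSIVE = "INCONCLUSIVE"


class Inheritance(enum.Enum):
    """The three inheritance streams of the filter workflow."""

    AD = "AD"
    AR = "AR"
    XLR = "XLR"


_X_NAMES = {"X", "CHRX"}


def is_x_contig(chrom: str) -> bool:
    """True for the X chromosome under common naming conventions."""
    return chrom.upper() in _X_NAMES


@dataclass(frozen=True, order=True)
class Variant:
    """An SNV or small indel in VCF representation.

    ``pos`` is the 1-based position of the first reference base. Equality and
    ordering are on ``(chrom, pos, ref, alt)``; callers are expected to
    normalize (see :func:`normalize_variant`) before using variants as keys
    across data sources.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValidationError(f"empty allele in variant {self!r}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt in variant {self!r}")
        if self.pos < 1:
            raise ValidationError(f"non-positive position in variant {self!r}")

    @property
    def end(self) -> int:
        """Last reference base covered (== pos for SNVs and insertions)."""
        return self.pos + len(self.ref) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_variant(v: Variant) -> Variant:
    """Return the minimal representation of ``v``.

    Shared trailing bases are trimmed first, then shared leading bases (the
    position advances by one per leading base removed); at least one base is
    always retained in each allele. The operation is idempotent. This is
    parsimony-style trimming without reference-genome left-alignment, so two
    representations of the same indel inside a repeat tract that start at
    different anchor positions are not unified.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == v.ref and alt == v.alt:
        return v
    return Variant(v.chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantOccurrence:
    """One variant in one participant with its zygosity — the unit of matchmaking."""

    variant: Variant
    participant_id: str
    zygosity: Zygosity

    def sort_key(self) -> tuple:
        return (*self.variant.key(), self.participant_id)


@dataclass
class Participant:
    """A cohort member: identity, family, sex, affected status and phenotype.

    ``hpo_terms`` holds ontology term identifiers (e.g. ``HP:0001250``);
    ``candidate_genes`` are genes flagged with an inconclusive role in the
    participant's condition, ``causal_genes`` those considered a likely
    explanation.
    """

    participant_id: str
    family_id: str
    sex: Sex = Sex.UNKNOWN
    affected: AffectedStatus = AffectedStatus.UNKNOWN
    hpo_terms: frozenset[str] = frozenset()
    candidate_genes: frozenset[str] = frozenset()
    causal_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.affected is AffectedStatus.AFFECTED and not self.hpo_terms:
            warnings.warn(
                f"affected participant {self.participant_id!r} has no HPO terms",
                stacklevel=2,
            )


class Cohort:
    """An id-indexed collection of participants.

    Participant ids must be unique; lookups are by id. The cohort also knows
    how many chromosomes it contributes at a locus, which the query engine
    needs for internal allele frequencies.
    """

    def __init__(self, participants: Iterable[Participant] = ()) -> None:
        self._by_id: dict[str, Participant] = {}
        for p in participants:
            self.add(p)

    def add(self, p: Participant) -> None:
        if p.participant_id in self._by_id:
            raise ValidationError(f"duplicate participant_id {p.participant_id!r}")
        self._by_id[p.participant_id] = p

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Participant]:
        return iter(self._by_id.values())

    def __contains__(self, participant_id: str) -> bool:
        return participant_id in self._by_id

    def __getitem__(self, participant_id: str) -> Participant:
        return self._by_id[participant_id]

    def get(self, participant_id: str) -> Optional[Participant]:
        return self._by_id.get(participant_id)

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def unaffected(self) -> list[Participant]:
        return [p for p in self if p.affected is AffectedStatus.UNAFFECTED]

    def total_allele_count(self, chrom: str) -> int:
        """Chromosome copies the cohort contributes at a locus on ``chrom``.

        Autosomes: two per participant. X: one per male, two otherwise
        (UNKNOWN sex is counted as diploid on X, the conservative choice).
        """
        if not self._by_id:
            raise ValidationError("empty cohort has no allele count")
        if not is_x_contig(chrom):
            return 2 * len(self._by_id)
        n_male = sum(1 for p in self if p.sex is Sex.MALE)
        return 2 * (len(self._by_id) - n_male) + n_male


class VOStore:
    """All variant occurrences of a cohort, queryable by genomic span.

    (variant, participant) pairs are unique; VOs are kept sorted by
    (chrom, pos, ref, alt, participant_id) so downstream output is
    byte-stable.
    """

    def __init__(self, vos: Iterable[VariantOccurrence] = ()) -> None:
        self._vos: list[VariantOccurrence] = []
        self._seen: set[tuple] = set()
        self._sorted = True
        for vo in vos:
            self.add(vo)

    def add(self, vo: VariantOccurrence) -> None:
        key = (vo.variant.key(), vo.participant_id)
        if key in self._seen:
            raise ValidationError(
                f"duplicate occurrence of {vo.variant} in {vo.participant_id!r}"
            )
        self._seen.add(key)
        self._vos.append(vo)
        self._sorted = False

    def _ensure_sorted(self) -> None:
        if not self._sorted:
            self._vos.sort(key=VariantOccurrence.sort_key)
            self._sorted = True

    def __len__(self) -> int:
        return len(self._vos)

    def __iter__(self) -> Iterator[VariantOccurrence]:
        self._ensure_sorted()
        return iter(self._vos)

    def in_span(self, chrom: str, start: int, end: int) -> list[VariantOccurrence]:
        """VOs whose (normalized) start position lies within [start, end]."""
        self._ensure_sorted()
        return [
            vo
            for vo in self._vos
            if vo.variant.chrom == chrom and start <= vo.variant.pos <= end
        ]

    def occurrences_of(self, variant: Variant) -> list[VariantOccurrence]:
        self._ensure_sorted()
        return [vo for vo in self._vos if vo.variant == variant]


@dataclass
class GeneModel:
    """A gene as a genomic span with an ordered exon list.

    Exon intervals are 1-based inclusive, sorted, non-overlapping and
    contained in [gene_start, gene_end]. An empty exon list is legal and
    marks the model as structurally uninformative (consequence calls become
    INCONCLUSIVE).
    """

    gene_symbol: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_symbol}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.gene_end < self.gene_start:
            raise ValidationError(
                f"gene {self.gene_symbol}: inverted span "
                f"[{self.gene_start}, {self.gene_end}]"
            )
        prev_end = None
        for (s, e) in self.exons:
            if e < s:
                raise ValidationError(
                    f"gene {self.gene_symbol}: inverted exon interval [{s}, {e}]"
                )
            if s < self.gene_start or e > self.gene_end:
                raise ValidationError(
                    f"gene {self.gene_symbol}: exon [{s}, {e}] outside gene span"
                )
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"gene {self.gene_symbol}: exons unsorted or overlapping at [{s}, {e}]"
                )
            prev_end = e

    @property
    def span_bp(self) -> int:
        return self.gene_end - self.gene_start + 1


class GeneModelSet:
    """Gene models indexed by symbol."""

    def __init__(self, models: Iterable[GeneModel] = ()) -> None:
        self._by_symbol: dict[str, GeneModel] = {}
        for m in models:
            if m.gene_symbol in self._by_symbol:
                raise ValidationError(f"duplicate gene symbol {m.gene_symbol!r}")
            self._by_symbol[m.gene_symbol] = m

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._by_symbol.values())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def symbols(self) -> list[str]:
        return sorted(self._by_symbol)

    def resolve(self, symbol: str) -> GeneModel:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            near = sorted(
                self._by_symbol,
                key=lambda s: (_symbol_distance(symbol, s), s),
            )[:3]
            raise UnknownGeneError(
                f"unknown gene {symbol!r}; nearest known symbols: {', '.join(near)}"
            ) from None


def _symbol_distance(a: str, b: str) -> int:
    """Cheap edit-distance proxy used only for 'did you mean' suggestions."""
    a, b = a.upper(), b.upper()
    if a == b:
        return 0
    common = len(set(a) & set(b))
    return abs(len(a) - len(b)) + max(len(a), len(b)) - common


@dataclass(frozen=True)
class FrequencyRecord:
    """Allele frequency and carrier counts of a variant in a control population."""

    variant: Variant
    af: float
    n_het: int
    n_hom: int
    n_hemi: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValidationError(f"control AF {self.af} outside [0, 1] for {self.variant}")
        for name in ("n_het", "n_hom", "n_hemi"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative {name} for {self.variant}")


class FrequencyTable:
    """Control-population records keyed by normalized variant.

    Absence of a record means the variant was not seen in the control
    population — a meaningful state, distinct from zero counts.
    """

    def __init__(self, records: Iterable[FrequencyRecord] = ()) -> None:
        self._by_variant: dict[Variant, FrequencyRecord] = {}
        for r in records:
            self._by_variant[normalize_variant(r.variant)] = r

    def __len__(self) -> int:
        return len(self._by_variant)

    def lookup(self, variant: Variant) -> Optional[FrequencyRecord]:
        return self._by_variant.get(normalize_variant(variant))

    def records(self) -> list[FrequencyRecord]:
        return [self._by_variant[k] for k in sorted(self._by_variant, key=Variant.key)]


@dataclass(frozen=True)
class ScoreRecord:
    """Precomputed splice-impact and deleteriousness scores for a variant."""

    variant: Variant
    splice_score: Optional[float] = None
    deleteriousness_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.splice_score is not None and not (0.0 <= self.splice_score <= 1.0):
            raise ValidationError(
                f"splice score {self.splice_score} outside [0, 1] for {self.variant}"
            )
        if self.deleteriousness_score is not None and self.deleteriousness_score < 0:
            raise ValidationError(f"negative deleteriousness score for {self.variant}")


class ScoreTable:
    """Score records keyed by normalized variant."""

    def __init__(self, records: Iterable[ScoreRecord] = ()) -> None:
        self._by_variant: dict[Variant, ScoreRecord] = {}
        for r in records:
            self._by_variant[normalize_variant(r.variant)] = r

    def __len__(self) -> int:
        return len(self._by_variant)

    def lookup(self, variant: Variant) -> Optional[ScoreRecord]:
        return self._by_variant.get(normalize_variant(variant))

    def records(self) -> list[ScoreRecord]:
        return [self._by_variant[k] for k in sorted(self._by_variant, key=Variant.key)]


class Ontology:
    """A phenotype ontology as a term → parents DAG (``is_a`` edges only)."""

    def __init__(self, parents: dict[str, frozenset[str]]) -> None:
        for term, ps in parents.items():
            for p in ps:
                if p not in parents:
                    raise ValidationError(
                        f"ontology parent {p!r} of {term!r} is not itself a term"
                    )
        self._parents = {t: frozenset(ps) for t, ps in parents.items()}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self._parents}
        for start in self._parents:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterator[str]]] = [(start, iter(self._parents[start]))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == GRAY:
                        raise ValidationError(f"ontology cycle involving {nxt!r}")
                    if color[nxt] == WHITE:
                        color[nxt] = GRAY
                        stack.append((nxt, iter(self._parents[nxt])))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._parents)

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    def parents(self, term: str) -> frozenset[str]:
        return self._parents[term]

    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self._parents.items() if not ps)


@dataclass
class AnnotatedVO:
    """One row of the result table: a VO plus everything a reviewer sees.

    Field groups mirror the three information categories of the result table:
    variant information (the VO itself), variant annotations (consequence,
    control-population counts, scores) and participant-level details
    (affected status, sex, phenotype terms, flagged genes, cohort statistics).
    Control/score fields are ``None`` exactly when the variant is absent from
    the corresponding side table.
    """

    vo: VariantOccurrence
    consequence: Optional[ConsequenceClass] = None
    control_af: Optional[float] = None
    control_n_het: Optional[int] = None
    control_n_hom: Optional[int] = None
    control_n_hemi: Optional[int] = None
    splice_score: Optional[float] = None
    deleteriousness_score: Optional[float] = None
    n_het_cohort: int = 0
    n_hom_cohort: int = 0
    n_hemi_cohort: int = 0
    cohort_af: Optional[float] = None
    burden: int = 0
    affected: AffectedStatus = AffectedStatus.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    hpo_terms: frozenset[str] = frozenset()
    candidate_genes: frozenset[str] = frozenset()
    causal_genes: frozenset[str] = frozenset()

    @property
    def variant(self) -> Variant:
        return self.vo.variant

    @property
    def participant_id(self) -> str:
        return self.vo.participant_id

    @property
    def zygosity(self) -> Zygosity:
        return self.vo.zygosity

    def in_control_population(self) -> bool:
        """True when the variant has any nonzero carrier count in controls."""
        counts = (self.control_n_het, self.control_n_hom, self.control_n_hemi)
        return any(c is not None and c > 0 for c in counts)


@dataclass
class FilterStep:
    """One step of the audit report: what came in, what was removed."""

    name: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_in if self.n_in else 0.0


@dataclass
class FilterReport:
    """Ordered per-step counts for one workflow run, plus terminal totals.

    Invariants (enforced by :meth:`validate`): within each step
    ``n_in = n_removed + n_out``; consecutive steps chain (step k's input is
    step k-1's output). The terminal note records that surviving VOs still
    require manual review against external sources (variant classification
    databases, family segregation, clinical notes) — that review is outside
    this toolkit.
    """

    steps: list[FilterStep] = field(default_factory=list)
    n_prioritized: int = 0
    n_participants: int = 0
    n_variants: int = 0
    terminal_note: str = (
        "surviving VOs require manual external review "
        "(variant classification databases, family segregation, clinical notes)"
    )

    def validate(self) -> None:
        prev_out: Optional[int] = None
        for step in self.steps:
            if step.n_removed < 0 or step.n_removed > step.n_in:
                raise ValidationError(f"step {step.name!r}: inconsistent counts")
            if prev_out is not None and step.n_in != prev_out:
                raise ValidationError(
                    f"step {step.name!r}: n_in {step.n_in} != previous n_out {prev_out}"
                )
            prev_out = step.n_out
        if self.steps and self.steps[-1].n_out != self.n_prioritized:
            raise ValidationError("terminal count does not match last step output")
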