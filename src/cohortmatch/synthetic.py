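"""Synthetic rare-disease cohorts with known ground truth.

The generator emits a complete on-disk cohort bundle — participants, a
multi-sample VCF, gene models, a control-population frequency table, a score
table, a mini phenotype ontology and per-gene disease hypotheses — together
with a truth manifest labelling every planted variant occurrence. Planted VOs
come in two kinds:

* **true positives** — VOs constructed to pass all six executable filters of
  the matchmaking workflow (impactful consequence, absent from controls,
  inheritance-compatible zygosity, no unaffected carrier, phenotype-matched
  carrier);
* **decoys** — VOs constructed to be removed at exactly one designated filter
  step and no other, one decoy class per executable filter.

Background VOs are sampled Poisson per participant-gene pair with uniform
positions; most are removable by some filter, but residual survivors are
expected and labelled ``INCIDENTAL`` in the manifest (real cohorts also
surface non-planted survivors). The bundle emulates a rare-disease gene
discovery cohort: families with affected probands and unaffected relatives,
roughly half the cohort affected, and affected participants annotated with
between 1 and 79 phenotype terms.

Everything is deterministic given the seed: the same configuration and seed
reproduce a byte-identical bundle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as cmio
from .models import (
    AffectedStatus,
    Cohort,
    CohortmatchError,
    FrequencyRecord,
    FrequencyTable,
    GeneModel,
    GeneModelSet,
    Inheritance,
    Ontology,
    Participant,
    ScoreRecord,
    ScoreTable,
    Sex,
    Variant,
    Zygosity,
)
from .phenotype import build_profile, overlap_score
from .workflow import DEFAULT_PHENOTYPE_THRESHOLD

__all__ = [
    "DecoyClass",
    "TruthPattern",
    "PlantedTruth",
    "PlantedDecoy",
    "SimConfig",
    "ManifestEntry",
    "build_mini_ontology",
    "default_truth_spec",
    "default_decoy_spec",
    "generate",
    "validation_suite_config",
    "MANIFEST_COLUMNS",
    "HYPOTHESES_COLUMNS",
    "write_manifest",
    "read_manifest",
]


class DecoyClass(enum.Enum):
    """Each decoy class is engineered to fail exactly one workflow filter."""

    LOW_IMPACT_NO_SPLICE = "LOW_IMPACT_NO_SPLICE"
    GNOMAD_HOM = "GNOMAD_HOM"
    WRONG_ZYGOSITY = "WRONG_ZYGOSITY"
    GNOMAD_HET_SEVERE_AD = "GNOMAD_HET_SEVERE_AD"
    UNAFFECTED_CARRIER = "UNAFFECTED_CARRIER"
    PHENOTYPE_MISMATCH = "PHENOTYPE_MISMATCH"


DECOY_EXPECTED_STEP = {
    DecoyClass.LOW_IMPACT_NO_SPLICE: "consequence",
    DecoyClass.GNOMAD_HOM: "gnomad_hom",
    DecoyClass.WRONG_ZYGOSITY: "zygosity",
    DecoyClass.GNOMAD_HET_SEVERE_AD: "gnomad_het",
    DecoyClass.UNAFFECTED_CARRIER: "affected_status",
    DecoyClass.PHENOTYPE_MISMATCH: "phenotype",
}


class TruthPattern(enum.Enum):
    """Zygosity pattern of a planted true positive."""

    HET = "HET"                      # AD
    HOM = "HOM"                      # AR
    COMPHET = "COMPHET"              # AR, two het VOs in one participant
    HEMI = "HEMI"                    # XLR male
    HOM_FEMALE = "HOM_FEMALE"        # XLR female
    COMPHET_FEMALE = "COMPHET_FEMALE"  # XLR female, two het VOs


@dataclass(frozen=True)
class PlantedTruth:
    gene_index: int
    inheritance: Inheritance
    severe_pediatric: bool
    pattern: TruthPattern


@dataclass(frozen=True)
class PlantedDecoy:
    gene_index: int
    decoy_class: DecoyClass


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a desk-scale rare-disease discovery cohort: ~315
    participants in 90 families of 2-5 members, slightly over half affected,
    20 queried genes of 5-60 kb with 4-10 exons, and affected participants
    carrying 1-79 phenotype terms.
    """

    n_families: int = 90
    family_size_range: tuple[int, int] = (2, 5)
    affected_fraction: float = 0.54
    n_genes: int = 20
    gene_span_range: tuple[int, int] = (5_000, 60_000)
    exons_per_gene: tuple[int, int] = (4, 10)
    background_vo_rate: float = 0.15
    hpo_terms_per_affected: tuple[int, int] = (1, 79)
    planted_truth_spec: Optional[list[PlantedTruth]] = None
    planted_decoy_spec: Optional[list[PlantedDecoy]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise CohortmatchError("affected_fraction must be in [0, 1]")
        for name in ("family_size_range", "gene_span_range", "exons_per_gene",
                     "hpo_terms_per_affected"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise CohortmatchError(f"{name} must be an ordered positive range")
        if self.background_vo_rate < 0:
            raise CohortmatchError("background_vo_rate must be non-negative")


@dataclass(frozen=True)
class ManifestEntry:
    """One labelled VO of the truth manifest.

    ``expected_removal_step`` is a workflow step name for decoys, the empty
    string for true positives (expected to survive) and for incidental
    background VOs (no expectation either way).
    """

    variant: Variant
    participant_id: str
    gene_symbol: str
    label: str  # "TRUE_POSITIVE", a DecoyClass name, or "INCIDENTAL"
    expected_removal_step: str


def build_mini_ontology(
    n_systems: int = 8, n_sub: int = 4, n_leaves: int = 6
) -> tuple[Ontology, list[list[list[str]]]]:
    """A deterministic four-level phenotype DAG (~230 terms).

    Level 0 is a single root, level 1 holds ``n_systems`` organ-system terms,
    level 2 ``n_sub`` subcategories per system, level 3 ``n_leaves`` leaf
    findings per subcategory. Returns the ontology and, per system, the term
    lists ``[sub_term, leaf, leaf, ...]`` for each subcategory — disease
    profiles are drawn from single subcategories so that profiles from
    different systems have disjoint closures.
    """
    counter = 1

    def next_id() -> str:
        nonlocal counter
        tid = f"HP:{counter:07d}"
        counter += 1
        return tid

    root = next_id()
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    branches: list[list[list[str]]] = []
    for _ in range(n_systems):
        system = next_id()
        parents[system] = frozenset([root])
        subs = []
        for _ in range(n_sub):
            sub = next_id()
            parents[sub] = frozenset([system])
            terms = [sub]
            for _ in range(n_leaves):
                leaf = next_id()
                parents[leaf] = frozenset([sub])
                terms.append(leaf)
            subs.append(terms)
        branches.append(subs)
    return Ontology(parents), branches


_STREAM_CYCLE = [
    (Inheritance.AD, False, TruthPattern.HET),
    (Inheritance.AR, False, TruthPattern.HOM),
    (Inheritance.XLR, False, TruthPattern.HEMI),
    (Inheritance.AD, True, TruthPattern.HET),
    (Inheritance.AR, False, TruthPattern.COMPHET),
    (Inheritance.XLR, False, TruthPattern.HOM_FEMALE),
    (Inheritance.AD, False, TruthPattern.HET),
    (Inheritance.AR, False, TruthPattern.HOM),
    (Inheritance.XLR, False, TruthPattern.COMPHET_FEMALE),
    (Inheritance.AD, True, TruthPattern.HET),
]


def default_truth_spec(n_genes: int) -> list[PlantedTruth]:
    """One true positive per gene, cycling through all streams and patterns."""
    spec = []
    for i in range(n_genes):
        inh, severe, pattern = _STREAM_CYCLE[i % len(_STREAM_CYCLE)]
        spec.append(PlantedTruth(i, inh, severe, pattern))
    return spec


def default_decoy_spec(truths: Sequence[PlantedTruth]) -> list[PlantedDecoy]:
    """Plant every compatible decoy class in every gene.

    The gnomAD-het decoy only exists on severe pediatric-onset AD genes — on
    any other stream that filter is a no-op.
    """
    spec = []
    for t in truths:
        for cls in (
            DecoyClass.LOW_IMPACT_NO_SPLICE,
            DecoyClass.GNOMAD_HOM,
            DecoyClass.WRONG_ZYGOSITY,
            DecoyClass.UNAFFECTED_CARRIER,
            DecoyClass.PHENOTYPE_MISMATCH,
        ):
            spec.append(PlantedDecoy(t.gene_index, cls))
        if t.inheritance is Inheritance.AD and t.severe_pediatric:
            spec.append(PlantedDecoy(t.gene_index, DecoyClass.GNOMAD_HET_SEVERE_AD))
    return spec


# ---------------------------------------------------------------------------
# generation internals


@dataclass
class _GenePlan:
    model: GeneModel
    inheritance: Inheritance
    severe_pediatric: bool
    system_index: int
    disease_terms: frozenset[str]
    used_positions: set[int] = field(default_factory=set)
    exon_slot: int = 0

    def next_exon_position(self) -> int:
        while True:
            exon = self.model.exons[self.exon_slot % len(self.model.exons)]
            offset = self.exon_slot // len(self.model.exons)
            self.exon_slot += 1
            pos = exon[0] + offset
            if pos > exon[1]:
                raise CohortmatchError(
                    f"gene {self.model.gene_symbol}: exhausted exonic planting slots"
                )
            if pos not in self.used_positions:
                self.used_positions.add(pos)
                return pos

    def deep_intron_position(self) -> int:
        exons = self.model.exons
        for i in range(len(exons) - 1):
            mid = (exons[i][1] + exons[i + 1][0]) // 2
            # stay clear of both splice-site windows
            if exons[i][1] + 10 < mid < exons[i + 1][0] - 10 and mid not in self.used_positions:
                self.used_positions.add(mid)
                return mid
        raise CohortmatchError(
            f"gene {self.model.gene_symbol}: no deep-intronic planting slot"
        )


_BASES = "ACGT"


def _random_snv(rng: np.random.Generator, chrom: str, pos: int) -> Variant:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
    return Variant(chrom, pos, ref, alt)


class _CarrierPools:
    """Deterministic allocation of carriers for planted VOs.

    Affected carriers are used at most once across all plantings (each gets a
    purpose-built phenotype profile); unaffected evidence carriers may be
    reused across genes.
    """

    def __init__(self, cohort_order: list[Participant], rng: np.random.Generator):
        affected = [p for p in cohort_order if p.affected is AffectedStatus.AFFECTED]
        unaffected = [p for p in cohort_order if p.affected is AffectedStatus.UNAFFECTED]
        self.affected = list(affected)
        rng.shuffle(self.affected)  # type: ignore[arg-type]
        self.unaffected = list(unaffected)
        self._unaffected_cursor = 0

    def take_affected(self, sex: Optional[Sex] = None) -> Participant:
        for i, p in enumerate(self.affected):
            if sex is None or p.sex is sex:
                return self.affected.pop(i)
        raise CohortmatchError(
            f"infeasible config: no unused affected participant"
            + (f" of sex {sex.value}" if sex else "")
        )

    def take_unaffected(self, sex: Optional[Sex] = None) -> Participant:
        n = len(self.unaffected)
        if n == 0:
            raise CohortmatchError("infeasible config: cohort has no unaffected participants")
        for k in range(n):
            p = self.unaffected[(self._unaffected_cursor + k) % n]
            if sex is None or p.sex is sex:
                self._unaffected_cursor = (self._unaffected_cursor + k + 1) % n
                return p
        raise CohortmatchError(
            f"infeasible config: no unaffected participant of sex {sex.value}"  # type: ignore[union-attr]
        )


def _truth_zygosities(
    t: PlantedTruth,
) -> tuple[Optional[Sex], list[Zygosity]]:
    """Required carrier sex and per-variant zygosities for a truth pattern."""
    return {
        TruthPattern.HET: (None, [Zygosity.HET]),
        TruthPattern.HOM: (None, [Zygosity.HOM]),
        TruthPattern.COMPHET: (None, [Zygosity.HET, Zygosity.HET]),
        TruthPattern.HEMI: (Sex.MALE, [Zygosity.HEMI]),
        TruthPattern.HOM_FEMALE: (Sex.FEMALE, [Zygosity.HOM]),
        TruthPattern.COMPHET_FEMALE: (Sex.FEMALE, [Zygosity.HET, Zygosity.HET]),
    }[t.pattern]


def _stream_zygosity(plan: _GenePlan) -> tuple[Optional[Sex], Zygosity]:
    """A stream-compatible (sex, zygosity) for decoys that must pass the
    zygosity filter — or at least carry a zygosity writable for the sex."""
    if plan.inheritance is Inheritance.AD:
        return None, Zygosity.HET
    if plan.inheritance is Inheritance.AR:
        return None, Zygosity.HOM
    return Sex.MALE, Zygosity.HEMI


def generate(config: SimConfig, out_dir: Path | str) -> list[ManifestEntry]:
    """Write a full cohort bundle under ``out_dir`` and return the manifest.

    Files written: ``participants.tsv``, ``cohort.vcf``, ``genes.tsv``,
    ``frequency.tsv``, ``scores.tsv``, ``ontology.obo``, ``hypotheses.tsv``
    (per-gene inheritance stream, severity flag and disease phenotype
    profile) and ``truth.tsv`` (the manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    truths = (
        config.planted_truth_spec
        if config.planted_truth_spec is not None
        else default_truth_spec(config.n_genes)
    )
    decoys = (
        config.planted_decoy_spec
        if config.planted_decoy_spec is not None
        else default_decoy_spec(truths)
    )
    for t in truths:
        if not (0 <= t.gene_index < config.n_genes):
            raise CohortmatchError(f"truth gene index {t.gene_index} out of range")
    for d in decoys:
        if not (0 <= d.gene_index < config.n_genes):
            raise CohortmatchError(f"decoy gene index {d.gene_index} out of range")

    ontology, branches = build_mini_ontology()

    # --- participants -----------------------------------------------------
    participants: list[Participant] = []
    lo, hi = config.family_size_range
    avg_size = (lo + hi) / 2
    p_other = 0.0
    if avg_size > 1:
        p_other = min(1.0, max(0.0, (config.affected_fraction * avg_size - 1) / (avg_size - 1)))
    pid_counter = 0
    for f in range(config.n_families):
        family_id = f"F{f + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        for m in range(size):
            pid_counter += 1
            affected = (
                AffectedStatus.AFFECTED
                if m == 0 or rng.random() < p_other
                else AffectedStatus.UNAFFECTED
            )
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            participants.append(
                Participant(
                    participant_id=f"P{pid_counter:05d}",
                    family_id=family_id,
                    sex=sex,
                    affected=affected,
                    hpo_terms=frozenset(["HP:0000001"]) if affected is AffectedStatus.AFFECTED else frozenset(),
                )
            )
    # hpo_terms are assigned properly below; the placeholder above only
    # avoids the "affected without terms" warning during construction.

    # --- genes ------------------------------------------------------------
    truth_by_gene = {t.gene_index: t for t in truths}
    severe_decoy_genes = {
        d.gene_index
        for d in decoys
        if d.decoy_class is DecoyClass.GNOMAD_HET_SEVERE_AD
    }
    plans: list[_GenePlan] = []
    chrom_cursor: dict[str, int] = {}
    autosome_cycle = [str(c) for c in range(1, 23)]
    n_terms_sets = len(branches) * len(branches[0])
    for g in range(config.n_genes):
        t = truth_by_gene.get(g)
        if t is not None:
            inh, severe = t.inheritance, t.severe_pediatric
        elif g in severe_decoy_genes:
            inh, severe = Inheritance.AD, True
        else:
            inh, severe = Inheritance.AD, False
        chrom = "X" if inh is Inheritance.XLR else autosome_cycle[g % 22]
        span = int(rng.integers(config.gene_span_range[0], config.gene_span_range[1] + 1))
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        start = chrom_cursor.get(chrom, 1_000_000)
        chrom_cursor[chrom] = start + span + 1_000_000
        step = span // n_ex
        exon_len = max(50, min(150, step // 3))
        exons = tuple(
            (start + i * step, start + i * step + exon_len - 1) for i in range(n_ex)
        )
        model = GeneModel(
            gene_symbol=f"GENE{g + 1:03d}",
            chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            gene_start=start,
            gene_end=start + span - 1,
            exons=exons,
        )
        slot = g % n_terms_sets
        system_index = slot // len(branches[0])
        sub_index = slot % len(branches[0])
        disease_terms = frozenset(branches[system_index][sub_index][:6])
        plans.append(_GenePlan(model, inh, severe, system_index, disease_terms))

    # --- plant truths and decoys -----------------------------------------
    pools = _CarrierPools(participants, rng)
    vo_registry: dict[Variant, list[tuple[str, Zygosity]]] = {}
    freq_records: list[FrequencyRecord] = []
    score_records: list[ScoreRecord] = []
    manifest: list[ManifestEntry] = []
    planted_pairs: set[tuple[str, int]] = set()
    profile_assignment: dict[str, tuple[str, int]] = {}  # pid -> (kind, gene index)

    def plant(
        variant: Variant, pid: str, zyg: Zygosity, gene_index: int, label: str, step: str
    ) -> None:
        vo_registry.setdefault(variant, []).append((pid, zyg))
        planted_pairs.add((pid, gene_index))
        manifest.append(
            ManifestEntry(variant, pid, plans[gene_index].model.gene_symbol, label, step)
        )

    for t in sorted(truths, key=lambda t: t.gene_index):
        plan = plans[t.gene_index]
        sex, zygs = _truth_zygosities(t)
        carrier = pools.take_affected(sex)
        profile_assignment[carrier.participant_id] = ("overlap", t.gene_index)
        for zyg in zygs:
            v = _random_snv(rng, plan.model.chrom, plan.next_exon_position())
            plant(v, carrier.participant_id, zyg, t.gene_index, "TRUE_POSITIVE", "")
            score_records.append(
                ScoreRecord(v, splice_score=None,
                            deleteriousness_score=round(20 + 15 * float(rng.random()), 2))
            )

    for d in sorted(decoys, key=lambda d: (d.gene_index, d.decoy_class.value)):
        plan = plans[d.gene_index]
        cls = d.decoy_class
        step = DECOY_EXPECTED_STEP[cls]
        label = cls.value

        if cls is DecoyClass.GNOMAD_HET_SEVERE_AD and not (
            plan.inheritance is Inheritance.AD and plan.severe_pediatric
        ):
            raise CohortmatchError(
                f"gnomAD-het decoy requires a severe pediatric AD gene; "
                f"{plan.model.gene_symbol} is {plan.inheritance.value}"
            )

        if cls is DecoyClass.LOW_IMPACT_NO_SPLICE:
            sex, zyg = _stream_zygosity(plan)
            carrier = pools.take_affected(sex)
            profile_assignment[carrier.participant_id] = ("overlap", d.gene_index)
            v = _random_snv(rng, plan.model.chrom, plan.deep_intron_position())
            plant(v, carrier.participant_id, zyg, d.gene_index, label, step)
            score_records.append(
                ScoreRecord(v, splice_score=round(0.05 + 0.3 * float(rng.random()), 3),
                            deleteriousness_score=round(5 * float(rng.random()), 2))
            )
        elif cls is DecoyClass.GNOMAD_HOM:
            sex, zyg = _stream_zygosity(plan)
            carrier = pools.take_affected(sex)
            profile_assignment[carrier.participant_id] = ("overlap", d.gene_index)
            v = _random_snv(rng, plan.model.chrom, plan.next_exon_position())
            plant(v, carrier.participant_id, zyg, d.gene_index, label, step)
            freq_records.append(
                FrequencyRecord(v, af=round(1e-3 * float(rng.random()) + 1e-4, 6),
                                n_het=int(rng.integers(5, 50)), n_hom=int(rng.integers(1, 5)))
            )
        elif cls is DecoyClass.WRONG_ZYGOSITY:
            if plan.inheritance is Inheritance.AD:
                sex, zyg = (Sex.FEMALE, Zygosity.HOM) if plan.model.chrom == "X" else (None, Zygosity.HOM)
            elif plan.inheritance is Inheritance.AR:
                sex, zyg = None, Zygosity.HET  # single het, no partner
            else:  # XLR: a lone heterozygous female matches no keep rule
                sex, zyg = Sex.FEMALE, Zygosity.HET
            carrier = pools.take_affected(sex)
            profile_assignment[carrier.participant_id] = ("overlap", d.gene_index)
            v = _random_snv(rng, plan.model.chrom, plan.next_exon_position())
            plant(v, carrier.participant_id, zyg, d.gene_index, label, step)
        elif cls is DecoyClass.GNOMAD_HET_SEVERE_AD:
            carrier = pools.take_affected(None)
            profile_assignment[carrier.participant_id] = ("overlap", d.gene_index)
            v = _random_snv(rng, plan.model.chrom, plan.next_exon_position())
            plant(v, carrier.participant_id, Zygosity.HET, d.gene_index, label, step)
            # rare enough that the published relaxation (AF <= 1e-4) rescues it
            freq_records.append(
                FrequencyRecord(v, af=round(5e-5 * float(rng.random()) + 1e-5, 8),
                                n_het=int(rng.integers(1, 5)), n_hom=0)
            )
        elif cls is DecoyClass.UNAFFECTED_CARRIER:
            sex, zyg = _stream_zygosity(plan)
            carrier = pools.take_affected(sex)
            evidence = pools.take_unaffected(sex)
            profile_assignment[carrier.participant_id] = ("overlap", d.gene_index)
            v = _random_snv(rng, plan.model.chrom, plan.next_exon_position())
            plant(v, carrier.participant_id, zyg, d.gene_index, label, step)
            plant(v, evidence.participant_id, zyg, d.gene_index, label, step)
        elif cls is DecoyClass.PHENOTYPE_MISMATCH:
            sex, zyg = _stream_zygosity(plan)
            carrier = pools.take_affected(sex)
            profile_assignment[carrier.participant_id] = ("mismatch", d.gene_index)
            v = _random_snv(rng, plan.model.chrom, plan.next_exon_position())
            plant(v, carrier.participant_id, zyg, d.gene_index, label, step)

    # --- phenotype profiles ----------------------------------------------
    all_terms = sorted(ontology.terms - ontology.roots())
    lo_t, hi_t = config.hpo_terms_per_affected
    new_terms: dict[str, frozenset[str]] = {}
    for p in participants:
        if p.affected is not AffectedStatus.AFFECTED:
            continue
        kind, gidx = profile_assignment.get(p.participant_id, ("random", -1))
        if kind == "overlap":
            plan = plans[gidx]
            leaves = sorted(plan.disease_terms)[1:]  # drop the subcategory term
            k = int(rng.integers(2, len(leaves) + 1))
            chosen = list(rng.choice(leaves, size=k, replace=False))
            n_noise = int(rng.integers(0, 6))
            noise_pool = [t for t in all_terms if t not in plan.disease_terms]
            chosen += list(rng.choice(noise_pool, size=n_noise, replace=False))
            terms = frozenset(chosen)
            score = overlap_score(
                build_profile(terms, ontology),
                build_profile(plan.disease_terms, ontology),
            )
            if score < DEFAULT_PHENOTYPE_THRESHOLD:
                raise CohortmatchError("internal: overlap profile below threshold")
        elif kind == "mismatch":
            plan = plans[gidx]
            other_systems = [
                i for i in range(len(branches)) if i != plan.system_index
            ]
            sys_i = other_systems[int(rng.integers(len(other_systems)))]
            pool = [t for sub in branches[sys_i] for t in sub]
            k = int(rng.integers(1, min(hi_t, len(pool)) + 1))
            terms = frozenset(rng.choice(pool, size=k, replace=False))
        else:
            k = int(rng.integers(lo_t, hi_t + 1))
            k = min(k, len(all_terms))
            terms = frozenset(rng.choice(all_terms, size=k, replace=False))
        new_terms[p.participant_id] = terms
    participants = [
        Participant(
            p.participant_id,
            p.family_id,
            p.sex,
            p.affected,
            new_terms.get(p.participant_id, frozenset()),
            p.candidate_genes,
            p.causal_genes,
        )
        for p in participants
    ]
    cohort = Cohort(participants)

    # --- background VOs ---------------------------------------------------
    if config.background_vo_rate > 0:
        for gene_index, plan in enumerate(plans):
            for p in participants:
                if (p.participant_id, gene_index) in planted_pairs:
                    continue
                n = int(rng.poisson(config.background_vo_rate))
                for _ in range(n):
                    for _attempt in range(20):
                        pos = int(
                            rng.integers(plan.model.gene_start, plan.model.gene_end + 1)
                        )
                        if pos not in plan.used_positions:
                            break
                    else:
                        continue
                    plan.used_positions.add(pos)
                    v = _random_snv(rng, plan.model.chrom, pos)
                    if plan.model.chrom == "X" and p.sex is Sex.MALE:
                        zyg = Zygosity.HEMI
                    else:
                        zyg = Zygosity.HOM if rng.random() < 0.05 else Zygosity.HET
                    vo_registry.setdefault(v, []).append((p.participant_id, zyg))
                    manifest.append(
                        ManifestEntry(v, p.participant_id, plan.model.gene_symbol,
                                      "INCIDENTAL", "")
                    )
                    # most background variants are removable by some filter
                    if rng.random() < 0.7:
                        if rng.random() < 0.5:
                            freq_records.append(
                                FrequencyRecord(
                                    v,
                                    af=round(1e-3 * float(rng.random()) + 1e-4, 6),
                                    n_het=int(rng.integers(1, 40)),
                                    n_hom=int(rng.integers(1, 4)),
                                )
                            )
                        else:
                            freq_records.append(
                                FrequencyRecord(
                                    v,
                                    af=round(1e-3 * float(rng.random()) + 1e-4, 6),
                                    n_het=int(rng.integers(1, 40)),
                                    n_hom=0,
                                )
                            )
                    if rng.random() < 0.5:
                        score_records.append(
                            ScoreRecord(
                                v,
                                splice_score=round(0.45 * float(rng.random()), 3),
                                deleteriousness_score=round(40 * float(rng.random()), 2),
                            )
                        )

    # --- write bundle -----------------------------------------------------
    cmio.write_participants(cohort, out / "participants.tsv")
    cmio.write_gene_models(GeneModelSet([p.model for p in plans]), out / "genes.tsv")
    cmio.write_frequency_table(FrequencyTable(freq_records), out / "frequency.tsv")
    cmio.write_score_table(ScoreTable(score_records), out / "scores.tsv")
    cmio.write_ontology(ontology, out / "ontology.obo")
    _write_vcf(vo_registry, cohort, out / "cohort.vcf")
    _write_hypotheses(plans, out / "hypotheses.tsv")
    manifest.sort(key=lambda e: (*e.variant.key(), e.participant_id))
    write_manifest(manifest, out / "truth.tsv")
    return manifest


def _chrom_order(chrom: str) -> tuple[int, str]:
    return (int(chrom), chrom) if chrom.isdigit() else (100, chrom)


def _write_vcf(
    registry: dict[Variant, list[tuple[str, Zygosity]]],
    cohort: Cohort,
    path: Path,
) -> None:
    sample_ids = sorted(cohort.ids)
    sexes = {pid: cohort[pid].sex for pid in sample_ids}
    variants = sorted(registry, key=lambda v: (_chrom_order(v.chrom), v.pos, v.ref, v.alt))
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    contigs.sort(key=_chrom_order)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for v in variants:
            carriers = dict(registry[v])
            male_x = v.chrom.upper() in ("X", "CHRX")
            gts = []
            for pid in sample_ids:
                haploid = male_x and sexes[pid] is Sex.MALE
                zyg = carriers.get(pid)
                if zyg is None:
                    gts.append("0" if haploid else "0/0")
                elif zyg is Zygosity.HEMI:
                    gts.append("1")
                elif zyg is Zygosity.HOM:
                    gts.append("1" if haploid else "1/1")
                else:
                    gts.append("0/1")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


HYPOTHESES_COLUMNS = ["gene", "inheritance", "severe_pediatric", "disease_hpo_terms"]


def _write_hypotheses(plans: Sequence[_GenePlan], path: Path) -> None:
    import csv

    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HYPOTHESES_COLUMNS)
        for p in sorted(plans, key=lambda p: p.model.gene_symbol):
            w.writerow(
                [
                    p.model.gene_symbol,
                    p.inheritance.value,
                    int(p.severe_pediatric),
                    ";".join(sorted(p.disease_terms)),
                ]
            )


MANIFEST_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "participant",
    "gene",
    "class",
    "expected_removal_step",
]


def write_manifest(manifest: Sequence[ManifestEntry], path: Path | str) -> None:
    import csv

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for e in manifest:
            v = e.variant
            w.writerow(
                [v.chrom, v.pos, v.ref, v.alt, e.participant_id, e.gene_symbol,
                 e.label, e.expected_removal_step]
            )


def read_manifest(path: Path | str) -> list[ManifestEntry]:
    import csv

    entries = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entries.append(
                ManifestEntry(
                    Variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                    row["participant"],
                    row["gene"],
                    row["class"],
                    row["expected_removal_step"],
                )
            )
    return entries


def validation_suite_config(
    seed: int = 0, include_failures: bool = True
) -> SimConfig:
    """The workflow-validation reconstruction: 140 genes, one planted
    candidate VO each.

    124 genes carry a VO that passes every executable filter; 6 carry a VO
    sitting just outside a canonical splice site without splice-impact
    support (removed by the consequence filter), 9 are severe pediatric AD
    genes whose VO is present at very low frequency in the control
    population (removed by the gnomAD het filter; rescued when that filter
    is relaxed to admit control AF <= 1e-4), and 1 carries a VO also present
    in an unaffected relative (removed by the affected-status filter). With
    ``include_failures=False`` all 140 genes carry passing VOs.
    """
    n_genes = 140
    truths: list[PlantedTruth] = []
    decoys: list[PlantedDecoy] = []
    consequence_fail = set(range(0, 6))
    gnomad_het_fail = set(range(6, 15))
    affected_fail = {15}
    # stream mix for the passing genes, dominated by recessive hypotheses
    passing_cycle = [
        (Inheritance.AR, False, TruthPattern.HOM),
        (Inheritance.AD, False, TruthPattern.HET),
        (Inheritance.AR, False, TruthPattern.COMPHET),
        (Inheritance.AR, False, TruthPattern.HOM),
        (Inheritance.AD, True, TruthPattern.HET),
        (Inheritance.XLR, False, TruthPattern.HEMI),
        (Inheritance.AR, False, TruthPattern.HOM),
        (Inheritance.AD, False, TruthPattern.HET),
        (Inheritance.AR, False, TruthPattern.COMPHET),
        (Inheritance.XLR, False, TruthPattern.HOM_FEMALE),
    ]
    k = 0
    for g in range(n_genes):
        # failure genes carry ONLY the failing construction: their single
        # candidate VO is removed at the designated step, so the gene fails
        if include_failures and g in consequence_fail:
            decoys.append(PlantedDecoy(g, DecoyClass.LOW_IMPACT_NO_SPLICE))
        elif include_failures and g in gnomad_het_fail:
            decoys.append(PlantedDecoy(g, DecoyClass.GNOMAD_HET_SEVERE_AD))
        elif include_failures and g in affected_fail:
            decoys.append(PlantedDecoy(g, DecoyClass.UNAFFECTED_CARRIER))
        else:
            inh, severe, pattern = passing_cycle[k % len(passing_cycle)]
            k += 1
            truths.append(PlantedTruth(g, inh, severe, pattern))
    return SimConfig(
        n_families=160,
        family_size_range=(2, 2),
        affected_fraction=0.5,
        n_genes=n_genes,
        gene_span_range=(4_000, 8_000),
        exons_per_gene=(4, 6),
        background_vo_rate=0.0,
        planted_truth_spec=truths,
        planted_decoy_spec=decoys,
        seed=seed,
    )
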