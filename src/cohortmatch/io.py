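"""Readers and writers for every on-disk format the toolkit touches.

Formats
-------
- participants: TSV with columns ``id, family, sex, affected, hpo_terms,
  candidate_genes, causal_genes``; list-valued columns are ``;``-delimited.
- cohort variants: VCF 4.2+ (plain or bgzipped) with GT; read via cyvcf2.
- gene models: 6-column TSV (``gene, chrom, strand, start, end, exons``) or
  GFF3 with ``gene``/``exon`` features.
- control frequency table: TSV ``chrom, pos, ref, alt, af, n_het, n_hom,
  n_hemi``.
- score table: TSV ``chrom, pos, ref, alt, splice_score, cadd`` (empty
  cells mean "no prediction").
- ontology: OBO, ``is_a`` edges only (via obonet).
- result tables: TSV, one VO per row (or one unique variant per row in
  consolidated mode); audit reports: JSON.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from pathlib import Path
from typing import Optional, Union

import obonet

from .models import (
    AffectedStatus,
    AnnotatedVO,
    Cohort,
    ConsequenceClass,
    FilterReport,
    FilterStep,
    FrequencyRecord,
    FrequencyTable,
    GeneModel,
    GeneModelSet,
    Ontology,
    Participant,
    ScoreRecord,
    ScoreTable,
    Sex,
    ValidationError,
    Variant,
    VariantOccurrence,
    VOStore,
    Zygosity,
    is_x_contig,
    normalize_variant,
)

PathLike = Union[str, Path]

_TERM_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d+$")

PARTICIPANT_COLUMNS = [
    "id",
    "family",
    "sex",
    "affected",
    "hpo_terms",
    "candidate_genes",
    "causal_genes",
]


def _split_list(cell: str) -> frozenset[str]:
    return frozenset(x for x in (s.strip() for s in cell.split(";")) if x)


def load_participants(path: PathLike) -> Cohort:
    """Read a participant TSV into a :class:`Cohort`.

    Raises :class:`ValidationError` naming the offending line on malformed
    rows, duplicate ids, or HPO term ids that do not match the ``PREFIX:digits``
    syntax. Affected participants without HPO terms are accepted with a
    warning (emitted by the :class:`Participant` constructor).
    """
    path = Path(path)
    cohort = Cohort()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PARTICIPANT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(
                f"{path}: missing participant columns: {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                terms = _split_list(row["hpo_terms"])
                for t in terms:
                    if not _TERM_ID_RE.match(t):
                        raise ValidationError(f"malformed term id {t!r}")
                p = Participant(
                    participant_id=row["id"].strip(),
                    family_id=row["family"].strip(),
                    sex=Sex[row["sex"].strip().upper()],
                    affected=AffectedStatus[row["affected"].strip().upper()],
                    hpo_terms=terms,
                    candidate_genes=_split_list(row["candidate_genes"]),
                    causal_genes=_split_list(row["causal_genes"]),
                )
                if not p.participant_id:
                    raise ValidationError("empty participant id")
            except (KeyError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            cohort.add(p)
    return cohort


def write_participants(cohort: Cohort, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PARTICIPANT_COLUMNS)
        for p in sorted(cohort, key=lambda p: p.participant_id):
            w.writerow(
                [
                    p.participant_id,
                    p.family_id,
                    p.sex.value,
                    p.affected.value,
                    ";".join(sorted(p.hpo_terms)),
                    ";".join(sorted(p.candidate_genes)),
                    ";".join(sorted(p.causal_genes)),
                ]
            )


_BASES_RE = re.compile(r"^[ACGTN]+$", re.IGNORECASE)


def load_vcf(path: PathLike, cohort: Cohort, strict: bool = True) -> VOStore:
    """Read a multi-sample VCF into a :class:`VOStore`.

    One VO is produced per (decomposed alt, sample) pair with a non-reference
    called genotype. Multi-allelic records are decomposed into per-alt
    variants before zygosity assignment; each alt is normalized independently.
    Phase separators are ignored; genotypes containing a missing allele
    (``./1``) yield no VO. On the X chromosome a male's non-reference call —
    haploid or homozygous diploid — is HEMI; UNKNOWN-sex participants are
    treated as diploid (no HEMI). Symbolic and spanning-deletion alts are
    skipped with a warning.

    With ``strict=True`` (default) a VCF sample missing from the cohort is an
    error; otherwise it is skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples: list[str] = list(vcf.samples)
    keep_idx: list[int] = []
    for i, s in enumerate(samples):
        if s in cohort:
            keep_idx.append(i)
        elif strict:
            raise ValidationError(f"VCF sample {s!r} not present in cohort")
        else:
            warnings.warn(f"VCF sample {s!r} not in cohort; skipping")

    store = VOStore()
    for rec in vcf:
        alts = rec.ALT or []
        genotypes = rec.genotypes  # [allele1, allele2, phased] or [allele, phased]
        for alt_index, alt in enumerate(alts, start=1):
            if not alt or not _BASES_RE.match(alt):
                warnings.warn(
                    f"skipping non-sequence alt {alt!r} at {rec.CHROM}:{rec.POS}"
                )
                continue
            try:
                variant = normalize_variant(
                    Variant(rec.CHROM, rec.POS, rec.REF.upper(), alt.upper())
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"non-normalizable record at {rec.CHROM}:{rec.POS}: {exc}"
                ) from None
            for i in keep_idx:
                gt = genotypes[i]
                alleles = [a for a in gt[:-1]]  # strip phased flag
                if any(a < 0 for a in alleles):
                    continue  # missing or half-call
                n_alt = sum(1 for a in alleles if a == alt_index)
                if n_alt == 0:
                    continue
                participant = cohort[samples[i]]
                zyg = _assign_zygosity(
                    n_alt, len(alleles), participant.sex, variant.chrom
                )
                store.add(VariantOccurrence(variant, participant.participant_id, zyg))
    return store


def _assign_zygosity(n_alt: int, ploidy: int, sex: Sex, chrom: str) -> Zygosity:
    male_x = sex is Sex.MALE and is_x_contig(chrom)
    if ploidy == 1:
        return Zygosity.HEMI if male_x else Zygosity.HOM
    if n_alt >= ploidy:
        return Zygosity.HEMI if male_x else Zygosity.HOM
    return Zygosity.HET


GENE_MODEL_COLUMNS = ["gene", "chrom", "strand", "start", "end", "exons"]


def load_gene_models(path: PathLike) -> GeneModelSet:
    """Read gene models from the 6-column TSV or from GFF3 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _load_gene_models_gff3(path)
    models = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(GENE_MODEL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(
                f"{path}: missing gene model columns: {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                exons = []
                for chunk in row["exons"].split(";"):
                    chunk = chunk.strip()
                    if not chunk:
                        continue
                    s, _, e = chunk.partition("-")
                    exons.append((int(s), int(e)))
                models.append(
                    GeneModel(
                        gene_symbol=row["gene"].strip(),
                        chrom=row["chrom"].strip(),
                        strand=row["strand"].strip(),
                        gene_start=int(row["start"]),
                        gene_end=int(row["end"]),
                        exons=tuple(exons),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return GeneModelSet(models)


def _load_gene_models_gff3(path: Path) -> GeneModelSet:
    genes: dict[str, dict] = {}
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    with path.open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(f"{path}: short GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                symbol = attr.get("gene_name") or attr.get("Name") or attr.get("ID")
                if not symbol:
                    raise ValidationError(f"{path}: gene feature without a name")
                genes[symbol] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": int(start),
                    "end": int(end),
                }
            elif ftype == "exon":
                parent = attr.get("gene_name") or attr.get("Parent")
                if parent:
                    exons_by_gene.setdefault(parent, []).append((int(start), int(end)))
    models = []
    for symbol, g in genes.items():
        exons = sorted(set(exons_by_gene.get(symbol, [])))
        models.append(
            GeneModel(symbol, g["chrom"], g["strand"], g["start"], g["end"], tuple(exons))
        )
    return GeneModelSet(models)


def write_gene_models(models: GeneModelSet, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_MODEL_COLUMNS)
        for m in sorted(models, key=lambda m: m.gene_symbol):
            w.writerow(
                [
                    m.gene_symbol,
                    m.chrom,
                    m.strand,
                    m.gene_start,
                    m.gene_end,
                    ";".join(f"{s}-{e}" for s, e in m.exons),
                ]
            )


FREQUENCY_COLUMNS = ["chrom", "pos", "ref", "alt", "af", "n_het", "n_hom", "n_hemi"]
SCORE_COLUMNS = ["chrom", "pos", "ref", "alt", "splice_score", "cadd"]


def load_frequency_table(path: PathLike) -> FrequencyTable:
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(FREQUENCY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(
                f"{path}: missing frequency columns: {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    FrequencyRecord(
                        Variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                        af=float(row["af"]),
                        n_het=int(row["n_het"]),
                        n_hom=int(row["n_hom"]),
                        n_hemi=int(row["n_hemi"]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return FrequencyTable(records)


def write_frequency_table(table: FrequencyTable, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(FREQUENCY_COLUMNS)
        for r in table.records():
            v = r.variant
            w.writerow([v.chrom, v.pos, v.ref, v.alt, _fmt(r.af), r.n_het, r.n_hom, r.n_hemi])


def load_score_table(path: PathLike) -> ScoreTable:
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SCORE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(
                f"{path}: missing score columns: {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    ScoreRecord(
                        Variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                        splice_score=_opt_float(row["splice_score"]),
                        deleteriousness_score=_opt_float(row["cadd"]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return ScoreTable(records)


def write_score_table(table: ScoreTable, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SCORE_COLUMNS)
        for r in table.records():
            v = r.variant
            w.writerow(
                [v.chrom, v.pos, v.ref, v.alt, _fmt(r.splice_score), _fmt(r.deleteriousness_score)]
            )


def load_ontology(path: PathLike) -> Ontology:
    """Parse an OBO file into an :class:`Ontology`, keeping ``is_a`` edges only."""
    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return Ontology({t: frozenset(ps) for t, ps in parents.items()})


def write_ontology(ont: Ontology, path: PathLike, name_prefix: str = "term") -> None:
    """Write an ontology as minimal OBO (ids, names, is_a edges)."""
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: cohortmatch-mini\n")
        for term in sorted(ont.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {name_prefix} {term}\n")
            for p in sorted(ont.parents(term)):
                fh.write(f"is_a: {p}\n")


RESULT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "participant_id",
    "zygosity",
    "consequence",
    "cohort_af",
    "n_het_cohort",
    "n_hom_cohort",
    "n_hemi_cohort",
    "burden",
    "control_af",
    "control_n_het",
    "control_n_hom",
    "control_n_hemi",
    "splice_score",
    "cadd",
    "affected",
    "sex",
    "hpo_terms",
    "candidate_genes",
    "causal_genes",
]

CONSOLIDATED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "cohort_af",
    "n_het_cohort",
    "n_hom_cohort",
    "n_hemi_cohort",
    "n_occurrences",
    "participants",
    "control_af",
    "control_n_het",
    "control_n_hom",
    "control_n_hemi",
    "splice_score",
    "cadd",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _opt_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    return float(cell) if cell else None


def _opt_int(cell: str) -> Optional[int]:
    cell = cell.strip()
    return int(cell) if cell else None


def write_result_table(
    rows: list[AnnotatedVO], path: PathLike, consolidate: bool = False
) -> None:
    """Write annotated VOs as TSV — one VO per row, or one unique variant per
    row when ``consolidate`` is set."""
    if consolidate:
        _write_consolidated(rows, path)
        return
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        for r in sorted(rows, key=lambda r: r.vo.sort_key()):
            v = r.variant
            w.writerow(
                [
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    r.participant_id,
                    r.zygosity.value,
                    r.consequence.value if r.consequence else "",
                    _fmt(r.cohort_af),
                    r.n_het_cohort,
                    r.n_hom_cohort,
                    r.n_hemi_cohort,
                    r.burden,
                    _fmt(r.control_af),
                    _fmt(r.control_n_het),
                    _fmt(r.control_n_hom),
                    _fmt(r.control_n_hemi),
                    _fmt(r.splice_score),
                    _fmt(r.deleteriousness_score),
                    r.affected.value,
                    r.sex.value,
                    ";".join(sorted(r.hpo_terms)),
                    ";".join(sorted(r.candidate_genes)),
                    ";".join(sorted(r.causal_genes)),
                ]
            )


def _write_consolidated(rows: list[AnnotatedVO], path: PathLike) -> None:
    by_variant: dict[Variant, list[AnnotatedVO]] = {}
    for r in rows:
        by_variant.setdefault(r.variant, []).append(r)
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CONSOLIDATED_COLUMNS)
        for v in sorted(by_variant, key=Variant.key):
            group = by_variant[v]
            first = group[0]
            w.writerow(
                [
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    first.consequence.value if first.consequence else "",
                    _fmt(first.cohort_af),
                    first.n_het_cohort,
                    first.n_hom_cohort,
                    first.n_hemi_cohort,
                    len(group),
                    ";".join(sorted(r.participant_id for r in group)),
                    _fmt(first.control_af),
                    _fmt(first.control_n_het),
                    _fmt(first.control_n_hom),
                    _fmt(first.control_n_hemi),
                    _fmt(first.splice_score),
                    _fmt(first.deleteriousness_score),
                ]
            )


def read_result_table(path: PathLike) -> list[AnnotatedVO]:
    """Read back a per-VO result TSV written by :func:`write_result_table`."""
    path = Path(path)
    rows = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(RESULT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(
                f"{path}: missing result columns: {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                vo = VariantOccurrence(
                    Variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                    row["participant_id"],
                    Zygosity[row["zygosity"]],
                )
                rows.append(
                    AnnotatedVO(
                        vo=vo,
                        consequence=(
                            ConsequenceClass[row["consequence"]]
                            if row["consequence"]
                            else None
                        ),
                        cohort_af=_opt_float(row["cohort_af"]),
                        n_het_cohort=int(row["n_het_cohort"]),
                        n_hom_cohort=int(row["n_hom_cohort"]),
                        n_hemi_cohort=int(row["n_hemi_cohort"]),
                        burden=int(row["burden"]),
                        control_af=_opt_float(row["control_af"]),
                        control_n_het=_opt_int(row["control_n_het"]),
                        control_n_hom=_opt_int(row["control_n_hom"]),
                        control_n_hemi=_opt_int(row["control_n_hemi"]),
                        splice_score=_opt_float(row["splice_score"]),
                        deleteriousness_score=_opt_float(row["cadd"]),
                        affected=AffectedStatus[row["affected"]],
                        sex=Sex[row["sex"]],
                        hpo_terms=_split_list(row["hpo_terms"]),
                        candidate_genes=_split_list(row["candidate_genes"]),
                        causal_genes=_split_list(row["causal_genes"]),
                    )
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return rows


REPORT_SCHEMA_VERSION = 1


def write_report(report: FilterReport, path: PathLike) -> None:
    """Serialize a filter audit report as versioned JSON."""
    report.validate()
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "steps": [
            {
                "name": s.name,
                "n_in": s.n_in,
                "n_removed": s.n_removed,
                "n_out": s.n_out,
                "removed_fraction": s.removed_fraction,
            }
            for s in report.steps
        ],
        "n_prioritized": report.n_prioritized,
        "n_participants": report.n_participants,
        "n_variants": report.n_variants,
        "terminal_note": report.terminal_note,
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: PathLike) -> FilterReport:
    with Path(path).open() as fh:
        doc = json.load(fh)
    report = FilterReport(
        steps=[
            FilterStep(s["name"], s["n_in"], s["n_removed"]) for s in doc["steps"]
        ],
        n_prioritized=doc["n_prioritized"],
        n_participants=doc["n_participants"],
        n_variants=doc["n_variants"],
        terminal_note=doc["terminal_note"],
    )
    report.validate()
    return report
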