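"""End-to-end orchestration over an on-disk cohort bundle.

A *bundle* is the directory layout the synthetic generator writes (and that
a real deployment would assemble from its own sources): participant records,
a multi-sample VCF, gene models, control frequency and score tables, the
phenotype ontology, and per-gene disease hypotheses. This module loads a
bundle once and runs query → annotate → filter for any of its genes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import io as cmio
from .annotation import annotate
from .models import (
    Cohort,
    CohortmatchError,
    FrequencyTable,
    GeneModelSet,
    Inheritance,
    Ontology,
    ScoreTable,
    VOStore,
)
from .query import GeneQuery, QueryResult, query_gene
from .synthetic import HYPOTHESES_COLUMNS
from .workflow import WorkflowConfig, WorkflowOutput, run_workflow

__all__ = ["GeneHypothesis", "Bundle", "load_bundle", "run_gene"]

BUNDLE_FILES = {
    "participants": "participants.tsv",
    "vcf": "cohort.vcf",
    "genes": "genes.tsv",
    "frequency": "frequency.tsv",
    "scores": "scores.tsv",
    "ontology": "ontology.obo",
    "hypotheses": "hypotheses.tsv",
}


@dataclass(frozen=True)
class GeneHypothesis:
    """One disease-gene hypothesis: stream, severity and disease phenotype."""

    gene_symbol: str
    inheritance: Inheritance
    severe_pediatric: bool
    disease_hpo_terms: frozenset[str]


@dataclass
class Bundle:
    cohort: Cohort
    store: VOStore
    models: GeneModelSet
    frequency: FrequencyTable
    scores: ScoreTable
    ontology: Ontology
    hypotheses: dict[str, GeneHypothesis]


def _load_hypotheses(path: Path) -> dict[str, GeneHypothesis]:
    out: dict[str, GeneHypothesis] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(HYPOTHESES_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise CohortmatchError(
                f"{path}: missing hypothesis columns: {', '.join(sorted(missing))}"
            )
        for row in reader:
            terms = frozenset(
                t for t in (s.strip() for s in row["disease_hpo_terms"].split(";")) if t
            )
            out[row["gene"]] = GeneHypothesis(
                gene_symbol=row["gene"],
                inheritance=Inheritance[row["inheritance"]],
                severe_pediatric=bool(int(row["severe_pediatric"])),
                disease_hpo_terms=terms,
            )
    return out


def load_bundle(bundle_dir: Path | str, strict: bool = True) -> Bundle:
    """Load every component of a cohort bundle directory."""
    d = Path(bundle_dir)
    for f in BUNDLE_FILES.values():
        if not (d / f).exists():
            raise CohortmatchError(f"bundle {d} is missing {f}")
    cohort = cmio.load_participants(d / BUNDLE_FILES["participants"])
    store = cmio.load_vcf(d / BUNDLE_FILES["vcf"], cohort, strict=strict)
    return Bundle(
        cohort=cohort,
        store=store,
        models=cmio.load_gene_models(d / BUNDLE_FILES["genes"]),
        frequency=cmio.load_frequency_table(d / BUNDLE_FILES["frequency"]),
        scores=cmio.load_score_table(d / BUNDLE_FILES["scores"]),
        ontology=cmio.load_ontology(d / BUNDLE_FILES["ontology"]),
        hypotheses=_load_hypotheses(d / BUNDLE_FILES["hypotheses"]),
    )


def run_gene(
    bundle: Bundle,
    gene_symbol: str,
    max_cohort_af: float = 0.01,
    gnomad_het_relax_af: Optional[float] = None,
    phenotype_threshold: Optional[float] = None,
) -> tuple[QueryResult, WorkflowOutput]:
    """Query, annotate and filter one gene of a bundle under its hypothesis."""
    hyp = bundle.hypotheses.get(gene_symbol)
    if hyp is None:
        raise CohortmatchError(f"no disease hypothesis recorded for {gene_symbol!r}")
    result = query_gene(
        GeneQuery(gene_symbol, max_cohort_af=max_cohort_af),
        bundle.store,
        bundle.cohort,
        bundle.models,
    )
    annotate(result, bundle.frequency, bundle.scores, bundle.models)
    kwargs = {}
    if phenotype_threshold is not None:
        kwargs["phenotype_threshold"] = phenotype_threshold
    config = WorkflowConfig(
        inheritance=hyp.inheritance,
        severe_pediatric=hyp.severe_pediatric,
        disease_hpo_terms=hyp.disease_hpo_terms,
        gnomad_het_relax_af=gnomad_het_relax_af,
        **kwargs,
    )
    output = run_workflow(result.rows, config, bundle.cohort, bundle.ontology)
    return result, output
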