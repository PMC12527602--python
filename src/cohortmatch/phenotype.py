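"""Phenotype-ontology reasoning: ancestor closures and overlap scoring.

A participant's phenotype and a queried disease's phenotype are each a set of
ontology terms. Comparing raw term sets is too brittle — two clinicians may
annotate the same finding at different granularity — so both sets are expanded
to their *ancestor closure* (every term plus all of its ``is_a`` ancestors,
excluding the ontology root, which carries no information) before comparison.

The overlap score is closure recall: the fraction of the disease closure
covered by the participant closure. Matchmaking asks "could this participant
plausibly have the queried disease?", so coverage of the disease profile is
the relevant direction; a participant with many additional unrelated findings
is not penalized. Symmetric (Jaccard) and information-content-weighted
variants are deliberate non-features of this release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .models import CohortmatchError, Ontology

__all__ = ["TermSetProfile", "ancestor_closure", "overlap_score", "build_profile"]


@dataclass(frozen=True)
class TermSetProfile:
    """A raw term set together with its ancestor closure."""

    raw_terms: frozenset[str]
    closure: frozenset[str]


def _term_depths(ont: Ontology) -> dict[str, int]:
    """Minimum distance of each term from a root (roots have depth 0)."""
    depths: dict[str, int] = {}

    def depth(term: str) -> int:
        if term in depths:
            return depths[term]
        parents = ont.parents(term)
        d = 0 if not parents else 1 + min(depth(p) for p in parents)
        depths[term] = d
        return d

    for t in ont.terms:
        depth(t)
    return depths


def ancestor_closure(
    terms: Iterable[str], ont: Ontology, min_depth: int = 1
) -> frozenset[str]:
    """The least superset of ``terms`` closed under the parent relation.

    Terms shallower than ``min_depth`` are dropped from the closure; the
    default of 1 excludes exactly the ontology root(s), whose presence in
    every closure would create trivial overlap between any two profiles.
    Terms not present in the ontology are skipped with a warning.
    """
    depths = _term_depths(ont)
    closure: set[str] = set()
    stack = []
    for t in terms:
        if t not in ont:
            warnings.warn(f"unknown ontology term {t!r}; skipping")
            continue
        stack.append(t)
    while stack:
        t = stack.pop()
        if t in closure:
            continue
        closure.add(t)
        stack.extend(ont.parents(t))
    return frozenset(t for t in closure if depths[t] >= min_depth)


def build_profile(
    terms: Iterable[str], ont: Ontology, min_depth: int = 1
) -> TermSetProfile:
    raw = frozenset(terms)
    return TermSetProfile(raw_terms=raw, closure=ancestor_closure(raw, ont, min_depth))


def overlap_score(participant: TermSetProfile, disease: TermSetProfile) -> float:
    """Closure recall of the disease profile by the participant profile.

    Returns ``|participant.closure ∩ disease.closure| / |disease.closure|``,
    in [0, 1]. Monotone non-decreasing in the participant's term set.
    """
    if not disease.closure:
        raise CohortmatchError("disease profile has an empty closure")
    return len(participant.closure & disease.closure) / len(disease.closure)
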