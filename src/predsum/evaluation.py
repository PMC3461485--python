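"""Scoring summarizer output against a reference standard.

Precision is measured over *subject groups*: summary predications of the
accepted point-of-view form (``Intervention X TREATS disease Y`` for
treatment, ``X PREVENTS Y`` plus configured extras for prevention) are
grouped by normalized subject name, and precision is the fraction of groups
expressing a true-positive intervention.  Recall is the fraction of
reference-standard interventions claimed by at least one group; F1 is their
harmonic mean.  Inter-annotator agreement is the simple proportion
matches / (matches + non-matches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Predication,
    PredicationSet,
    ReferenceStandard,
    normalize_name,
)

#: Core accepted predicates per point of view.
POV_PREDICATES = {
    "treatment": frozenset({"TREATS"}),
    "prevention": frozenset({"PREVENTS"}),
    "none": frozenset(),
}


@dataclass(frozen=True)
class SubjectGroup:
    """All accepted summary records sharing one normalized subject name."""

    name: str
    display_name: str
    records: tuple[Predication, ...]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class EvaluationReport:
    recall: float
    precision: float
    f1: float
    matched_interventions: tuple[str, ...]
    unmatched_interventions: tuple[str, ...]
    subject_groups_total: int
    subject_groups_true: int
    precision_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "matched_interventions": list(self.matched_interventions),
            "unmatched_interventions": list(self.unmatched_interventions),
            "subject_groups_total": self.subject_groups_total,
            "subject_groups_true": self.subject_groups_true,
            "precision_defined": self.precision_defined,
        }


def f1_score(precision: float, recall: float) -> float:
    """Balanced F-measure; 0 when both components vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def group_subjects(
    summary: PredicationSet,
    pov: str,
    disease_names: Iterable[str],
    extra_predicates: Iterable[str] = (),
    include_negated: bool = False,
) -> list[SubjectGroup]:
    """Group accepted summary records by normalized subject name.

    Core-form records (TREATS/PREVENTS) must have an object matching a
    disease name.  Extra predicates — prevention-adjacent relations such as
    AFFECTS or USES whose relevance is established independently — are
    admitted without the object constraint, and only under the prevention
    point of view.
    """
    if pov not in POV_PREDICATES:
        raise ValueError(f"unknown point of view {pov!r}")
    core = POV_PREDICATES[pov]
    extras = (
        frozenset(p.upper() for p in extra_predicates)
        if pov == "prevention"
        else frozenset()
    )
    diseases = {normalize_name(n) for n in disease_names}
    grouped: dict[str, list[Predication]] = {}
    display: dict[str, str] = {}
    for rec in summary:
        if rec.negated and not include_negated:
            continue
        if rec.predicate in core:
            if rec.object_key not in diseases:
                continue
        elif rec.predicate not in extras:
            continue
        key = rec.subject_key
        grouped.setdefault(key, []).append(rec)
        display.setdefault(key, rec.subject_name)
    return [
        SubjectGroup(name=key, display_name=display[key], records=tuple(recs))
        for key, recs in grouped.items()
    ]


def match_reference(
    groups: Sequence[SubjectGroup],
    ref: ReferenceStandard,
    synonyms: Optional[Mapping[str, str]] = None,
) -> EvaluationReport:
    """Match subject groups to reference interventions and compute R/P/F1.

    A group is a true positive when its subject name — or its alias under the
    supplied synonym map — normalizes to a reference entry.  The alias map
    makes manual matching judgments explicit and auditable; there is no fuzzy
    matching.
    """
    if len(ref) == 0:
        raise ValueError("reference standard must be non-empty")
    alias = {
        normalize_name(k): normalize_name(v) for k, v in (synonyms or {}).items()
    }
    ref_set = set(ref.interventions)
    matched: set[str] = set()
    true_groups = 0
    for group in groups:
        candidates = {group.name, alias.get(group.name, group.name)}
        hits = candidates & ref_set
        if hits:
            true_groups += 1
            matched |= hits
    total = len(groups)
    precision_defined = total > 0
    precision = true_groups / total if precision_defined else 0.0
    recall = len(matched) / len(ref)
    matched_ordered = tuple(i for i in ref.interventions if i in matched)
    unmatched = tuple(i for i in ref.interventions if i not in matched)
    return EvaluationReport(
        recall=recall,
        precision=precision,
        f1=f1_score(precision, recall),
        matched_interventions=matched_ordered,
        unmatched_interventions=unmatched,
        subject_groups_total=total,
        subject_groups_true=true_groups,
        precision_defined=precision_defined,
    )


def groups_from_terms(terms: Iterable[str]) -> list[SubjectGroup]:
    """Degenerate one-term-per-group structure for evaluating bare term lists
    (baseline outputs) with the same matcher as predication summaries."""
    groups = []
    seen = set()
    for term in terms:
        key = normalize_name(term)
        if key and key not in seen:
            seen.add(key)
            groups.append(SubjectGroup(name=key, display_name=term, records=()))
    return groups


def iaa(agreements: int, disagreements: int) -> float:
    """Inter-annotator agreement: matches / (matches + non-matches)."""
    if agreements < 0 or disagreements < 0:
        raise ValueError("counts must be non-negative")
    if agreements + disagreements == 0:
        raise ValueError("at least one annotation instance is required")
    return agreements / (agreements + disagreements)
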