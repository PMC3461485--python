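"""The first three tiers of the summarization cascade.

The cascade refines a predication dataset toward a user-selected disease
(the *seed topic*) in sequential, record-wise tiers:

* **Novelty** drops vague predications whose arguments are too general to be
  informative (e.g. ``pharmaceutical preparation TREATS patients``), using a
  configurable stoplist of generic concept names.
* **Relevance** keeps predications in which the seed topic appears as the
  subject or the object.
* **Connectivity** augments the relevant records with predications that share
  a semantic type with a non-seed argument of a relevant record (e.g. other
  ``phsu``-typed drugs once one drug is known to treat the seed disease).

A generic static-pattern filter is also provided for schema-style filtering
by (subject semtype, predicate, object semtype) triples with wildcards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import Predication, PredicationSet, normalize_name

logger = logging.getLogger(__name__)

#: Generic concept names removed by default in the Novelty tier.
DEFAULT_STOPLIST_NAMES = (
    "pharmaceutical preparation",
    "pharmaceutical preparations",
    "patients",
    "intervention regimes",
    "therapeutic procedure",
)

WILDCARD = "*"


@dataclass(frozen=True)
class SeedTopic:
    """The user-selected concept anchoring Relevance filtering.

    ``names`` may hold several labels treated as the same topic (e.g.
    "Congestive heart failure" and "Heart failure"); matching is by
    normalized-name equality, never substring.
    """

    names: frozenset[str]
    semtypes: frozenset[str] = frozenset()

    @classmethod
    def of(cls, *names: str, semtypes: Iterable[str] = ()) -> "SeedTopic":
        keys = frozenset(normalize_name(n) for n in names if n.strip())
        if not keys:
            raise ValueError("seed topic needs at least one non-empty name")
        return cls(names=keys, semtypes=frozenset(semtypes))

    def matches(self, concept_name: str) -> bool:
        return normalize_name(concept_name) in self.names

    def bears_seed(self, record: Predication) -> bool:
        return self.matches(record.subject_name) or self.matches(record.object_name)


@dataclass(frozen=True)
class NoveltyStoplist:
    """Concept names considered too general to be informative."""

    generic_names: frozenset[str]

    @classmethod
    def of(cls, names: Iterable[str] = DEFAULT_STOPLIST_NAMES) -> "NoveltyStoplist":
        return cls(generic_names=frozenset(normalize_name(n) for n in names))

    def __contains__(self, concept_name: str) -> bool:
        return normalize_name(concept_name) in self.generic_names


def novelty_filter(data: PredicationSet, stop: NoveltyStoplist) -> PredicationSet:
    """Drop predications whose subject or object name is on the stoplist."""
    kept = [
        r
        for r in data
        if r.subject_name not in stop and r.object_name not in stop
    ]
    if not kept and len(data):
        logger.warning("novelty filter removed every predication")
    return data.replace_records(kept)


def relevance_filter(data: PredicationSet, seed: SeedTopic) -> PredicationSet:
    """Keep predications whose subject or object is a seed-topic name."""
    kept = [r for r in data if seed.bears_seed(r)]
    if not kept:
        logger.warning("seed topic %s matched no predication", sorted(seed.names))
    return data.replace_records(kept)


def licensed_semtypes(
    relevant: PredicationSet, seed: SeedTopic, positions: str = "both"
) -> dict[str, frozenset[str]]:
    """Semantic types of non-seed arguments in the relevant records.

    Returns per-position sets keyed ``"subject"``/``"object"``.  With
    ``positions="both"`` (default) the union is mirrored into both slots, so
    a candidate may match on either argument; ``positions="same"`` keeps the
    sets position-specific.
    """
    if positions not in ("both", "same"):
        raise ValueError("positions must be 'both' or 'same'")
    by_pos = {"subject": set(), "object": set()}
    for rec in relevant:
        sub_is_seed = seed.matches(rec.subject_name)
        obj_is_seed = seed.matches(rec.object_name)
        if sub_is_seed and not obj_is_seed:
            by_pos["object"].update(rec.object_semtypes)
        elif obj_is_seed and not sub_is_seed:
            by_pos["subject"].update(rec.subject_semtypes)
        # both-seed records contribute no non-seed argument
    if positions == "both":
        merged = frozenset(by_pos["subject"] | by_pos["object"])
        return {"subject": merged, "object": merged}
    return {k: frozenset(v) for k, v in by_pos.items()}


def connectivity_filter(
    data: PredicationSet,
    relevant: PredicationSet,
    seed: SeedTopic,
    positions: str = "both",
) -> PredicationSet:
    """Predications from ``data`` minus ``relevant`` sharing a licensed semtype.

    The licensed semantic types are those carried by the non-seed arguments
    of the relevant records; the output is disjoint from ``relevant`` under
    multiset record identity.
    """
    licensed = licensed_semtypes(relevant, seed, positions)
    remaining = data.subtract(relevant)
    kept = [
        r
        for r in remaining
        if (set(r.subject_semtypes) & licensed["subject"])
        or (set(r.object_semtypes) & licensed["object"])
    ]
    return data.replace_records(kept)


Pattern = tuple[str, str, str]


def _slot_matches(slot: str, values: Sequence[str]) -> bool:
    return slot == WILDCARD or slot in values


def static_pattern_filter(
    data: PredicationSet, patterns: Sequence[Pattern]
) -> PredicationSet:
    """Keep predications matching any (subject-semtype, predicate, object-semtype)
    triple; ``*`` is a wildcard in any slot."""
    if not patterns:
        raise ValueError("at least one pattern is required")
    kept = []
    for rec in data:
        for sub_st, predicate, obj_st in patterns:
            if (
                _slot_matches(sub_st, rec.subject_semtypes)
                and (predicate == WILDCARD or predicate.upper() == rec.predicate)
                and _slot_matches(obj_st, rec.object_semtypes)
            ):
                kept.append(rec)
                break
    return data.replace_records(kept)


def parse_pattern(text: str) -> Pattern:
    """Parse a ``"subject_semtype predicate object_semtype"`` config entry."""
    parts = text.split()
    if len(parts) != 3:
        raise ValueError(f"pattern must have three fields, got {text!r}")
    return (parts[0], parts[1], parts[2])
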