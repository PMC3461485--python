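"""Core data model for semantic predications and their companion tables.

A *semantic predication* is a subject--predicate--object assertion extracted
from biomedical citation text, e.g. ``cetuximab[phsu] TREATS Endometrial
carcinoma[neop]``.  Each argument carries one or more UMLS-style semantic-type
codes (``phsu`` = pharmacological substance, ``neop`` = neoplastic process);
the predicate is an uppercase relation label drawn from an open vocabulary
(TREATS, PREVENTS, AFFECTS, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import Counter
from typing import Iterable, Iterator, Mapping


class PredsumError(Exception):
    """Base class for package errors."""


class EmptyInputError(PredsumError):
    """An input file or dataset contained no usable records."""


class FormatError(PredsumError):
    """An input file violated its declared format."""


def normalize_name(name: str) -> str:
    """Normalize a concept name: collapse internal whitespace, lower-case.

    Matching throughout the package (seed topics, stoplists, reference
    standards, alias maps) is by equality of normalized names; no synonym
    expansion is attempted.
    """
    return " ".join(name.split()).lower()


def _clean_semtypes(semtypes: Iterable[str]) -> tuple[str, ...]:
    out = tuple(s.strip() for s in semtypes if s and s.strip())
    if not out:
        raise ValueError("semantic-type list must have at least one entry")
    return out


@dataclass(frozen=True)
class Predication:
    """One subject--predicate--object assertion with provenance.

    Instances are immutable and hashable; duplicate predications are
    meaningful (frequency drives saliency scoring) and are kept as separate
    records in a :class:`PredicationSet`.
    """

    subject_name: str
    subject_semtypes: tuple[str, ...]
    predicate: str
    object_name: str
    object_semtypes: tuple[str, ...]
    citation_id: str = ""
    negated: bool = False
    sentence_text: str = ""

    def __post_init__(self) -> None:
        subject = " ".join(self.subject_name.split())
        obj = " ".join(self.object_name.split())
        predicate = self.predicate.strip().upper()
        if not subject or not obj:
            raise ValueError("argument names must be non-empty")
        if not predicate:
            raise ValueError("predicate must be non-empty")
        object.__setattr__(self, "subject_name", subject)
        object.__setattr__(self, "object_name", obj)
        object.__setattr__(self, "predicate", predicate)
        object.__setattr__(
            self, "subject_semtypes", _clean_semtypes(self.subject_semtypes)
        )
        object.__setattr__(
            self, "object_semtypes", _clean_semtypes(self.object_semtypes)
        )

    @property
    def subject_key(self) -> str:
        return normalize_name(self.subject_name)

    @property
    def object_key(self) -> str:
        return normalize_name(self.object_name)

    def all_semtypes(self) -> frozenset[str]:
        return frozenset(self.subject_semtypes) | frozenset(self.object_semtypes)


@dataclass(frozen=True)
class PredicationSet:
    """An ordered collection of predications.

    Iteration order is the input order and is stable; duplicates are allowed.
    """

    records: tuple[Predication, ...]
    provenance: str = ""

    @classmethod
    def from_records(
        cls, records: Iterable[Predication], provenance: str = ""
    ) -> "PredicationSet":
        return cls(records=tuple(records), provenance=provenance)

    def __iter__(self) -> Iterator[Predication]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    def replace_records(self, records: Iterable[Predication]) -> "PredicationSet":
        return replace(self, records=tuple(records))

    def predicate_counts(self, include_negated: bool = False) -> Counter:
        """Absolute predicate frequencies over (by default non-negated) records."""
        return Counter(
            p.predicate
            for p in self.records
            if include_negated or not p.negated
        )

    def without_negations(self) -> "PredicationSet":
        return self.replace_records(p for p in self.records if not p.negated)

    def subtract(self, other: "PredicationSet") -> "PredicationSet":
        """Multiset difference preserving this set's record order."""
        remaining = Counter(other.records)
        kept = []
        for rec in self.records:
            if remaining[rec] > 0:
                remaining[rec] -= 1
            else:
                kept.append(rec)
        return self.replace_records(kept)


@dataclass(frozen=True)
class BackgroundDistribution:
    """Predicate -> count table for a broad literature corpus (distribution Q).

    Stands in for a large citation database processed into predications; the
    query corpus's predicate distribution (P) is compared against it to find
    point-of-view-enriched predicates.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for predicate, count in self.counts.items():
            if not predicate or not predicate.strip():
                raise ValueError("background predicates must be non-empty")
            if count < 0:
                raise ValueError(f"negative count for predicate {predicate!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def rel_freq(self, predicate: str) -> float:
        total = self.total
        if total == 0:
            return 0.0
        return self.counts.get(predicate, 0) / total

    def rel_freqs(self) -> dict[str, float]:
        """Relative frequencies of predicates with non-zero counts."""
        total = self.total
        return {p: c / total for p, c in self.counts.items() if c > 0}


@dataclass(frozen=True)
class ReferenceStandard:
    """A vetted list of intervention names serving as evaluation ground truth."""

    interventions: tuple[str, ...]
    pairing_label: str = ""

    @classmethod
    def from_lines(
        cls, lines: Iterable[str], pairing_label: str = ""
    ) -> "ReferenceStandard":
        """Build from raw lines: normalize, drop blanks, de-duplicate in order."""
        seen: dict[str, None] = {}
        for line in lines:
            key = normalize_name(line)
            if key and key not in seen:
                seen[key] = None
        if not seen:
            raise EmptyInputError("reference standard contains no interventions")
        return cls(interventions=tuple(seen), pairing_label=pairing_label)

    def __len__(self) -> int:
        return len(self.interventions)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.interventions
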