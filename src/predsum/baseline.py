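"""Term-frequency baseline summarizer.

Simulates what a busy reader might notice when scanning retrieved citations:
count term occurrences, then retain the terms whose frequency exceeds the
group mean plus one standard deviation.  For a prevention-oriented corpus the
input lines are first restricted to those containing prevention trigger
phrases, and terms in excluded categories (e.g. the disorders themselves)
can be removed through a configurable category map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import EmptyInputError, normalize_name

#: Trigger phrases marking a line as prevention-relevant (case-insensitive
#: substring match); configurable per call.
DEFAULT_PREVENTION_PHRASES = (
    "prevent",
    "prevents",
    "for prevention of",
    "for the prevention of",
)


@dataclass(frozen=True)
class TermFrequencyTable:
    """Term -> positive occurrence count for one disease/point-of-view group."""

    counts: Mapping[str, int]
    group_label: str = ""

    def __post_init__(self) -> None:
        for term, count in self.counts.items():
            if count < 1:
                raise ValueError(f"count for {term!r} must be >= 1")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def unique_terms(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class BaselineResult:
    """Mean/SD threshold and the terms retained above it."""

    mean: float
    sd: float
    threshold: float
    retained: tuple[tuple[str, int], ...]


def frequency_threshold(
    table: TermFrequencyTable, sd_mode: str = "population"
) -> BaselineResult:
    """Retain terms whose count strictly exceeds mean + 1 SD.

    The standard deviation is the population SD of the count multiset by
    default (the table is the whole group, not a sample); ``sd_mode="sample"``
    switches to the n-1 denominator.  Retained terms are sorted by descending
    count, then term.
    """
    if table.unique_terms == 0:
        raise EmptyInputError("empty term-frequency table")
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    counts = np.array(list(table.counts.values()), dtype=float)
    mean = float(counts.mean())
    ddof = 0 if sd_mode == "population" else 1
    sd = float(counts.std(ddof=ddof)) if counts.size > ddof else 0.0
    threshold = mean + sd
    retained = sorted(
        ((t, c) for t, c in table.counts.items() if c > threshold),
        key=lambda tc: (-tc[1], tc[0]),
    )
    return BaselineResult(
        mean=mean, sd=sd, threshold=threshold, retained=tuple(retained)
    )


def prevention_line_filter(
    citation_text: Iterable[str],
    phrases: Sequence[str] = DEFAULT_PREVENTION_PHRASES,
) -> list[str]:
    """Keep lines containing any trigger phrase (case-insensitive substring)."""
    lowered = [p.lower() for p in phrases]
    return [
        line
        for line in citation_text
        if any(p in line.lower() for p in lowered)
    ]


def category_exclusion(
    table: TermFrequencyTable,
    category_map: Mapping[str, str],
    excluded: set[str],
) -> TermFrequencyTable:
    """Drop terms whose mapped category is excluded; unmapped terms stay."""
    norm_map = {normalize_name(t): c.lower() for t, c in category_map.items()}
    excluded_lower = {c.lower() for c in excluded}
    kept = {
        term: count
        for term, count in table.counts.items()
        if norm_map.get(normalize_name(term)) not in excluded_lower
    }
    return TermFrequencyTable(counts=kept, group_label=table.group_label)


_TOKEN = re.compile(r"[a-z0-9][a-z0-9'-]*")


def tokenize_terms(lines: Iterable[str], group_label: str = "") -> TermFrequencyTable:
    """Whitespace/punctuation fallback tokenizer building a term table.

    A stand-in for concept extraction: lower-cases, strips punctuation edges,
    counts single-word tokens.  Adequate for fixtures and demonstrations only.
    """
    counts: dict[str, int] = {}
    for line in lines:
        for token in _TOKEN.findall(line.lower()):
            counts[token] = counts.get(token, 0) + 1
    if not counts:
        raise EmptyInputError("no tokens found")
    return TermFrequencyTable(counts=counts, group_label=group_label)
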