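"""Dynamic saliency scoring of predication patterns ("Combo" scoring).

The saliency tier ranks (semantic type, predicate) patterns by the product of
three terms and keeps the predications matching the best patterns:

* a per-predicate **Kullback--Leibler enrichment term**
  ``P(x) * log2(P(x)/Q(x))`` comparing the query corpus's predicate
  distribution P against a broad background distribution Q — large when a
  predicate is over-represented in the query, signed (negative when
  under-represented);
* an **RlogF pattern-relevance term**
  ``log2(f) * f/F`` where ``f`` is the pattern's absolute frequency and ``F``
  the absolute frequency of all semantic types paired with that predicate —
  a frequency-weighted conditional relevance, zero for singletons;
* a **PredScal scaling factor** ``1/log2(c)`` (``1`` when ``c = 1``), with
  ``c`` the number of unique predicates in the dataset, which shrinks raw
  RlogF magnitudes onto the KLD scale.

Patterns are profiled separately for the relevance tier (seed-bearing
records; the semantic type comes from the argument opposite the seed) and the
connectivity tier (records admitted by a shared non-seed semantic type; the
semantic type is the one that licensed inclusion).  The final summary keeps
the top ``k`` patterns of each tier (``k = 4`` by default).
"""

from __future__ import annotations

import difflib
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .filters import (
    DEFAULT_STOPLIST_NAMES,
    NoveltyStoplist,
    SeedTopic,
    connectivity_filter,
    licensed_semtypes,
    novelty_filter,
    relevance_filter,
)
from .model import (
    BackgroundDistribution,
    EmptyInputError,
    Predication,
    PredicationSet,
)

logger = logging.getLogger(__name__)

RELEVANCE = "relevance"
CONNECTIVITY = "connectivity"


class EmptyRelevanceError(EmptyInputError):
    """The seed topic matched nothing; carries nearest-name suggestions."""

    def __init__(self, seed: SeedTopic, suggestions: Sequence[str]):
        self.suggestions = list(suggestions)
        hint = f"; nearest names: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(
            f"seed topic {sorted(seed.names)} matched no predication{hint}"
        )


@dataclass(frozen=True)
class PredicateDistribution:
    """Relative predicate frequencies; zero-frequency predicates are absent."""

    rel_freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = {p: f for p, f in self.rel_freqs.items() if f > 0}
        if freqs:
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"relative frequencies sum to {total}, not 1")
        object.__setattr__(self, "rel_freqs", freqs)

    def __contains__(self, predicate: str) -> bool:
        return predicate in self.rel_freqs

    def __getitem__(self, predicate: str) -> float:
        return self.rel_freqs[predicate]

    @classmethod
    def from_background(
        cls, background: BackgroundDistribution
    ) -> "PredicateDistribution":
        if background.total == 0:
            raise EmptyInputError("background distribution has zero total")
        return cls(rel_freqs=background.rel_freqs())


def predicate_distribution(
    data: PredicationSet, include_negated: bool = False
) -> PredicateDistribution:
    """Relative predicate frequencies of a dataset (distribution P)."""
    counts = data.predicate_counts(include_negated=include_negated)
    n = sum(counts.values())
    if n == 0:
        raise EmptyInputError("no (non-negated) predications to profile")
    return PredicateDistribution(rel_freqs={p: c / n for p, c in counts.items()})


@dataclass(frozen=True)
class KLDResult:
    """Per-predicate KLD terms over the shared support of P and Q.

    ``terms[x] = P(x) * log2(P(x)/Q(x))`` for each predicate present in both
    distributions; ``divergence`` is their sum.  Predicates of P absent from
    Q receive no term and are listed in ``unscored_predicates``.
    """

    terms: Mapping[str, float]
    divergence: float
    unscored_predicates: tuple[str, ...]


def kld_terms(
    p: PredicateDistribution,
    q: PredicateDistribution,
    smoothing: float = 0.0,
) -> KLDResult:
    """Per-predicate KLD enrichment terms of P against Q.

    With ``smoothing`` alpha > 0, Q is additively smoothed over the union
    vocabulary (add-alpha on pseudo-counts of Q's relative frequencies), so
    every predicate of P receives a term; by default only the shared support
    is scored.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if smoothing > 0:
        vocab = set(p.rel_freqs) | set(q.rel_freqs)
        denom = 1.0 + smoothing * len(vocab)
        q_eff = {x: (q.rel_freqs.get(x, 0.0) + smoothing) / denom for x in vocab}
    else:
        q_eff = dict(q.rel_freqs)
    terms: dict[str, float] = {}
    unscored: list[str] = []
    for x, px in p.rel_freqs.items():
        qx = q_eff.get(x, 0.0)
        if qx > 0:
            terms[x] = px * math.log2(px / qx)
        else:
            unscored.append(x)
    return KLDResult(
        terms=terms,
        divergence=sum(terms.values()),
        unscored_predicates=tuple(sorted(unscored)),
    )


def rlogf(freq_pattern: int, freq_predicate_total: int) -> float:
    """RlogF relevance of a pattern: ``log2(f) * f/F``.

    ``f`` is the absolute frequency of the semantic type within the
    predicate's patterns and ``F`` the absolute frequency of all semantic
    types paired with the predicate; ``1 <= f <= F`` is required.
    """
    if freq_pattern < 1:
        raise ValueError("pattern frequency must be >= 1")
    if freq_pattern > freq_predicate_total:
        raise ValueError("pattern frequency cannot exceed the predicate total")
    return math.log2(freq_pattern) * (freq_pattern / freq_predicate_total)


def predscal(c: int) -> float:
    """Predicate-count scaling factor ``1/log2(c)``; defined as 1 for c = 1."""
    if c < 1:
        raise ValueError("unique-predicate count must be >= 1")
    if c == 1:
        return 1.0
    return 1.0 / math.log2(c)


@dataclass(frozen=True, order=True)
class PatternKey:
    """A (semantic type, predicate) pattern tagged with its cascade tier."""

    semtype: str
    predicate: str
    tier: str

    def __post_init__(self) -> None:
        if not self.semtype or not self.predicate:
            raise ValueError("semtype and predicate must be non-empty")
        if self.tier not in (RELEVANCE, CONNECTIVITY):
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class DatasetProfile:
    """Pattern frequencies and the unique-predicate count of a dataset.

    ``predicate_totals[p]`` is the summed frequency of every semantic type
    paired with predicate ``p`` across the profiled patterns (the RlogF
    denominator); ``unique_predicate_count`` is ``c`` in the PredScal factor.
    """

    unique_predicate_count: int
    pattern_counts: Mapping[PatternKey, int]
    predicate_totals: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.unique_predicate_count < 1:
            raise ValueError("unique_predicate_count must be >= 1")
        totals: dict[str, int] = {}
        for key, count in self.pattern_counts.items():
            if count < 1:
                raise ValueError("pattern counts must be >= 1")
            totals[key.predicate] = totals.get(key.predicate, 0) + count
        if totals != dict(self.predicate_totals):
            raise ValueError("predicate_totals inconsistent with pattern_counts")


def _semtype_counts(
    semtypes: Iterable[str], multi_semtype: bool
) -> tuple[str, ...]:
    semtypes = tuple(semtypes)
    if not semtypes:
        return ()
    return semtypes if multi_semtype else semtypes[:1]


def build_profile(
    relevant: PredicationSet,
    connectivity: PredicationSet,
    seed: SeedTopic,
    unique_predicate_count: int,
    multi_semtype: bool = True,
    positions: str = "both",
) -> DatasetProfile:
    """Profile relevance- and connectivity-tier patterns.

    Relevance patterns pair a record's predicate with the semantic type(s) of
    the argument opposite the seed; connectivity patterns pair the predicate
    with the semantic type(s) that licensed the record's inclusion.  In
    multi-semtype mode (default) an argument carrying several types
    contributes one count per type.
    """
    counts: dict[PatternKey, int] = {}

    def bump(semtype: str, predicate: str, tier: str) -> None:
        key = PatternKey(semtype=semtype, predicate=predicate, tier=tier)
        counts[key] = counts.get(key, 0) + 1

    for rec in relevant:
        sub_is_seed = seed.matches(rec.subject_name)
        obj_is_seed = seed.matches(rec.object_name)
        if sub_is_seed and not obj_is_seed:
            opposite = rec.object_semtypes
        elif obj_is_seed and not sub_is_seed:
            opposite = rec.subject_semtypes
        else:
            continue  # both arguments are the seed: no non-seed pattern
        for st in _semtype_counts(opposite, multi_semtype):
            bump(st, rec.predicate, RELEVANCE)

    licensed = licensed_semtypes(relevant, seed, positions)
    for rec in connectivity:
        matching = tuple(
            dict.fromkeys(
                [st for st in rec.subject_semtypes if st in licensed["subject"]]
                + [st for st in rec.object_semtypes if st in licensed["object"]]
            )
        )
        for st in _semtype_counts(matching, multi_semtype):
            bump(st, rec.predicate, CONNECTIVITY)

    totals: dict[str, int] = {}
    for key, count in counts.items():
        totals[key.predicate] = totals.get(key.predicate, 0) + count
    return DatasetProfile(
        unique_predicate_count=unique_predicate_count,
        pattern_counts=counts,
        predicate_totals=totals,
    )


@dataclass(frozen=True)
class ScoredPattern:
    """A pattern with its score components; ``combo`` is their exact product.

    ``kld_term`` and ``combo`` are ``None`` for patterns whose predicate has
    no KLD term (absent from the background's support); such patterns are
    excluded from ranking.
    """

    key: PatternKey
    frequency: int
    rlogf: float
    predscal: float
    kld_term: Optional[float] = None

    @property
    def combo(self) -> Optional[float]:
        if self.kld_term is None:
            return None
        return self.kld_term * self.rlogf * self.predscal


def score_patterns(
    profile: DatasetProfile, klds: Mapping[str, float]
) -> list[ScoredPattern]:
    """Score every profiled pattern: ``combo = KLD term x RlogF x PredScal``."""
    scale = predscal(profile.unique_predicate_count)
    scored = []
    for key in sorted(profile.pattern_counts):
        freq = profile.pattern_counts[key]
        scored.append(
            ScoredPattern(
                key=key,
                frequency=freq,
                rlogf=rlogf(freq, profile.predicate_totals[key.predicate]),
                predscal=scale,
                kld_term=klds.get(key.predicate),
            )
        )
    return scored


def _rank_key(sp: ScoredPattern):
    # descending combo, then descending frequency, then (semtype, predicate)
    return (-sp.combo, -sp.frequency, sp.key.semtype, sp.key.predicate)


def select_top(
    scored: Sequence[ScoredPattern], top_k: int = 4
) -> dict[str, list[ScoredPattern]]:
    """The ``top_k`` highest-combo patterns per tier, deterministically ordered."""
    selection: dict[str, list[ScoredPattern]] = {}
    for tier in (RELEVANCE, CONNECTIVITY):
        ranked = sorted(
            (sp for sp in scored if sp.key.tier == tier and sp.combo is not None),
            key=_rank_key,
        )
        selection[tier] = ranked[:top_k]
    return selection


@dataclass(frozen=True)
class SummaryConfig:
    """Tunable knobs of the dynamic summarizer (defaults follow the method)."""

    stoplist: NoveltyStoplist = field(
        default_factory=lambda: NoveltyStoplist.of(DEFAULT_STOPLIST_NAMES)
    )
    top_k: int = 4
    smoothing: float = 0.0
    include_negated: bool = False
    multi_semtype: bool = True
    connectivity_positions: str = "both"
    use_summed_kld: bool = False


@dataclass(frozen=True)
class SummaryResult:
    """Selected patterns, the predications matching them, and diagnostics."""

    selected_relevance: tuple[ScoredPattern, ...]
    selected_connectivity: tuple[ScoredPattern, ...]
    predications: PredicationSet
    diagnostics: tuple[ScoredPattern, ...]
    kld: KLDResult
    profile: DatasetProfile
    no_enrichment: bool

    @property
    def selected_patterns(self) -> tuple[ScoredPattern, ...]:
        return self.selected_relevance + self.selected_connectivity


def _nearest_names(seed: SeedTopic, data: PredicationSet, n: int = 5) -> list[str]:
    names = sorted(
        {r.subject_name for r in data} | {r.object_name for r in data}
    )
    pool: list[str] = []
    for target in sorted(seed.names):
        pool.extend(difflib.get_close_matches(target, names, n=n, cutoff=0.3))
    return list(dict.fromkeys(pool))[:n]


def _matches_selected(
    rec: Predication,
    selected: Sequence[ScoredPattern],
    semtypes_for_rec: Sequence[str],
) -> bool:
    carried = set(semtypes_for_rec)
    return any(
        sp.key.predicate == rec.predicate and sp.key.semtype in carried
        for sp in selected
    )


def summarize(
    data: PredicationSet,
    seed: SeedTopic,
    background: BackgroundDistribution,
    config: SummaryConfig | None = None,
) -> SummaryResult:
    """Run the full cascade: Novelty, Relevance, Connectivity, then saliency.

    The predicate distribution P is computed from the entire novelty-filtered
    dataset (not just seed-bearing records) and compared against the
    background Q; patterns are profiled, scored and the top ``top_k`` of each
    tier selected; the returned predication set holds every relevance- or
    connectivity-tier record matching a selected pattern, in input order
    within each tier.
    """
    config = config or SummaryConfig()
    if not len(data):
        raise EmptyInputError("no predications to summarize")
    if background.total == 0:
        raise EmptyInputError("empty background distribution")

    working = data if config.include_negated else data.without_negations()
    novel = novelty_filter(working, config.stoplist)
    if not len(novel):
        raise EmptyInputError("novelty filter removed every predication")
    relevant = relevance_filter(novel, seed)
    if not len(relevant):
        raise EmptyRelevanceError(seed, _nearest_names(seed, novel))
    connectivity = connectivity_filter(
        novel, relevant, seed, positions=config.connectivity_positions
    )

    p = predicate_distribution(novel, include_negated=config.include_negated)
    q = PredicateDistribution.from_background(background)
    kld = kld_terms(p, q, smoothing=config.smoothing)
    if config.use_summed_kld:
        term_map = {x: kld.divergence for x in kld.terms}
    else:
        term_map = dict(kld.terms)

    c = len(p.rel_freqs)
    profile = build_profile(
        relevant,
        connectivity,
        seed,
        unique_predicate_count=c,
        multi_semtype=config.multi_semtype,
        positions=config.connectivity_positions,
    )
    scored = score_patterns(profile, term_map)
    selection = select_top(scored, top_k=config.top_k)
    ranked = [sp for sp in scored if sp.combo is not None]
    no_enrichment = bool(ranked) and all(sp.combo == 0 for sp in ranked)
    if no_enrichment:
        logger.warning(
            "no enrichment: every combo score is 0; selection falls back to "
            "tie-break order"
        )

    licensed = licensed_semtypes(
        relevant, seed, positions=config.connectivity_positions
    )
    out: list[Predication] = []
    for rec in relevant:
        sub_is_seed = seed.matches(rec.subject_name)
        obj_is_seed = seed.matches(rec.object_name)
        if sub_is_seed and not obj_is_seed:
            opposite = rec.object_semtypes
        elif obj_is_seed and not sub_is_seed:
            opposite = rec.subject_semtypes
        else:
            continue
        if _matches_selected(rec, selection[RELEVANCE], opposite):
            out.append(rec)
    for rec in connectivity:
        matching = [
            st for st in rec.subject_semtypes if st in licensed["subject"]
        ] + [st for st in rec.object_semtypes if st in licensed["object"]]
        if _matches_selected(rec, selection[CONNECTIVITY], matching):
            out.append(rec)

    return SummaryResult(
        selected_relevance=tuple(selection[RELEVANCE]),
        selected_connectivity=tuple(selection[CONNECTIVITY]),
        predications=data.replace_records(out),
        diagnostics=tuple(scored),
        kld=kld,
        profile=profile,
        no_enrichment=no_enrichment,
    )
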