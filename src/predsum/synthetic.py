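"""Synthetic predication corpora with controlled statistical structure.

The generator emulates the statistics of extracted-predication output that
the summarizer consumes: a skewed predicate distribution, a pool of
semantic types, a Zipf-tailed vocabulary of concept names, and a
configurable fraction of records bearing the seed topic.  *Planted patterns*
tilt the joint (semantic type, predicate) distribution of seed-bearing
records by an enrichment multiplier, creating a known ground truth that the
saliency engine should recover.  Generation is a pure function of the spec:
the same spec (including its RNG seed) yields an identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import BackgroundDistribution, Predication, PredicationSet, ReferenceStandard

#: Predicate weights with a literature-like skew toward treatment assertions.
DEFAULT_PREDICATE_WEIGHTS = {
    "TREATS": 30.0,
    "AFFECTS": 20.0,
    "ASSOCIATED_WITH": 15.0,
    "CAUSES": 10.0,
    "PREVENTS": 8.0,
    "INTERACTS_WITH": 7.0,
    "COEXISTS_WITH": 5.0,
    "PREDISPOSES": 3.0,
    "ADMINISTERED_TO": 2.0,
}

#: Semantic-type pool (UMLS-style codes: drugs, procedures, disorders, ...).
DEFAULT_SEMTYPE_POOL = (
    "phsu", "topp", "dsyn", "neop", "aapp",
    "orch", "food", "lbpr", "diap", "popg",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Everything needed to generate one corpus, deterministically."""

    n_records: int = 5000
    predicate_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREDICATE_WEIGHTS)
    )
    semtype_pool: Sequence[str] = DEFAULT_SEMTYPE_POOL
    seed_name: str = "Congestive heart failure"
    seed_semtype: str = "dsyn"
    planted_patterns: Sequence[tuple[str, str, float]] = (
        ("phsu", "TREATS", 8.0),
    )
    noise_name_count: int = 200
    seed_fraction: float = 0.3
    zipf_exponent: float = 1.2
    background_total: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        weights = dict(self.predicate_weights)
        if not weights or any(w < 0 for w in weights.values()) or not any(
            w > 0 for w in weights.values()
        ):
            raise ValueError("predicate weights must be >= 0 with one > 0")
        for st, predicate, mult in self.planted_patterns:
            if mult < 1:
                raise ValueError("enrichment multipliers must be >= 1")
            if predicate not in weights:
                raise ValueError(f"planted predicate {predicate!r} has no weight")
            if st not in self.semtype_pool:
                raise ValueError(f"planted semtype {st!r} not in the pool")
        if not 0 <= self.seed_fraction <= 1:
            raise ValueError("seed_fraction must be in [0, 1]")
        if self.noise_name_count < 1:
            raise ValueError("noise_name_count must be >= 1")
        object.__setattr__(self, "predicate_weights", weights)
        object.__setattr__(self, "semtype_pool", tuple(self.semtype_pool))
        object.__setattr__(
            self, "planted_patterns", tuple(self.planted_patterns)
        )


@dataclass(frozen=True)
class SyntheticCorpus:
    """A generated corpus plus its ground truth."""

    predications: PredicationSet
    background: BackgroundDistribution
    planted_patterns: tuple[tuple[str, str], ...]
    intervention_names: tuple[str, ...]


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def _background_counts(spec: CorpusSpec) -> dict[str, int]:
    weights = {p: w for p, w in spec.predicate_weights.items() if w > 0}
    total_w = sum(weights.values())
    counts = {
        p: max(1, round(w / total_w * spec.background_total))
        for p, w in weights.items()
    }
    return counts


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate a predication corpus and its matched background table.

    Seed-bearing records take the form ``intervention PREDICATE seed``; their
    joint (predicate, subject semtype) law is the product of the predicate
    weights and a uniform semtype choice, tilted by the planted enrichment
    multipliers.  Non-seed records pair two Zipf-drawn noise concepts with
    uniformly typed arguments and an untilted predicate.  With all
    multipliers at 1 the corpus predicate distribution matches the
    background.
    """
    rng = np.random.default_rng(spec.rng_seed)
    predicates = sorted(p for p, w in spec.predicate_weights.items() if w > 0)
    pred_w = np.array([spec.predicate_weights[p] for p in predicates])
    pred_p = pred_w / pred_w.sum()
    pool = list(spec.semtype_pool)
    mult = {(st, pr): m for st, pr, m in spec.planted_patterns}

    # joint (predicate, semtype) law for seed-bearing records
    joint_items = [(pr, st) for pr in predicates for st in pool]
    joint_w = np.array(
        [
            spec.predicate_weights[pr] * mult.get((st, pr), 1.0)
            for pr, st in joint_items
        ]
    )
    joint_p = joint_w / joint_w.sum()

    interventions = tuple(
        f"intervention {i:03d}" for i in range(1, spec.noise_name_count + 1)
    )
    name_p = _zipf_probs(spec.noise_name_count, spec.zipf_exponent)

    n = spec.n_records
    is_seed = rng.random(n) < spec.seed_fraction
    n_seed = int(is_seed.sum())
    n_noise = n - n_seed
    joint_idx = rng.choice(len(joint_items), size=n_seed, p=joint_p)
    seed_subjects = rng.choice(spec.noise_name_count, size=n_seed, p=name_p)
    noise_pred = rng.choice(len(predicates), size=n_noise, p=pred_p)
    noise_sub = rng.choice(spec.noise_name_count, size=n_noise, p=name_p)
    noise_obj = rng.choice(spec.noise_name_count, size=n_noise, p=name_p)
    noise_sub_st = rng.choice(len(pool), size=n_noise)
    noise_obj_st = rng.choice(len(pool), size=n_noise)

    records: list[Predication] = []
    si = ni = 0
    for i in range(n):
        cit = f"cit{i:06d}"
        if is_seed[i]:
            pr, st = joint_items[joint_idx[si]]
            subject = interventions[seed_subjects[si]]
            records.append(
                Predication(
                    subject_name=subject,
                    subject_semtypes=(st,),
                    predicate=pr,
                    object_name=spec.seed_name,
                    object_semtypes=(spec.seed_semtype,),
                    citation_id=cit,
                    sentence_text=f"{subject} {pr.lower()} {spec.seed_name}.",
                )
            )
            si += 1
        else:
            subject = interventions[noise_sub[ni]]
            obj = interventions[noise_obj[ni]]
            records.append(
                Predication(
                    subject_name=subject,
                    subject_semtypes=(pool[noise_sub_st[ni]],),
                    predicate=predicates[noise_pred[ni]],
                    object_name=obj,
                    object_semtypes=(pool[noise_obj_st[ni]],),
                    citation_id=cit,
                    sentence_text=f"{subject} and {obj}.",
                )
            )
            ni += 1

    return SyntheticCorpus(
        predications=PredicationSet.from_records(
            records, provenance=f"synthetic corpus (rng_seed={spec.rng_seed})"
        ),
        background=BackgroundDistribution(counts=_background_counts(spec)),
        planted_patterns=tuple((st, pr) for st, pr, _ in spec.planted_patterns),
        intervention_names=interventions,
    )


def generate_reference(
    interventions: Sequence[str],
    overlap: float = 1.0,
    size: int | None = None,
    pairing_label: str = "",
    alias_count: int = 0,
) -> tuple[ReferenceStandard, dict[str, str]]:
    """A reference standard overlapping known intervention names.

    ``round(overlap * size)`` entries are drawn (in order) from
    ``interventions``; the remainder are distractors no summarizer can
    produce, so a perfect summarizer's expected recall equals ``overlap``.
    The alias map carries ``alias_count`` spelled variants of included names,
    for exercising synonym-mediated matching.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    size = len(interventions) if size is None else size
    if size < 1:
        raise ValueError("reference size must be >= 1")
    k = round(overlap * size)
    if k > len(interventions):
        raise ValueError("not enough intervention names for requested overlap")
    entries = list(interventions[:k]) + [
        f"unlisted intervention {i:03d}" for i in range(size - k)
    ]
    aliases = {
        f"{name} regimen": name for name in interventions[: min(alias_count, k)]
    }
    ref = ReferenceStandard.from_lines(entries, pairing_label=pairing_label)
    return ref, aliases
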