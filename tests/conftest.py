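import random

import pytest
from hypothesis import settings

from predsum import Predication, PredicationSet

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_pred(subject, sub_st, predicate, obj, obj_st, **kwargs):
    return Predication(
        subject_name=subject,
        subject_semtypes=(sub_st,) if isinstance(sub_st, str) else tuple(sub_st),
        predicate=predicate,
        object_name=obj,
        object_semtypes=(obj_st,) if isinstance(obj_st, str) else tuple(obj_st),
        **kwargs,
    )


PREDICATES = ["TREATS", "AFFECTS", "PREVENTS", "CAUSES", "ASSOCIATED_WITH"]
SEMTYPES = ["phsu", "topp", "dsyn", "neop", "orch", "food"]


def random_corpus(rng: random.Random, n: int, seed_name="heart failure",
                  seed_rate=0.4, names=None) -> PredicationSet:
    """Plain-random corpus built directly from records (independent of the
    package's own generator)."""
    names = names or [f"concept {i}" for i in range(30)]
    records = []
    for i in range(n):
        subject = rng.choice(names)
        obj = rng.choice(names)
        if rng.random() < seed_rate:
            obj = seed_name
        records.append(
            make_pred(
                subject,
                rng.sample(SEMTYPES, rng.randint(1, 2)),
                rng.choice(PREDICATES),
                obj,
                rng.sample(SEMTYPES, rng.randint(1, 2)),
                citation_id=f"c{i}",
            )
        )
    return PredicationSet.from_records(records)


@pytest.fixture
def cetuximab():
    return make_pred("cetuximab", "phsu", "TREATS", "Endometrial carcinoma",
                     "neop", citation_id="c1")


@pytest.fixture
def small_set(cetuximab):
    return PredicationSet.from_records(
        [
            cetuximab,
            make_pred("trastuzumab", "phsu", "TREATS", "Breast cancer", "neop",
                      citation_id="c2"),
            make_pred("pharmaceutical preparation", "phsu", "TREATS",
                      "patients", "podg", citation_id="c3"),
            make_pred("aspirin", "phsu", "PREVENTS", "Myocardial infarction",
                      "dsyn", citation_id="c4"),
        ]
    )
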