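import math
import random
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from predsum import (
    BackgroundDistribution,
    EmptyRelevanceError,
    PatternKey,
    PredicateDistribution,
    PredicationSet,
    ScoredPattern,
    SeedTopic,
    SummaryConfig,
    build_profile,
    kld_terms,
    predicate_distribution,
    predscal,
    rlogf,
    score_patterns,
    select_top,
    summarize,
)
from predsum.combo import CONNECTIVITY, RELEVANCE
from predsum.filters import DEFAULT_STOPLIST_NAMES, NoveltyStoplist
from predsum.synthetic import CorpusSpec, generate_corpus

from conftest import make_pred


def dist(**freqs):
    return PredicateDistribution(rel_freqs=freqs)


class TestPredicateDistribution:
    def test_counts_to_relative_frequencies(self):
        pset = PredicationSet.from_records(
            [make_pred("a", "x", "TREATS", "b", "y")] * 3
            + [make_pred("a", "x", "AFFECTS", "b", "y")]
        )
        p = predicate_distribution(pset)
        assert p.rel_freqs == {"TREATS": 0.75, "AFFECTS": 0.25}

    def test_single_record(self):
        pset = PredicationSet.from_records([make_pred("a", "x", "TREATS", "b", "y")])
        assert predicate_distribution(pset).rel_freqs == {"TREATS": 1.0}

    def test_matches_counting_oracle_on_random_records(self):
        rng = random.Random(3)
        preds = [rng.choice("ABCDE") for _ in range(500)]
        pset = PredicationSet.from_records(
            [make_pred("s", "x", p, "o", "y") for p in preds]
        )
        expected = {p: c / 500 for p, c in Counter(preds).items()}
        assert predicate_distribution(pset).rel_freqs == pytest.approx(expected)

    def test_negated_records_excluded_by_default(self):
        pset = PredicationSet.from_records(
            [make_pred("a", "x", "TREATS", "b", "y"),
             make_pred("a", "x", "CAUSES", "b", "y", negated=True)]
        )
        assert predicate_distribution(pset).rel_freqs == {"TREATS": 1.0}


class TestKLD:
    def test_identical_distributions_give_zero_terms(self):
        p = dist(TREATS=0.6, AFFECTS=0.4)
        res = kld_terms(p, dist(TREATS=0.6, AFFECTS=0.4))
        assert all(t == 0 for t in res.terms.values())
        assert res.divergence == 0

    def test_hand_computed_terms(self):
        res = kld_terms(dist(TREATS=0.75, AFFECTS=0.25),
                        dist(TREATS=0.5, AFFECTS=0.5))
        assert res.terms["TREATS"] == pytest.approx(0.75 * math.log2(1.5))
        assert res.terms["AFFECTS"] == pytest.approx(-0.25)

    def test_predicate_absent_from_background_is_unscored(self):
        res = kld_terms(dist(TREATS=0.5, NOVEL=0.5), dist(TREATS=1.0))
        assert "NOVEL" not in res.terms
        assert res.unscored_predicates == ("NOVEL",)

    def test_smoothing_admits_unshared_predicates(self):
        res = kld_terms(dist(TREATS=0.5, NOVEL=0.5), dist(TREATS=1.0),
                        smoothing=0.01)
        assert "NOVEL" in res.terms
        assert res.unscored_predicates == ()


@st.composite
def distribution_pairs(draw):
    labels = [f"P{i}" for i in range(draw(st.integers(2, 8)))]
    def weights():
        w = draw(st.lists(st.floats(0.01, 10), min_size=len(labels),
                          max_size=len(labels)))
        total = sum(w)
        return {l: v / total for l, v in zip(labels, w)}
    keep_p = draw(st.integers(2, len(labels)))
    p_raw = dict(list(weights().items())[:keep_p])
    tot = sum(p_raw.values())
    return (
        PredicateDistribution({k: v / tot for k, v in p_raw.items()}),
        PredicateDistribution(weights()),
    )


@given(distribution_pairs())
def test_gibbs_inequality_on_renormalized_shared_support(pair):
    """D(P'||Q') >= 0 once both distributions are restricted to the shared
    support and renormalized."""
    p, q = pair
    shared = set(p.rel_freqs) & set(q.rel_freqs)
    ps = sum(p.rel_freqs[x] for x in shared)
    qs = sum(q.rel_freqs[x] for x in shared)
    renorm = sum(
        (p.rel_freqs[x] / ps) * math.log2((p.rel_freqs[x] / ps) / (q.rel_freqs[x] / qs))
        for x in shared
    )
    assert renorm >= -1e-12


@given(distribution_pairs())
def test_summed_divergence_cross_checked_against_scipy(pair):
    """On a common support, the summed per-predicate terms equal scipy's
    independently computed relative entropy (base 2)."""
    from scipy import stats

    p, q = pair
    shared = sorted(set(p.rel_freqs) & set(q.rel_freqs))
    ps = sum(p.rel_freqs[x] for x in shared)
    qs = sum(q.rel_freqs[x] for x in shared)
    p_r = PredicateDistribution({x: p.rel_freqs[x] / ps for x in shared})
    q_r = PredicateDistribution({x: q.rel_freqs[x] / qs for x in shared})
    ours = kld_terms(p_r, q_r).divergence
    theirs = stats.entropy([p_r[x] for x in shared],
                           [q_r[x] for x in shared], base=2)
    assert ours == pytest.approx(theirs)


class TestRlogF:
    @pytest.mark.parametrize(
        "f,total,expected",
        [(8, 16, 1.5), (1, 7, 0.0), (4, 4, 2.0), (2, 2, 1.0)],
    )
    def test_hand_values(self, f, total, expected):
        assert rlogf(f, total) == pytest.approx(expected)

    def test_rejects_frequency_above_total(self):
        with pytest.raises(ValueError):
            rlogf(5, 4)

    def test_rejects_zero_frequency(self):
        with pytest.raises(ValueError):
            rlogf(0, 4)


class TestPredScal:
    @pytest.mark.parametrize("c,expected", [(1, 1.0), (2, 1.0), (8, 1 / 3)])
    def test_values(self, c, expected):
        assert predscal(c) == pytest.approx(expected)

    def test_strictly_decreasing_beyond_two(self):
        values = [predscal(c) for c in range(2, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            predscal(0)


class TestScorePatterns:
    def test_combo_is_exact_product_of_worked_values(self):
        key = PatternKey("phsu", "TREATS", RELEVANCE)
        sp = ScoredPattern(key=key, frequency=8, rlogf=rlogf(8, 16),
                           predscal=predscal(8),
                           kld_term=0.75 * math.log2(1.5))
        assert sp.combo == pytest.approx(0.75 * math.log2(1.5) * 1.5 / 3)

    def test_singleton_pattern_scores_zero(self):
        pset_rel = PredicationSet.from_records(
            [make_pred("drug", "phsu", "TREATS", "flu", "dsyn"),
             make_pred("drug", "phsu", "TREATS", "flu", "dsyn"),
             make_pred("herb", "orch", "TREATS", "flu", "dsyn")]
        )
        profile = build_profile(pset_rel, pset_rel.replace_records([]),
                                SeedTopic.of("flu"), unique_predicate_count=4)
        scored = score_patterns(profile, {"TREATS": 0.3})
        by_semtype = {sp.key.semtype: sp for sp in scored}
        assert by_semtype["orch"].frequency == 1
        assert by_semtype["orch"].rlogf == 0
        assert by_semtype["orch"].combo == 0

    def test_unscored_predicate_excluded_from_ranking(self):
        pset_rel = PredicationSet.from_records(
            [make_pred("drug", "phsu", "NOVEL_REL", "flu", "dsyn")] * 2
        )
        profile = build_profile(pset_rel, pset_rel.replace_records([]),
                                SeedTopic.of("flu"), unique_predicate_count=2)
        scored = score_patterns(profile, {})
        assert scored[0].combo is None
        assert select_top(scored)[RELEVANCE] == []


class TestSelectTop:
    def _sp(self, semtype, predicate, combo, freq=5, tier=RELEVANCE):
        # choose kld so the product equals the requested combo (rlogf*scale=1)
        return ScoredPattern(
            key=PatternKey(semtype, predicate, tier), frequency=freq,
            rlogf=2.0, predscal=0.5, kld_term=combo,
        )

    def test_fewer_than_four_selects_all(self):
        scored = [self._sp("a", "X", 0.1), self._sp("b", "Y", 0.2)]
        assert len(select_top(scored)[RELEVANCE]) == 2

    def test_top_four_by_score(self):
        scored = [self._sp(f"s{i}", "X", i / 10) for i in range(10)]
        top = select_top(scored)[RELEVANCE]
        assert [sp.key.semtype for sp in top] == ["s9", "s8", "s7", "s6"]

    def test_tie_broken_by_frequency_then_lexicographic(self):
        scored = [
            self._sp("zeta", "X", 0.1, freq=9),
            self._sp("beta", "X", 0.1, freq=5),
            self._sp("alpha", "Y", 0.1, freq=5),
        ]
        top = select_top(scored, top_k=2)[RELEVANCE]
        assert [sp.key.semtype for sp in top] == ["zeta", "alpha"]

    def test_tiers_ranked_independently(self):
        scored = [self._sp("a", "X", 0.9),
                  self._sp("b", "X", 0.1, tier=CONNECTIVITY)]
        sel = select_top(scored)
        assert len(sel[RELEVANCE]) == 1 and len(sel[CONNECTIVITY]) == 1


def _background(**counts):
    return BackgroundDistribution(counts=counts)


class TestSummarize:
    def test_planted_dominant_pattern_ranks_first(self):
        corpus = generate_corpus(CorpusSpec(n_records=3000, rng_seed=42))
        seed = SeedTopic.of("Congestive heart failure")
        result = summarize(corpus.predications, seed, corpus.background)
        top = result.selected_relevance[0]
        assert (top.key.semtype, top.key.predicate) == ("phsu", "TREATS")

    def test_background_equal_corpus_flags_no_enrichment(self):
        records = (
            [make_pred("drug a", "phsu", "TREATS", "flu", "dsyn")] * 2
            + [make_pred("drug b", "phsu", "AFFECTS", "flu", "dsyn")] * 2
        )
        pset = PredicationSet.from_records(records)
        result = summarize(pset, SeedTopic.of("flu"),
                           _background(TREATS=50, AFFECTS=50))
        assert result.no_enrichment
        assert all(sp.combo == 0 for sp in result.diagnostics)
        assert len(result.selected_relevance) > 0  # tie-break fallback

    def test_output_is_subset_of_novelty_filtered_input(self):
        corpus = generate_corpus(CorpusSpec(n_records=400, rng_seed=9))
        seed = SeedTopic.of("Congestive heart failure")
        result = summarize(corpus.predications, seed, corpus.background)
        novel_count = len(corpus.predications)  # no stoplisted names generated
        assert 0 < len(result.predications) <= novel_count
        selected_rel = {(sp.key.semtype, sp.key.predicate)
                        for sp in result.selected_relevance}
        selected_conn = {(sp.key.semtype, sp.key.predicate)
                         for sp in result.selected_connectivity}
        for rec in result.predications:
            carried = set(rec.subject_semtypes) | set(rec.object_semtypes)
            assert any(
                sp_pred == rec.predicate and sp_st in carried
                for sp_st, sp_pred in selected_rel | selected_conn
            )

    def test_absent_seed_raises_with_suggestions(self):
        corpus = generate_corpus(CorpusSpec(n_records=200, rng_seed=2))
        with pytest.raises(EmptyRelevanceError) as err:
            summarize(corpus.predications,
                      SeedTopic.of("Congestive cardiac failure"),
                      corpus.background)
        assert err.value.suggestions  # nearest-name diagnostic present

    def test_duplicating_every_record_keeps_proportions(self):
        """Doubling the corpus leaves P and the RlogF quotients unchanged;
        only the log2(frequency) factor grows — checked via the formula."""
        corpus = generate_corpus(CorpusSpec(n_records=300, rng_seed=4))
        seed = SeedTopic.of("Congestive heart failure")
        once = summarize(corpus.predications, seed, corpus.background)
        doubled = corpus.predications.replace_records(
            list(corpus.predications.records) * 2
        )
        twice = summarize(doubled, seed, corpus.background)
        once_by_key = {sp.key: sp for sp in once.diagnostics}
        assert set(once_by_key) == {sp.key for sp in twice.diagnostics}
        for sp2 in twice.diagnostics:
            sp1 = once_by_key[sp2.key]
            assert sp2.frequency == 2 * sp1.frequency
            assert sp2.kld_term == pytest.approx(sp1.kld_term)
            assert sp2.predscal == sp1.predscal
            # quotient f/F unchanged, log2(f) grows by exactly 1
            q1 = sp1.rlogf / math.log2(sp1.frequency) if sp1.frequency > 1 else None
            q2 = sp2.rlogf / math.log2(sp2.frequency)
            if q1 is not None:
                assert q2 == pytest.approx(q1)

    def test_end_to_end_determinism(self):
        corpus = generate_corpus(CorpusSpec(n_records=500, rng_seed=6))
        seed = SeedTopic.of("Congestive heart failure")
        a = summarize(corpus.predications, seed, corpus.background)
        b = summarize(corpus.predications, seed, corpus.background)
        assert a.diagnostics == b.diagnostics
        assert a.predications.records == b.predications.records


def brute_force_scores(data, seed_names, background, stop_names):
    """Straight-line independent recomputation of the scoring kernel."""
    stop = {n.lower() for n in stop_names}
    seeds = {n.lower() for n in seed_names}
    recs = [r for r in data if not r.negated]
    novel = [r for r in recs
             if r.subject_name.lower() not in stop
             and r.object_name.lower() not in stop]
    rel = [r for r in novel
           if r.subject_name.lower() in seeds or r.object_name.lower() in seeds]

    licensed = set()
    for r in rel:
        if r.subject_name.lower() in seeds and r.object_name.lower() not in seeds:
            licensed |= set(r.object_semtypes)
        elif r.object_name.lower() in seeds and r.subject_name.lower() not in seeds:
            licensed |= set(r.subject_semtypes)
    rel_ids = {id(r) for r in rel}
    conn = [r for r in novel if id(r) not in rel_ids
            and (set(r.subject_semtypes) | set(r.object_semtypes)) & licensed]

    counts = Counter(r.predicate for r in novel)
    n = sum(counts.values())
    p = {x: c / n for x, c in counts.items()}
    total_q = sum(background.counts.values())
    q = {x: c / total_q for x, c in background.counts.items() if c > 0}
    kld = {x: p[x] * math.log2(p[x] / q[x]) for x in p if x in q}

    patterns = Counter()
    for r in rel:
        if r.subject_name.lower() in seeds and r.object_name.lower() not in seeds:
            opp = r.object_semtypes
        elif r.object_name.lower() in seeds and r.subject_name.lower() not in seeds:
            opp = r.subject_semtypes
        else:
            continue
        for stx in opp:
            patterns[(stx, r.predicate, "relevance")] += 1
    for r in conn:
        seen = []
        for stx in r.subject_semtypes + r.object_semtypes:
            if stx in licensed and stx not in seen:
                seen.append(stx)
        for stx in seen:
            patterns[(stx, r.predicate, "connectivity")] += 1

    totals = Counter()
    for (stx, pr, tier), c in patterns.items():
        totals[pr] += c
    cpred = len(p)
    scale = 1.0 if cpred == 1 else 1.0 / math.log2(cpred)
    out = {}
    for (stx, pr, tier), f in patterns.items():
        rl = math.log2(f) * f / totals[pr]
        out[(stx, pr, tier)] = (
            f, rl, kld[pr] * rl * scale if pr in kld else None
        )
    return out


def test_scoring_kernel_matches_brute_force_recomputation():
    """Full KLD/RlogF/PredScal/Combo kernel equals an independent
    straight-line recomputation across many random small corpora."""
    seed_name = "Congestive heart failure"
    stop = NoveltyStoplist.of(DEFAULT_STOPLIST_NAMES)
    for i in range(100):
        corpus = generate_corpus(CorpusSpec(
            n_records=60, rng_seed=1000 + i,
            planted_patterns=(("phsu", "TREATS", 1.0 + (i % 5)),),
        ))
        try:
            result = summarize(corpus.predications, SeedTopic.of(seed_name),
                               corpus.background,
                               SummaryConfig(stoplist=stop))
        except EmptyRelevanceError:
            continue
        expected = brute_force_scores(
            corpus.predications, [seed_name], corpus.background,
            DEFAULT_STOPLIST_NAMES)
        got = {
            (sp.key.semtype, sp.key.predicate, sp.key.tier):
                (sp.frequency, sp.rlogf, sp.combo)
            for sp in result.diagnostics
        }
        assert set(got) == set(expected)
        for key, (f, rl, combo) in expected.items():
            gf, grl, gcombo = got[key]
            assert gf == f
            assert grl == pytest.approx(rl)
            if combo is None:
                assert gcombo is None
            else:
                assert gcombo == pytest.approx(combo)
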