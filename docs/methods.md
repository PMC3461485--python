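# Methods

## Problem and data model

The package summarizes corpora of *semantic predications* — normalized
subject–predicate–object assertions extracted from biomedical citation text,
each argument tagged with one or more UMLS-style semantic-type codes
(`phsu`, `neop`, `dsyn`, …) and bound by an uppercase relation label
(TREATS, PREVENTS, AFFECTS, …). Concept names and semantic types are taken
as given: there is no UMLS, MetaMap, or RxNorm dependency, and all name
matching is exact equality after whitespace collapsing and lower-casing.
Duplicate records are meaningful (frequency drives saliency) and preserved.

## The summarization cascade

Given a predication set, a seed topic (one or more names for one disease
concept), and a background predicate table, `summarize` applies:

1. **Novelty** — remove records whose subject or object name is on a
   stoplist of overly generic concepts. The default stoplist
   ("pharmaceutical preparation(s)", "patients", "intervention regimes",
   "therapeutic procedure") replaces ontology-driven generality checks with
   an auditable, configurable list.
2. **Relevance** — keep records bearing a seed name as subject or object.
   Matching is exact, never substring, so "Heart failure" does not also
   match "Congestive heart failure"; supply both names if both should count.
3. **Connectivity** — from the remaining novel records, add those sharing a
   semantic type with a *non-seed* argument of some relevant record. By
   default a candidate may match on either argument position
   (`connectivity_positions="both"`); a position-restricted mode is
   available because the stricter reading is also defensible.
4. **Saliency** — score patterns and keep matching records (below).

Negated predications are parsed and round-tripped but excluded from
scoring by default (`include_negated=True` to change); scoring TREATS and
NEG_TREATS as one relation would conflate opposite claims.

The Novelty tier is applied first so that both the pattern profile and the
predicate distribution P are computed over novel records only; since Novelty
and Relevance are record-wise predicates they commute, and the ordering only
determines what the Connectivity tier can see.

## Saliency scoring

Let P be the relative predicate frequencies of the novelty-filtered corpus
and Q those of the background table. Each pattern — a (semantic type,
predicate) pair tagged with the tier it came from — receives

`Combo = KLD_term(predicate) × RlogF(pattern) × PredScal`

* **KLD term**: `P(x)·log2(P(x)/Q(x))`, the predicate's contribution to
  D(P‖Q) *before summing*. Only predicates present in both supports receive
  a term; others are reported as unscored diagnostics and excluded from
  ranking. An optional add-α smoothing of Q over the union vocabulary
  (`smoothing`, default 0 = off) admits them when robustness matters more
  than fidelity. Terms are kept signed: an under-represented predicate
  should rank low, and no clamping is applied. A variant that multiplies the
  summed divergence instead of the per-predicate term is available behind
  `use_summed_kld` for comparison.
* **RlogF**: `log2(f) · f/F` with `f` the pattern frequency and `F` the
  summed frequency of all semantic types paired with that predicate across
  the profiled patterns. Singleton patterns score exactly 0. For
  relevance-tier records the semantic type comes from the argument opposite
  the seed; for connectivity-tier records, from the type(s) that licensed
  inclusion. An argument carrying several types contributes one count per
  type by default (`multi_semtype=False` keeps only the first, treating it
  as primary).
* **PredScal**: `1/log2(c)`, defined as 1 when `c = 1`, where `c` counts
  unique predicates in the novelty-filtered corpus (not the background).
  Note `PredScal(2) = 1` as well; the factor is strictly decreasing from
  there.

The per-predicate `F` denominator spans both tiers' patterns for a
predicate, which keeps the profile a single consistent table (per-tier
totals would be the main alternative; it changes only a shared constant
within each predicate and so rarely reorders a tier's ranking).

Per tier, the `top_k` (default 4) highest Combo scores are selected; ties
break by descending pattern frequency, then lexicographic (semtype,
predicate), so output is deterministic. When every ranked score is 0 — e.g.
the corpus distribution equals the background — the result is flagged
`no_enrichment` and the selection is tie-break order only. The summary
contains every relevance/connectivity record matching a selected pattern.

## Baseline summarizer

The baseline retains the terms of a term-frequency table whose count
strictly exceeds mean + 1 SD of the table's counts. The SD is the
population (divide-by-N) standard deviation by default, since the table is
the whole group rather than a sample; the published worked example
(1784 terms, 63924 occurrences, mean ≈ 35.8, SD 154.4, threshold 190.3)
cannot discriminate the two at the printed precision, and `sd_mode="sample"`
is provided. The source description is internally inconsistent about
inclusivity at the threshold ("exceeded" vs "190 times or more" against a
threshold of 190.3); this package uses strict `>` and does not guess which
was executed. Prevention-oriented corpora are first reduced to lines
containing any of four trigger phrases ("prevent", "prevents",
"for prevention of", "for the prevention of" — kept verbatim although the
first subsumes the rest as a substring; the list is configurable), and a
term→category map supports excluding categories such as the disorders
themselves. Concept extraction is out of scope: the module consumes a ready
table, with a whitespace tokenizer as a fixture-grade fallback.

## Evaluation

Summary records are restricted to the point-of-view's accepted form —
`X TREATS disease` for treatment, `X PREVENTS disease` for prevention, plus
explicitly configured extra predicates (AFFECTS, USES, …) admitted without
the object constraint and only under prevention — and grouped by normalized
subject name. Precision is the fraction of subject groups matching a
reference intervention, recall the fraction of reference interventions
matched, F1 their harmonic mean (0 when both vanish; precision is reported
as 0 and flagged when there are no groups). Matching judgments that a human
assessor would make from context (e.g. crediting "Dietary Modification" to
"reduce sodium intake") are mechanized solely through an explicit alias map,
keeping results reproducible and auditable; there is no fuzzy matching.
Bare term lists (baseline output) evaluate through degenerate one-term
groups. Inter-annotator agreement is the simple proportion
matches/(matches + non-matches).

## Synthetic data

`generate_corpus` emulates the statistics the summarizer faces: a skewed
predicate law (default nine predicates, TREATS-heavy), a ten-type semantic
pool, a Zipf-tailed concept vocabulary (exponent 1.2, 200 names), and a
configurable fraction (default 0.3) of seed-bearing records of the form
*intervention PREDICATE seed*. Planted (semtype, predicate) patterns tilt
the joint law of seed-bearing records by a multiplier ≥ 1, giving a known
ground truth; the matched background is derived from the untilted weights,
so with all multipliers at 1 the corpus predicate distribution converges to
the background. The default condition — one (phsu, TREATS) pattern at ×8
enrichment in 5000-record corpora — is the recovery setting the validation
suite checks (top-ranked relevance pattern in ≥ 95% of 50 replicates).
Generation is a pure function of the spec including its RNG seed.

What the generator does **not** emulate: real extraction noise (mis-mapped
concepts, wrong predicates), correlated semantic types within arguments,
citation-level clustering of assertions, or natural-language sentences
(`sentence_text` is a template). Passing tests therefore demonstrate the
algorithmic behaviour of the cascade and scorer under controlled enrichment,
not end-to-end performance on literature-scale extractor output.

## Numerical and design notes

* All scoring uses exact `math.log2` on Python floats; Combo is computed as
  the literal product of its three stored factors, so the invariant
  `combo == kld_term * rlogf * predscal` holds to the bit.
* Relative-frequency tables validate to Σ = 1 within 1e-9; zero-frequency
  predicates are dropped rather than stored.
* Degenerate inputs raise typed errors: empty files/datasets
  (`EmptyInputError`, CLI exit code 3), malformed tables (`FormatError`),
  a seed matching nothing (`EmptyRelevanceError`, carrying nearest-name
  suggestions computed with difflib).
* Problem sizes in the validation suite — 100 corpora of 50–60 records for
  the kernel-vs-brute-force check, 50 corpora of 5000 records for planted
  recovery, 1e5 records for the distribution-convergence check — were
  chosen as the smallest sizes at which the statistical assertions are
  stable.
* Known limitations: name-equality matching undercounts synonyms unless an
  alias map is supplied; the Connectivity tier's both-positions default is a
  permissive reading of "shares a non-seed argument's semantic type"; the
  shipped background is synthetic and any real background table is accepted
  as-is.
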