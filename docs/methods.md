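# Methods

## Corpus model

A record is either free text or an ordered token stream with part-of-speech
tags drawn from a closed internal tagset (noun, verb, adjective, adverb,
interjection, prenominal, symbol, particle, auxiliary_verb, other; minor
tags distinguish suffixes, numbers, pronouns, formal nouns, auxiliary
adjectives, proper-noun subtypes). Each record carries a calendar month
(`YYYY-MM`); the study period is `post` iff `month >= cutoff` (default
cutoff `2018-04`), otherwise `pre` — exhaustive and exclusive. A corpus
retains the *total* record count per period alongside the seed-selected
records so that share-of-total statistics remain well defined after
selection.

Seed selection keeps records containing at least one seed-term variant:
token base/surface match for tokenized records, substring match for raw
text. The variants are collapsed onto one canonical seed term during
standardization, so the seed column of the incidence matrix is all-ones on a
seed-selected corpus.

All report rounding is half-up at the printed precision: 2 decimals for
percentages and odds ratios, 1 for per-record means, 3 for Dice
coefficients.

## Preprocessing

Tokenization is a pluggable contract. The default tokenizer reads
pre-annotated `surface[:base]/major[.minor]` streams, which makes the whole
pipeline language-neutral and testable; an adapter for a morphological
analyzer of unsegmented text can be registered, with `map_ipadic_pos`
translating ipadic-style tag names onto the internal tagset (unmapped major
tags collapse to `other` and are dropped).

POS filtering keeps content categories and drops, by default: suffixes,
numbers, pronouns and formal (non-independent) nouns within nouns; auxiliary
adjectives within adjectives; and all symbols, particles and auxiliary
verbs. Anonymization removes (or, optionally, replaces with a placeholder)
tokens tagged as person, organization or location proper nouns. Both
operations are pure filters on disjoint criteria, hence idempotent and
commuting — asserted as property tests.

Standardization applies, in order: greedy longest-match left-to-right
merging of compound lexicon entries; synonym mapping onto canonical terms
(synonym classes are intended to be keyed by controlled-vocabulary
identifiers such as MeSH/SNOMED codes); removal of exclusion words and
single alphabetic characters. Terms are normalized (NFKC width folding +
casefold) before any table lookup, because mapping tables in practice mix
scripts and widths. Terms are counted by base form by default (configurable
to surface forms).

## Compound-term scoring

Candidates are maximal contiguous noun runs (length ≥ 1; singleton runs are
needed for the neighbor statistics). For a candidate `W = N1 … NL` with
corpus frequency `f(W)`:

    LR(W)  = ( Π_i (FL(Ni)+1)(FR(Ni)+1) )^(1/(2L))
    FLR(W) = f(W) · LR(W)

where `FL(N)` / `FR(N)` count noun-bigram occurrences with `N` as the
second / first element. The `+1` smoothing floors LR at 1 for nouns never
adjacent to another noun. All noun bigrams lie inside maximal runs, so the
neighbor counts are recovered exactly from the candidates themselves.
The compound lexicon is the set of multi-part candidates whose FLR reaches
the top-5% threshold computed over *all* candidates (the `ceil(0.05·N)`-th
largest score; ties at the threshold are all included). Both the percentile
and the multi-part restriction are configurable; scoring of sub-runs of a
longer run is out of scope.

## Network stage

The incidence matrix binarizes term presence per record (multiplicity
ignored). Dice coefficients are computed from sparse column intersections.
The seed-centred network keeps every term pair with `dice ≥ θ` (default
0.3, a conservative threshold given that Dice runs higher than Jaccard) and
is restricted to the connected component containing the seed, which admits
terms linked to the seed only through intermediaries. The same θ applies to
seed and non-seed pairs. The display backbone is the maximum-weight
spanning tree (Kruskal on descending Dice with lexicographic tie-breaks, so
it is deterministic; equivalent to the minimum spanning tree under
`1 − dice`). Communities come from Louvain greedy modularity optimization
(resolution 1.0, Dice-weighted, seeded and deterministic); community ids
are assigned by each community's lexicographically smallest member.
Networks and spanning trees are exported as GraphML with node frequency,
node community and edge Dice attributes. Graph layout and visual styling
are left to external viewers.

## Clustering and cross-tabulation

Clustering operates on the union of the two per-period node sets.
Dissimilarity is `1 − dice` computed on the pooled two-period record set by
default (`dice_pool` can restrict it to one period). Ward's
minimum-variance linkage is applied directly to this precomputed matrix via
the Lance–Williams recurrence, without embedding first; since the merged
pair always attains the current minimum distance, the update stays
non-negative and merge heights are non-decreasing even for non-Euclidean
input. The dendrogram is cut at `k = max(2, round_half_up(0.10 · T))`
clusters for `T` terms; `k_override` replaces the rule (the reference
analysis of 84 terms used 7 groups, which no simple rounding of 8.4
produces, so reproduction of that analysis requires the override).

Each record "contains" a cluster iff it contains ≥ 1 member term. Per
cluster, the 2×2 table (post-with, post-without, pre-with, pre-without)
yields:

- odds ratio `OR = ad/(bc)` (post/pre orientation), Wald 95% CI
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`, with the Haldane–Anscombe +0.5
  correction when a single cell is zero (flagged) and an undefined result
  for cross-pattern double zeros;
- a two-sided Fisher exact p-value by the point-probability rule: the sum of
  hypergeometric probabilities (margins fixed) of all tables at most as
  probable as the observed one, with a 1e-12 relative tolerance guarding
  floating-point ties. An exact rational-arithmetic enumeration oracle and
  scipy's implementation serve as independent cross-checks in the tests.

Published Wald-CI note: recomputing the reported contingency rows
reproduces all five point odds ratios at 2 decimals and the Wald intervals
for two clusters exactly; for three rows one printed bound differs by 0.01
from the Wald value, and one interval (0.38–1.20) is not attainable by Wald
at all but matches the conditional exact CI of `fisher.test` — the source
analysis most likely printed exact conditional intervals. This package
documents and defaults to Wald, as the simplest standard choice, and the
tests assert only the bounds Wald reproduces.

No multiple-testing adjustment is applied across clusters (matching the
reference analysis); cluster naming is a human step — the package emits
member term lists.

The sensitivity analysis re-runs the identical pipeline after dropping all
records from a configurable month onward (default `2020-04`, the onset of
pandemic-era effects), labelled "pre vs early-post".

## Synthetic corpus generator

The generator emulates a seed-selected two-period corpus: the seed term in
every record; planted clusters of co-activating terms, each activating per
record as Bernoulli(π_period) with `odds(π_post) = OR_c · odds(π_pre)` and
emitting each member with probability `q` (default 0.9) given activation;
background presence of every vocabulary term with probability ε (default
0.02); filler nouns drawn uniformly from a large pool (default 2,000 types)
with a negative-binomial count per record (mean 49, shape 8 — tuned so the
analyzed stream runs at the observed ≈ 55–66 terms per record); injected
proper-noun and particle tokens (Poisson, to exercise anonymization and POS
filtering) and adjacent-noun compound pairs (to exercise compound merging);
months uniform within each period's range (2014-04…2018-03 and
2018-04…2022-03). Default record counts are the study's 1,353 / 5,155, and
the default planted clusters use pre-period prevalences and odds ratios in
the reported range (0.456/1.58, 0.442/2.09, 0.551/0.47). Records are
emitted directly as annotated token streams, so no morphological-analyzer
installation is needed. Generation is fully reproducible from `rng_seed`,
and the manifest's contingency cells are the *realized* presence counts —
exactly what the pipeline should recompute.

What the generator does not emulate: Zipfian vocabulary structure beyond a
uniform filler pool, temporal trends within periods, authorship style,
negation, or any real clinical language. Passing tests therefore
demonstrate the correctness and calibration of the measurement chain, not
the clinical validity of conclusions drawn from real records.

## Problem sizes and numerical choices in the test suite

- Odds-ratio recovery plants OR 1.58 (π_pre = 0.456) at the study-scale
  record counts 1,353/5,155 over 500 replicates (coverage) and 100
  replicates (median relative bias). The recovery configuration sets ε = 0:
  background noise attenuates record-level presence odds ratios relative to
  the planted activation odds ratio (an aggregation property, not an
  estimator defect), and the experiment is designed to measure estimator
  calibration against the planted value.
- Cluster-structure recovery uses 3 planted clusters of 4 terms (π = 0.35,
  q = 0.85, ε = 0.02) at 2,000 records, 20 replicates, scored by adjusted
  Rand index against the planted grouping restricted to cluster terms.
- The null-calibration experiment uses 3 null clusters (ORs = 1) at 800
  records over 100 replicates and asserts a no-rejection rate ≥ 0.93 at
  per-test α = 0.01 (nominal `0.99³ ≈ 0.97` minus a ~2.4-SD Monte-Carlo
  margin, fixed a priori).
- Structural oracles are exhaustive at small sizes: Ward against a naive
  Lance–Williams agglomerator on ≤ 5-point matrices, spanning trees against
  enumeration on ≤ 6 nodes, Louvain against full-partition modularity
  maximization on the 8-node two-clique benchmark, Fisher against exact
  rational enumeration on margins ≤ 50.

## Known limitations

- The tokenizer contract ships no real morphological analyzer; applying the
  pipeline to unsegmented clinical text requires registering one.
- Wald intervals are reported even for very sparse tables (with the +0.5
  correction); exact conditional intervals are not implemented.
- Compound extraction scores only maximal noun runs; nested term extraction
  and C-value/NC-value scoring are out of scope.
- The 10%-of-terms cluster-count rule is a heuristic; for small networks it
  bottoms out at k = 2.
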