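# Methods

## Overview

`aopminer` infers candidate stressor–event and event–event
relationships for Adverse Outcome Pathway (AOP) construction from
literature co-occurrence.  The underlying assumption is deliberately
weak: two terms mentioned in the same abstract *may* be mechanistically
related; frequency and statistical enrichment of the co-mention, not
its mere existence, carry the weight of evidence.  Direction and
causality of event–event relationships are left to expert curation —
the network is undirected by design.

## Text standardization

Dictionary terms, abstract text and annotation keys all pass through
one pipeline:

1. **Tokenization** — lowercase; tokens are maximal letter/digit runs,
   so hyphens and slashes split ("double-strand" → "double",
   "strand") and gene symbols like `tp53` survive as single tokens.
2. **Stopword removal** — a fixed English function-word list
   (`aopminer.stopwords`, version `en-1`, user-overridable) is applied
   to raw tokens *before* stemming, keeping list lookup exact.
3. **Stemming** — the original 1980 Porter algorithm, implemented in
   `aopminer._porter`.  Tokens shorter than three letters or containing
   digits are never stemmed, protecting gene symbols.
4. **Post-stem stopword filter** — any stem equal to the stem of a
   stopword is also dropped.  This second pass guarantees the invariant
   that no emitted stem collides with a function word's stem, so
   matching can never key on grammatical residue.

Sentence segmentation is rule-based (`.`, `!` or `?` followed by
whitespace).  A trained segmenter would handle abbreviations better but
would make outputs model- and version-dependent; determinism is worth
more here.  Normalization is idempotent on the vocabulary the package
actually processes (dictionary labels, generated corpora); this is a
property of that vocabulary, not of arbitrary letter sequences, and is
tested as such.

## Matching

A term with `k` distinct content stems matches a stem set containing
`j` of them when `4j ≥ 3k` (**partial** mode — "at least ¾ of the
words") or `j = k` (**exact** mode).  The threshold is evaluated as an
integer inequality, never by floating-point comparison of `j/k` with
0.75.  Distinct-stem counting means a repeated word in a label counts
once, consistent with set semantics downstream.  Matching defaults to
**abstract scope** (stems may be spread over the whole record); the
stricter **sentence scope** requires one sentence to satisfy the rule
alone.  Stopwords never enter the `k` denominator — only content words
are counted.

## Link scoring

For each unordered pair, the supporting set is the intersection of the
two terms' hit-record sets; the background `N` is the number of records
in the analyzed corpus — the only closed-world choice available without
live database access.  Significance is the one-sided (enrichment)
hypergeometric tail `P(X ≥ n_both)` computed via
`scipy.stats.hypergeom.sf`; the test suite checks it against exact
integer enumeration on every 2×2 table with `N ≤ 40`.  Enrichment
rather than a two-sided test because co-occurrence mining asks only
whether a pair co-occurs *more* than chance.

Optional Benjamini–Hochberg adjustment (statsmodels `fdr_bh`) is
applied separately per link population (stressor–event vs event–event),
with ties ordered by (p, pair) for determinism; when enabled, the
confidence rule reads the adjusted p-value.

**Confidence bins** (all three parameters config-exposed and recorded
in run metadata): with `significant = p < alpha` (default 0.05),

| category  | condition                                           |
|-----------|-----------------------------------------------------|
| Very High | significant and count ≥ 20                          |
| High      | significant and 5 ≤ count < 20                      |
| Moderate  | significant and count < 5, or not significant and count ≥ 20 |
| Low       | otherwise                                           |

This four-level default is the package's own calibration of
"frequency × significance"; it is monotone in both inputs (property
tested) and is not claimed to reproduce any particular web service's
bins.

## Annotation

Events are matched to database-extract keys by stem-set equality
(default, `exact-normalized` — annotation is a lookup) or by the same
¾ coverage arithmetic (`partial`, for recall).  Gene-category terms
additionally match on case-insensitive raw symbol equality, since
stemming can mangle symbols and databases key genes by symbol.
Annotations deduplicate by (source, annotation id); extracts are
accepted as-is with no ontology traversal or identifier mapping.

## Network

Nodes are exactly the terms incident to at least one link; edges carry
weight (= supporting-abstract count), p-value, confidence and the
sorted supporting record ids, so the "which articles support this
edge" question is answerable from the data alone.  Filtering keeps
edges with `weight ≥ min_count` and `confidence ≥ floor`, then removes
isolated nodes; raising either threshold never adds elements.
Serializations (viewer JSON with `elements`/`data` objects; TSV edge
and node tables) emit sorted keys and sorted element order, so equal
networks are byte-identical.  Confidence colors (Low → orange `#E69F00`,
Moderate → yellow `#F0E442`, High → light-green `#90EE90`, Very High →
dark-green `#006400`) are presentation metadata; the category string is
normative.

## Synthetic corpora

The generator (`aopminer.synth`) is the package's testing ground: it
plants term content words inside filler sentences drawn from a fixed
invented vocabulary whose stems are verified disjoint from every term
stem at generation time, so a planted co-mention is the only possible
source of a link.  Placement, abstract order and years come from one
numpy PCG64 generator seeded by the spec (`seed` recorded in the ground
truth), giving byte-identical corpora per seed.

A plant is *full* (all `k` content words) or *partial* (exactly
`⌈3k/4⌉` of them) — the precise boundary between the two matching
rules.  Note `⌈3k/4⌉ = k` for `k ≤ 3`, so only terms with four or more
content words produce plants that exact mode can miss; the built-in
study dictionary includes a four-word event for this reason.  Ground
truth stores each plant's `(j, k)` and derives expected hits, pair
counts and contingency tables per mode.

The **built-in study design** (`planted_study_spec`): 12 terms (2
stressors, 10 events spanning 1–4 content words), 20 planted pairs with
counts 0–15 (98 pair abstracts), 52 singleton abstracts and 50
background abstracts — 200 records total, small enough that the whole
suite runs in seconds yet large enough that Fisher p-values spread
across all confidence bins.  Fixtures are structural, not linguistic:
passing tests demonstrate correctness of the mechanics (normalization,
matching arithmetic, counting, scoring, serialization), not performance
on real PubMed prose, where synonymy, negation and section structure
add noise the generator does not model.

## Numerical and degenerate-input choices

- ¾ threshold: exact integer comparison `4j ≥ 3k`.
- Fisher on `n_both = 0`: exactly 1.0 without calling scipy.
- Scored p-values clamped to `[0, 1]` against floating-point drift.
- Empty corpus text → zero sentences; a term whose every variant
  normalizes to nothing is rejected (it could never match).
- TSV/JSON floats serialized with `repr`, which round-trips exactly.
- Run metadata contains the full configuration and corpus size but no
  timestamps; wall time is logged, not written, so reruns are
  byte-identical.

## Known limitations

- No sentence-graph filtering of spurious mentions (as used by some
  co-occurrence miners); sentence scope is the stricter option offered
  instead.
- No fuzzy matching, abbreviation expansion, lemmatization or
  embeddings; recall on real text is bounded by dictionary and synonym
  quality.
- Co-occurrence is symmetric evidence: the network cannot orient key
  event relationships.
- The confidence bins are a package default, not a community standard;
  treat categories as a triage aid, not a weight-of-evidence verdict.
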