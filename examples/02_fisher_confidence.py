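"""Score links with the one-sided Fisher exact test and confidence bins.

For each link the 2x2 table (both / A only / B only / neither abstracts)
is tested for co-occurrence enrichment; the p-value and the abstract
count then map to a Low / Moderate / High / Very High category.  A small
p with many supporting abstracts means the pair co-occurs far more often
than independent mention rates would predict.
"""

from aopminer import (ContingencyTable, detect_terms, expand_dictionary,
                      extract_links, fisher_right_tail, hits_by_term,
                      normalize_document, score_links)
from aopminer.synth import generate_corpus, planted_study_spec, study_terms

# a worked 2x2 example: 8 co-mentions out of 200 abstracts
table = ContingencyTable(n_both=8, n_a_only=12, n_b_only=10, n_neither=170)
print(f"P(X >= 8 | margins 20, 18, N=200) = {fisher_right_tail(table):.3e}")

records, _ = generate_corpus(planted_study_spec(seed=1))
docs = [normalize_document(r) for r in records]
hits = detect_terms(docs, expand_dictionary(study_terms()))
stressors = {t.term_id for t in study_terms() if t.category == "stressor"}
events = {t.term_id for t in study_terms()} - stressors
links = extract_links(hits, stressors, events)
scored = score_links(links, hits_by_term(hits), len(records))

labels = {t.term_id: t.label for t in study_terms()}
print(f"\n{'pair':<40} {'count':>5} {'p-value':>10} confidence")
for link in sorted(scored, key=lambda l: l.p_value)[:8]:
    pair = f"{labels[link.source_id]} -- {labels[link.target_id]}"
    print(f"{pair:<40} {link.count:>5} {link.p_value:>10.4f} {link.confidence}")
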