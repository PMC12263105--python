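"""Build, filter and export the AOP network.

The undirected network links stressors and biological events; edge
weight is the number of supporting abstracts and edge color encodes the
confidence category.  Filtering keeps well-supported edges and drops
nodes left isolated; exports are a graph-viewer JSON and
Cytoscape-readable TSV tables.
"""

from aopminer import (annotate_events, build_network, detect_terms,
                      expand_dictionary, extract_links, filter_network,
                      hits_by_term, normalize_document, score_links,
                      to_edge_table_tsv, to_network_json)
from aopminer.synth import (generate_annotation_db, generate_corpus,
                            planted_study_spec, study_annotation_plan,
                            study_terms)

records, _ = generate_corpus(planted_study_spec(seed=1))
docs = [normalize_document(r) for r in records]
hits = detect_terms(docs, expand_dictionary(study_terms()))
stressors = {t.term_id for t in study_terms() if t.category == "stressor"}
events = {t.term_id for t in study_terms()} - stressors
scored = score_links(extract_links(hits, stressors, events),
                     hits_by_term(hits), len(records))

event_terms = [t for t in study_terms() if t.category != "stressor"]
ann = annotate_events(event_terms,
                      generate_annotation_db(event_terms,
                                             study_annotation_plan()))
net = build_network(scored, study_terms(), ann, metadata={"seed": 1})
print(f"full network: {net.n_nodes} nodes, {net.n_edges} edges")

kept = filter_network(net, min_count=5, min_confidence="High")
print(f"after min_count=5, min_confidence=High: "
      f"{kept.n_nodes} nodes, {kept.n_edges} edges\n")
print(to_edge_table_tsv(kept))
json_text = to_network_json(kept)
print(f"network JSON: {len(json_text)} bytes, "
      f"{json_text.count('confidence_color')} colored edges")
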