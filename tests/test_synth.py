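"""The planted-corpus generator and its ground truth."""

import pytest

from aopminer import (TermEntry, ValidationError, detect_terms,
                      expand_dictionary, normalize_document, write_corpus_tsv,
                      read_corpus_tsv)
from aopminer.synth import (FILLER_VOCABULARY, CorpusSpec, GroundTruth,
                            generate_corpus, planted_study_spec, study_terms)
from aopminer.textnorm import get_stemmer


def small_spec(seed=3):
    terms = (TermEntry("S", "radon", "stressor"),
             TermEntry("E", "oxidative stress", "KE"))
    return CorpusSpec(terms=terms, pair_counts=((("S", "E"), 3),),
                      n_background=7, seed=seed)


def test_abstract_count_is_sum_of_design():
    records, truth = generate_corpus(small_spec())
    assert len(records) == 10
    assert truth.n_records == 10
    assert truth.expected_pair_counts("partial") == {("E", "S"): 3}


def test_same_seed_byte_identical(tmp_path):
    r1, t1 = generate_corpus(small_spec())
    r2, t2 = generate_corpus(small_spec())
    write_corpus_tsv(r1, tmp_path / "a.tsv")
    write_corpus_tsv(r2, tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
    assert t1 == t2


def test_different_seed_differs():
    r1, _ = generate_corpus(small_spec(seed=3))
    r2, _ = generate_corpus(small_spec(seed=4))
    assert r1 != r2


def test_colliding_term_stems_rejected():
    terms = (TermEntry("A", "oxidative stress", "KE"),
             TermEntry("B", "stress response", "KE"))  # shares "stress"
    with pytest.raises(ValidationError, match="stress"):
        generate_corpus(CorpusSpec(terms=terms, pair_counts=((("A", "B"), 1),)))


def test_filler_vocabulary_is_inert():
    """Filler stems collide with no study-term stem and no stopword."""
    stemmer = get_stemmer()
    term_stems = set()
    for term in study_terms():
        for variant in (term.label, *term.synonyms):
            term_stems.update(stemmer.stem(t) for t in variant.split())
    filler_stems = {stemmer.stem(w) for w in FILLER_VOCABULARY}
    assert not filler_stems & term_stems


def test_detection_recovers_planted_hits_exactly(planted_corpus):
    _, records, truth = planted_corpus
    docs = [normalize_document(r) for r in records]
    expanded = expand_dictionary(study_terms())
    hits = detect_terms(docs, expanded, mode="partial")
    assert {(h.term_id, h.record_id) for h in hits} == \
        truth.expected_hits("partial")


def test_partial_plants_found_only_by_partial_mode(planted_corpus_partial):
    _, records, truth = planted_corpus_partial
    docs = [normalize_document(r) for r in records]
    expanded = expand_dictionary(study_terms())
    partial = {(h.term_id, h.record_id)
               for h in detect_terms(docs, expanded, mode="partial")}
    exact = {(h.term_id, h.record_id)
             for h in detect_terms(docs, expanded, mode="exact")}
    degraded = {(p.term_id, p.record_id) for p in truth.plants if not p.is_full}
    assert degraded  # the design does contain genuinely partial plants
    assert partial == truth.expected_hits("partial")
    assert exact == truth.expected_hits("exact") == partial - degraded


def test_spec_and_truth_json_round_trip():
    spec = planted_study_spec(seed=9, partial_fraction=0.3)
    assert CorpusSpec.from_json(spec.to_json()) == spec
    _, truth = generate_corpus(small_spec())
    assert GroundTruth.from_json(truth.to_json()) == truth


def test_generated_corpus_is_readable_corpus_tsv(tmp_path):
    records, _ = generate_corpus(small_spec())
    path = tmp_path / "corpus.tsv"
    write_corpus_tsv(records, path)
    assert read_corpus_tsv(path) == records
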