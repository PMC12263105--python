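"""Tokenization, phrase/document normalization and synonym expansion."""

import pytest

from aopminer import (AbstractRecord, TermEntry, ValidationError,
                      expand_term, normalize_document, normalize_phrase,
                      tokenize)
from aopminer.stopwords import DEFAULT_STOPWORDS
from aopminer.textnorm import _stemmed_stopwords, get_stemmer, split_sentences


@pytest.mark.parametrize("text,expected", [
    ("DNA double-strand breaks", ["dna", "double", "strand", "breaks"]),
    ("", []),
    ("TP53-mediated apoptosis.", ["tp53", "mediated", "apoptosis"]),
    ("radon/radiation exposure", ["radon", "radiation", "exposure"]),
    ("p53 and 42", ["p53", "and", "42"]),
])
def test_tokenize(text, expected):
    assert tokenize(text) == expected


def test_normalize_phrase_drops_stopwords_keeps_order():
    phrase = normalize_phrase("increase in oxidative stress")
    assert len(phrase.stems) == 3
    assert phrase.stems == tuple(
        get_stemmer().stem(w) for w in ["increase", "oxidative", "stress"]
    )
    assert phrase.stem_set == set(phrase.stems)


def test_phrase_of_only_stopwords_rejected():
    with pytest.raises(ValidationError):
        normalize_phrase("the of")


def test_unknown_stemmer_rejected():
    with pytest.raises(ValidationError):
        normalize_phrase("oxidative stress", stemmer_id="lancaster")


def test_no_output_stem_collides_with_stemmed_stopword():
    """Neither a stopword nor anything stemming like one may survive."""
    banned = _stemmed_stopwords(DEFAULT_STOPWORDS, "porter")
    text = ("During the study, being very useful, we observed doing "
            "increased oxidative stress and apoptosis in lung tissue.")
    phrase = normalize_phrase(text)
    assert not set(phrase.stems) & banned


def test_sentence_segmentation_and_union():
    rec = AbstractRecord("1", title="Radon exposure.",
                         body="It induces apoptosis! Cells die. qed")
    doc = normalize_document(rec)
    assert len(doc.sentence_stems) >= 3
    assert doc.all_stems == frozenset().union(*doc.sentence_stems)


def test_title_only_record_has_sentences():
    doc = normalize_document(AbstractRecord("2", title="Oxidative stress"))
    assert len(doc.sentence_stems) == 1
    assert doc.record_id == "2"


def test_split_sentences_requires_whitespace_after_terminal():
    assert split_sentences("p. 53 rules") == ["p.", "53 rules"]
    assert split_sentences("one. two! three? four") == \
        ["one.", "two!", "three?", "four"]


def test_normalization_idempotent_on_study_vocabulary(planted_corpus):
    """Re-normalizing the stems of every study abstract is a no-op."""
    _, records, _ = planted_corpus
    for rec in records[:50]:
        doc = normalize_document(rec)
        for stems in doc.sentence_stems:
            rejoined = " ".join(sorted(stems))
            again = normalize_phrase(rejoined)
            assert frozenset(again.stems) == stems


def test_expand_term_counts_and_dedup():
    entry = TermEntry("E1", "oxidative stress",
                      "KE", ("oxidant stress", "redox imbalance"))
    expanded = expand_term(entry)
    # "oxidant stress" stems identically to the label and is deduplicated
    assert len(expanded.phrases) == 2
    assert expanded.phrases[0].source_label == "oxidative stress"


def test_expand_term_gene_symbols():
    expanded = expand_term(TermEntry("G1", "TP53", "gene", ("p53",)))
    assert len(expanded.phrases) == 2
    assert all(len(p.stems) == 1 for p in expanded.phrases)
    assert expanded.phrases[0].stems == ("tp53",)


def test_expand_term_all_variants_empty_rejected():
    with pytest.raises(ValidationError):
        expand_term(TermEntry("E9", "the", "KE", ("of and",)))
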