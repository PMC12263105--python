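"""NLP standardization applied identically to terms, abstracts and keys.

The pipeline is deliberately minimal and rule-based so that identical
inputs give byte-identical outputs on every platform: lowercase
tokenization on letter/digit runs, stopword removal, then Porter
stemming.  Stopwords are filtered twice — as raw tokens before stemming
(exact list lookup) and again as stems against the stemmed stopword set,
so no emitted stem can collide with a function word's stem.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

from ._porter import PorterStemmer
from .errors import ValidationError
from .records import AbstractRecord, TermEntry
from .stopwords import DEFAULT_STOPWORDS

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)
_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+")

_STEMMERS = {"porter": PorterStemmer()}


def get_stemmer(stemmer_id: str = "porter"):
    """Return the registered stemmer object for ``stemmer_id``."""
    try:
        return _STEMMERS[stemmer_id]
    except KeyError:
        raise ValidationError(
            f"unknown stemmer {stemmer_id!r} (supported: {sorted(_STEMMERS)})"
        ) from None


@dataclass(frozen=True)
class NormalizedPhrase:
    """A term or text fragment reduced to ordered content-word stems."""

    source_label: str
    stems: tuple[str, ...]
    stem_set: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stem_set", frozenset(self.stems))


@dataclass(frozen=True)
class NormalizedDocument:
    """A literature record segmented into per-sentence stem sets."""

    record_id: str
    sentence_stems: tuple[frozenset[str], ...]
    all_stems: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "all_stems", frozenset().union(*self.sentence_stems)
            if self.sentence_stems else frozenset()
        )


@dataclass(frozen=True)
class ExpandedTerm:
    """A dictionary term with all synonym variants normalized."""

    term_id: str
    category: str
    phrases: tuple[NormalizedPhrase, ...]


def tokenize(text: str) -> list[str]:
    """Lowercase and split into maximal letter/digit runs.

    Hyphens, slashes and all other punctuation split tokens; purely
    numeric tokens are retained; order is preserved.
    """
    return _TOKEN_RE.findall(text.lower())


@lru_cache(maxsize=8)
def _stemmed_stopwords(stopwords: frozenset[str], stemmer_id: str) -> frozenset[str]:
    stemmer = get_stemmer(stemmer_id)
    return stopwords | {stemmer.stem(w) for w in stopwords}


def _content_stems(
    tokens: Iterable[str], stopwords: frozenset[str], stemmer_id: str
) -> list[str]:
    stemmer = get_stemmer(stemmer_id)
    banned = _stemmed_stopwords(stopwords, stemmer_id)
    return [
        stem
        for tok in tokens
        if tok not in stopwords
        for stem in (stemmer.stem(tok),)
        if stem not in banned
    ]


def normalize_phrase(
    label: str,
    stopwords: Optional[frozenset[str]] = None,
    stemmer_id: str = "porter",
) -> NormalizedPhrase:
    """Tokenize, drop stopwords, and stem a phrase, preserving order.

    Raises :class:`ValidationError` if no content word survives — such a
    phrase can never be matched.
    """
    stopwords = DEFAULT_STOPWORDS if stopwords is None else stopwords
    get_stemmer(stemmer_id)  # fail fast on unknown stemmer
    stems = _content_stems(tokenize(label), stopwords, stemmer_id)
    if not stems:
        raise ValidationError(f"phrase {label!r} has no content words after filtering")
    return NormalizedPhrase(source_label=label, stems=tuple(stems))


def split_sentences(text: str) -> list[str]:
    """Rule-based segmentation on '.', '!' or '?' followed by whitespace."""
    return [s for s in _SENTENCE_RE.split(text) if s.strip()]


def normalize_document(
    rec: AbstractRecord,
    stopwords: Optional[frozenset[str]] = None,
    stemmer_id: str = "porter",
) -> NormalizedDocument:
    """Normalize title + body into per-sentence stem sets."""
    stopwords = DEFAULT_STOPWORDS if stopwords is None else stopwords
    get_stemmer(stemmer_id)
    text = (rec.title + " " + rec.body).strip()
    sentence_stems = []
    for sentence in split_sentences(text):
        stems = _content_stems(tokenize(sentence), stopwords, stemmer_id)
        if stems:
            sentence_stems.append(frozenset(stems))
    return NormalizedDocument(record_id=rec.record_id,
                              sentence_stems=tuple(sentence_stems))


def expand_term(
    entry: TermEntry,
    stopwords: Optional[frozenset[str]] = None,
    stemmer_id: str = "porter",
) -> ExpandedTerm:
    """Normalize a term's label and every synonym.

    Variants that duplicate an earlier variant's stem set are dropped
    (label variant kept first).  A term whose every variant fails to
    normalize cannot be matched and raises :class:`ValidationError`.
    """
    phrases: list[NormalizedPhrase] = []
    seen: set[frozenset[str]] = set()
    failures: list[str] = []
    for variant in (entry.label, *entry.synonyms):
        try:
            phrase = normalize_phrase(variant, stopwords, stemmer_id)
        except ValidationError as exc:
            failures.append(str(exc))
            continue
        if phrase.stem_set not in seen:
            seen.add(phrase.stem_set)
            phrases.append(phrase)
    if not phrases:
        raise ValidationError(
            f"term {entry.term_id!r}: no variant has content words "
            f"({'; '.join(failures)})"
        )
    return ExpandedTerm(term_id=entry.term_id, category=entry.category,
                        phrases=tuple(phrases))


def expand_dictionary(
    entries: Iterable[TermEntry],
    stopwords: Optional[frozenset[str]] = None,
    stemmer_id: str = "porter",
) -> list[ExpandedTerm]:
    return [expand_term(e, stopwords, stemmer_id) for e in entries]
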