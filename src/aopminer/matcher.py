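"""Detection of dictionary terms in normalized documents.

Two matching regimes are supported, mirroring the tool's two text-mining
modes: ``partial`` requires at least three quarters of a term's content
stems to be present (the original, recall-oriented rule), ``exact``
requires every stem (precision-oriented, fewer false positives).  The
3/4 threshold is evaluated in integer arithmetic (``4*j >= 3*k``), never
with floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal

from .errors import ValidationError
from .textnorm import ExpandedTerm, NormalizedDocument, NormalizedPhrase

Mode = Literal["partial", "exact"]
Scope = Literal["abstract", "sentence"]

MODES = ("partial", "exact")
SCOPES = ("abstract", "sentence")


@dataclass(frozen=True)
class DetectionHit:
    """One detected (term, record) pair.

    ``best_fraction`` is the maximum matched-stem fraction attained over
    all synonym variants (and sentences, under sentence scope).
    """

    term_id: str
    record_id: str
    best_fraction: float
    mode: Mode


def match_phrase(
    phrase: NormalizedPhrase, stems: frozenset[str] | set[str], mode: Mode
) -> tuple[bool, float]:
    """Match one normalized phrase against a stem set.

    Returns ``(matched, fraction)`` where fraction = matched distinct
    stems / distinct phrase stems.
    """
    k = len(phrase.stem_set)
    if k == 0:
        raise ValidationError(f"phrase {phrase.source_label!r} has no stems")
    j = len(phrase.stem_set & stems)
    if mode == "partial":
        matched = 4 * j >= 3 * k
    elif mode == "exact":
        matched = j == k
    else:
        raise ValidationError(f"unknown match mode {mode!r}")
    return matched, float(Fraction(j, k))


def detect_terms(
    docs: Iterable[NormalizedDocument],
    dictionary: Iterable[ExpandedTerm],
    mode: Mode = "partial",
    scope: Scope = "abstract",
) -> list[DetectionHit]:
    """Detect every dictionary term in every document.

    Under ``abstract`` scope a term may match with its stems spread over
    the whole record; under ``sentence`` scope some single sentence must
    satisfy the rule on its own.  At most one hit is emitted per
    (term, record), carrying the best fraction attained.
    """
    dictionary = list(dictionary)
    if not dictionary:
        raise ValidationError("dictionary is empty")
    if scope not in SCOPES:
        raise ValidationError(f"unknown scope {scope!r}")
    hits: list[DetectionHit] = []
    for doc in docs:
        scopes = [doc.all_stems] if scope == "abstract" else list(doc.sentence_stems)
        for term in dictionary:
            best = 0.0
            matched = False
            for phrase in term.phrases:
                for stem_set in scopes:
                    ok, fraction = match_phrase(phrase, stem_set, mode)
                    matched = matched or ok
                    if fraction > best:
                        best = fraction
            if matched:
                hits.append(
                    DetectionHit(term_id=term.term_id, record_id=doc.record_id,
                                 best_fraction=best, mode=mode)
                )
    hits.sort(key=lambda h: (h.term_id, h.record_id))
    return hits


def hits_by_term(hits: Iterable[DetectionHit]) -> dict[str, set[str]]:
    """Group hit record ids by term id."""
    out: dict[str, set[str]] = {}
    for h in hits:
        out.setdefault(h.term_id, set()).add(h.record_id)
    return out
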