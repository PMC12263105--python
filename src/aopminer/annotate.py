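"""Multi-source database annotation of detected biological events.

Annotation keys and event terms go through the same normalization used
for literature matching, so "Lung Cancer" in an extract annotates the
event "lung cancer".  Gene-category terms are additionally matched by
case-insensitive raw symbol equality, because stemming can mangle
symbols and databases key genes by symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .errors import ValidationError
from .records import AnnotationRecord, TermEntry
from .textnorm import expand_term, normalize_phrase

AnnotationRule = Literal["exact-normalized", "partial"]
ANNOTATION_RULES = ("exact-normalized", "partial")


@dataclass(frozen=True)
class EventAnnotationSet:
    """All annotations attached to one event term, grouped by source."""

    term_id: str
    by_source: tuple[tuple[str, tuple[AnnotationRecord, ...]], ...] = ()

    @property
    def annotations(self) -> tuple[AnnotationRecord, ...]:
        return tuple(a for _, group in self.by_source for a in group)

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)


def _matches(
    event_phrases, event_raw: set[str], is_gene: bool,
    key_phrase, key_raw: str, rule: AnnotationRule,
) -> bool:
    if is_gene and key_raw.lower() in event_raw:
        return True
    if key_phrase is None:
        return False
    for phrase in event_phrases:
        if rule == "exact-normalized":
            if phrase.stem_set == key_phrase.stem_set:
                return True
        else:  # partial: key stems cover >= 3/4 of the event's stems
            k = len(phrase.stem_set)
            j = len(phrase.stem_set & key_phrase.stem_set)
            if 4 * j >= 3 * k:
                return True
    return False


def annotate_events(
    events: Iterable[TermEntry],
    db: Iterable[AnnotationRecord],
    stopwords: Optional[frozenset[str]] = None,
    stemmer_id: str = "porter",
    rule: AnnotationRule = "exact-normalized",
) -> list[EventAnnotationSet]:
    """Attach matching database records to every event term.

    Every event yields an :class:`EventAnnotationSet`, empty if nothing
    matches; annotations are deduplicated by (source_db, annotation_id).
    """
    events = list(events)
    if not events:
        raise ValidationError("events list is empty")
    if rule not in ANNOTATION_RULES:
        raise ValidationError(f"unknown annotation rule {rule!r}")
    db = list(db)

    # normalize each distinct key once; keys with no content words can
    # still match gene symbols by raw equality
    key_phrases = {}
    for rec in db:
        if rec.key_term not in key_phrases:
            try:
                key_phrases[rec.key_term] = normalize_phrase(
                    rec.key_term, stopwords, stemmer_id)
            except ValidationError:
                key_phrases[rec.key_term] = None

    out = []
    for event in events:
        expanded = expand_term(event, stopwords, stemmer_id)
        raw_variants = {event.label.lower(), *(s.lower() for s in event.synonyms)}
        is_gene = event.category == "gene"
        seen: set[tuple[str, str]] = set()
        groups: dict[str, list[AnnotationRecord]] = {}
        for rec in db:
            if (rec.source_db, rec.annotation_id) in seen:
                continue
            if _matches(expanded.phrases, raw_variants, is_gene,
                        key_phrases[rec.key_term], rec.key_term, rule):
                seen.add((rec.source_db, rec.annotation_id))
                groups.setdefault(rec.source_db, []).append(rec)
        by_source = tuple(
            (src, tuple(sorted(groups[src], key=lambda r: r.annotation_id)))
            for src in sorted(groups)
        )
        out.append(EventAnnotationSet(term_id=event.term_id, by_source=by_source))
    return out


def summarize_annotations(sets: Iterable[EventAnnotationSet]):
    """Per-(term, source) annotation counts as a DataFrame.

    Columns: term_id, source_db, n_annotations; one row per nonempty
    group, so the column sum equals the total annotation count.
    """
    import pandas as pd

    rows = [
        {"term_id": s.term_id, "source_db": src, "n_annotations": len(group)}
        for s in sets
        for src, group in s.by_source
    ]
    return pd.DataFrame(rows, columns=["term_id", "source_db", "n_annotations"])
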