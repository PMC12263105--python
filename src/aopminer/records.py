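"""Core domain records: literature abstracts, dictionary terms, annotations.

These are plain frozen dataclasses; invariants that only make sense for a
whole collection (uniqueness of identifiers within a corpus or
dictionary) are enforced by the readers in :mod:`aopminer.io` and by the
collection validators here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ValidationError

#: Term categories. ``stressor`` is the exposure side; MIE / KE / AO are
#: the Adverse Outcome Pathway event levels; ``gene`` marks symbols that
#: are annotation-matched by identity rather than by stemmed phrase.
TERM_CATEGORIES = frozenset(
    {"stressor", "MIE", "KE", "AO", "gene", "event-unspecified"}
)

SOURCE_DBS = frozenset(
    {"AOP-Wiki", "HPA", "KEGG", "Reactome", "WikiPathways", "UniProt",
     "DISEASES", "DisGeNET"}
)

ANNOTATION_CLASSES = frozenset({"AOP", "pathway", "disease", "tissue", "process"})


@dataclass(frozen=True)
class AbstractRecord:
    """One literature record (PMID-like id, year, title, abstract body)."""

    record_id: str
    title: str = ""
    body: str = ""
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValidationError("record_id must be nonempty")
        if not self.title and not self.body:
            raise ValidationError(
                f"record {self.record_id!r}: title and body are both empty"
            )


@dataclass(frozen=True)
class TermEntry:
    """A dictionary term (stressor or biological event/gene) with synonyms."""

    term_id: str
    label: str
    category: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValidationError("term_id must be nonempty")
        if not self.label:
            raise ValidationError(f"term {self.term_id!r}: label must be nonempty")
        if self.category not in TERM_CATEGORIES:
            raise ValidationError(
                f"term {self.term_id!r}: unknown category {self.category!r} "
                f"(allowed: {sorted(TERM_CATEGORIES)})"
            )
        object.__setattr__(self, "synonyms", tuple(self.synonyms))


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of a local annotation-database extract."""

    source_db: str
    key_term: str
    annotation_id: str
    annotation_label: str
    annotation_class: str

    def __post_init__(self) -> None:
        if self.source_db not in SOURCE_DBS:
            raise ValidationError(
                f"unknown source_db {self.source_db!r} (allowed: {sorted(SOURCE_DBS)})"
            )
        if not self.key_term:
            raise ValidationError("annotation key_term must be nonempty")
        if not self.annotation_id:
            raise ValidationError("annotation_id must be nonempty")
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise ValidationError(
                f"unknown annotation_class {self.annotation_class!r} "
                f"(allowed: {sorted(ANNOTATION_CLASSES)})"
            )


def check_unique(ids: Sequence[str], what: str) -> None:
    """Raise :class:`ValidationError` listing any duplicated identifiers."""
    dupes = sorted(i for i, n in Counter(ids).items() if n > 1)
    if dupes:
        raise ValidationError(f"duplicate {what}: {', '.join(map(repr, dupes))}")
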