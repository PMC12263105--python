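"""Readers and writers for all external tabular and MEDLINE formats.

All tabular formats are UTF-8 TSV with a fixed header; a non-UTF-8 byte
is an error rather than being silently replaced, so that runs are
reproducible across machines and locales.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from Bio import Medline

from .errors import FormatError, ValidationError
from .records import AbstractRecord, AnnotationRecord, TermEntry, check_unique

CORPUS_COLUMNS = ["record_id", "year", "title", "abstract"]
DICTIONARY_COLUMNS = ["term_id", "label", "category", "synonyms"]
ANNOTATION_COLUMNS = [
    "source_db", "key_term", "annotation_id", "annotation_label", "annotation_class",
]

SYNONYM_SEP = "|"


def _read_tsv_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    try:
        text = Path(path).read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: not valid UTF-8 ({exc})") from None
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return [{k: (v or "") for k, v in row.items()} for row in reader]


# ---------------------------------------------------------------- corpora

def read_corpus_tsv(path: str | Path) -> list[AbstractRecord]:
    """Read a corpus TSV (columns record_id, year, title, abstract)."""
    rows = _read_tsv_rows(path, CORPUS_COLUMNS)
    records = []
    for row in rows:
        year_text = row["year"].strip()
        try:
            year = int(year_text) if year_text else None
        except ValueError:
            raise FormatError(
                f"{path}: record {row['record_id']!r}: non-integer year {year_text!r}"
            ) from None
        records.append(
            AbstractRecord(
                record_id=row["record_id"],
                title=row["title"],
                body=row["abstract"],
                year=year,
            )
        )
    check_unique([r.record_id for r in records], "record_id")
    return records


def write_corpus_tsv(records: Iterable[AbstractRecord], path: str | Path) -> None:
    lines = ["\t".join(CORPUS_COLUMNS)]
    for r in records:
        year = "" if r.year is None else str(r.year)
        lines.append("\t".join([r.record_id, year, r.title, r.body]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_medline(path: str | Path) -> list[AbstractRecord]:
    """Read a MEDLINE tagged-format export (PMID-/TI-/AB-/DP- fields).

    Continuation lines are joined with single spaces; the year is the
    first four-digit token of the DP (date of publication) field.
    """
    try:
        with open(path, encoding="utf-8") as handle:
            entries = list(Medline.parse(handle))
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: not valid UTF-8 ({exc})") from None
    records = []
    for entry in entries:
        pmid = entry.get("PMID", "")
        if not pmid:
            raise ValidationError(f"{path}: MEDLINE record without PMID field")
        year = None
        for token in entry.get("DP", "").replace("-", " ").split():
            if len(token) == 4 and token.isdigit():
                year = int(token)
                break
        records.append(
            AbstractRecord(
                record_id=pmid,
                title=entry.get("TI", ""),
                body=entry.get("AB", ""),
                year=year,
            )
        )
    check_unique([r.record_id for r in records], "record_id")
    return records


# ------------------------------------------------------------ dictionaries

def read_dictionary(path: str | Path) -> list[TermEntry]:
    """Read a term dictionary TSV; synonyms are pipe-separated."""
    rows = _read_tsv_rows(path, DICTIONARY_COLUMNS)
    entries = []
    for i, row in enumerate(rows, start=2):
        synonyms = tuple(
            s.strip() for s in row["synonyms"].split(SYNONYM_SEP) if s.strip()
        )
        try:
            entries.append(
                TermEntry(
                    term_id=row["term_id"],
                    label=row["label"],
                    category=row["category"],
                    synonyms=synonyms,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from None
    check_unique([e.term_id for e in entries], "term_id")
    return entries


def write_dictionary_tsv(entries: Iterable[TermEntry], path: str | Path) -> None:
    lines = ["\t".join(DICTIONARY_COLUMNS)]
    for e in entries:
        lines.append(
            "\t".join([e.term_id, e.label, e.category, SYNONYM_SEP.join(e.synonyms)])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -------------------------------------------------------- annotation DBs

def read_annotation_db(path: str | Path) -> list[AnnotationRecord]:
    """Read one annotation-database extract TSV."""
    rows = _read_tsv_rows(path, ANNOTATION_COLUMNS)
    records = []
    for i, row in enumerate(rows, start=2):
        try:
            records.append(AnnotationRecord(**{c: row[c] for c in ANNOTATION_COLUMNS}))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from None
    return records


def write_annotation_tsv(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join([r.source_db, r.key_term, r.annotation_id,
                       r.annotation_label, r.annotation_class])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotation_dir(directory: str | Path) -> list[AnnotationRecord]:
    """Concatenate every ``*.tsv`` extract in a directory (sorted by name)."""
    paths = sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise ValidationError(f"{directory}: no .tsv annotation extracts found")
    records: list[AnnotationRecord] = []
    for p in paths:
        records.extend(read_annotation_db(p))
    return records
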