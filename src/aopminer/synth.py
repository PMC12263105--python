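"""Synthetic corpora, dictionaries and annotation extracts with planted,
fully known structure.

The generator embeds the content words of dictionary terms inside filler
sentences built from a fixed vocabulary whose stems are checked to be
disjoint from every term stem, so a planted co-mention is the only way a
link can arise.  A plant is *full* (all k content words of the term) or
*partial* (exactly ceil(3k/4) of them), which is precisely the boundary
between the exact and the three-quarters matching rules.  Randomness
(word placement, abstract order, years) comes from one numpy PCG64
generator seeded by the spec, so a spec generates byte-identical corpora
on every run.

Fixtures are structural, not linguistic: no attempt is made to mimic
real PubMed prose statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import ValidationError
from .records import AbstractRecord, AnnotationRecord, TermEntry
from .stopwords import DEFAULT_STOPWORDS
from .textnorm import get_stemmer, tokenize

PRNG_ID = "numpy-PCG64"

#: Filler vocabulary for titles and padding sentences.  Invented,
#: stopword-free words whose stems collide with no real dictionary term
#: (verified again at generation time against the actual term list).
FILLER_VOCABULARY = (
    "blarnic", "crondle", "dravick", "fenwold", "glimber", "harvex",
    "jintrel", "kelmora", "lorvane", "mindrax", "norvell", "plimshaw",
    "quendrel", "ruvanto", "sarbelin", "tremvick", "ulmandra", "vorplex",
    "wintrell", "xandrel", "yorvane", "zelmont", "brundex", "clarvon",
    "dremlin", "farnwick", "grelmora", "hulvane", "janvick", "korbelle",
)

_CLASS_BY_SOURCE = {
    "AOP-Wiki": "AOP",
    "HPA": "tissue",
    "KEGG": "pathway",
    "Reactome": "pathway",
    "WikiPathways": "pathway",
    "UniProt": "process",
    "DISEASES": "disease",
    "DisGeNET": "disease",
}

Pair = tuple[str, str]


def _canon(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class CorpusSpec:
    """Planted design of a synthetic corpus.

    ``pair_counts`` maps unordered term pairs to the number of abstracts
    co-mentioning both terms; ``singleton_counts`` adds solo-mention
    abstracts; ``n_background`` abstracts mention no term at all.
    ``partial_fraction_plants`` optionally makes a fraction of a pair's
    plants partial (one endpoint planted with ceil(3k/4) of its k
    stems).
    """

    terms: tuple[TermEntry, ...]
    pair_counts: tuple[tuple[Pair, int], ...]
    singleton_counts: tuple[tuple[str, int], ...] = ()
    n_background: int = 0
    partial_fraction_plants: tuple[tuple[Pair, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        ids = {t.term_id for t in self.terms}
        object.__setattr__(
            self, "pair_counts",
            tuple(sorted((_canon(*p), int(n)) for p, n in self.pair_counts)),
        )
        object.__setattr__(
            self, "singleton_counts",
            tuple(sorted((t, int(n)) for t, n in self.singleton_counts)),
        )
        object.__setattr__(
            self, "partial_fraction_plants",
            tuple(sorted((_canon(*p), float(f))
                         for p, f in self.partial_fraction_plants)),
        )
        for (a, b), n in self.pair_counts:
            if a == b or a not in ids or b not in ids:
                raise ValidationError(f"bad pair ({a!r}, {b!r})")
            if n < 0:
                raise ValidationError(f"negative count for pair ({a!r}, {b!r})")
        for t, n in self.singleton_counts:
            if t not in ids:
                raise ValidationError(f"unknown singleton term {t!r}")
            if n < 0:
                raise ValidationError(f"negative singleton count for {t!r}")
        if self.n_background < 0:
            raise ValidationError("n_background must be >= 0")
        for p, f in self.partial_fraction_plants:
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"partial fraction for {p} outside [0,1]")

    @property
    def n_abstracts(self) -> int:
        return (sum(n for _, n in self.pair_counts)
                + sum(n for _, n in self.singleton_counts)
                + self.n_background)

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [
                    {"term_id": t.term_id, "label": t.label,
                     "category": t.category, "synonyms": list(t.synonyms)}
                    for t in self.terms
                ],
                "pair_counts": [[a, b, n] for (a, b), n in self.pair_counts],
                "singleton_counts": [[t, n] for t, n in self.singleton_counts],
                "n_background": self.n_background,
                "partial_fraction_plants": [
                    [a, b, f] for (a, b), f in self.partial_fraction_plants
                ],
                "seed": self.seed,
            },
            indent=2, sort_keys=True,
        ) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "CorpusSpec":
        d = json.loads(text)
        return cls(
            terms=tuple(
                TermEntry(t["term_id"], t["label"], t["category"],
                          tuple(t.get("synonyms", ())))
                for t in d["terms"]
            ),
            pair_counts=tuple(((a, b), n) for a, b, n in d["pair_counts"]),
            singleton_counts=tuple(
                (t, n) for t, n in d.get("singleton_counts", ())
            ),
            n_background=d.get("n_background", 0),
            partial_fraction_plants=tuple(
                ((a, b), f) for a, b, f in d.get("partial_fraction_plants", ())
            ),
            seed=d.get("seed", 0),
        )


@dataclass(frozen=True)
class Plant:
    """One planted term occurrence: j of the term's k stems embedded."""

    record_id: str
    term_id: str
    n_planted: int
    n_total: int

    @property
    def is_full(self) -> bool:
        return self.n_planted == self.n_total


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator planted, queryable per matching mode."""

    seed: int
    n_records: int
    plants: tuple[Plant, ...]
    stemmer_id: str = "porter"
    prng: str = PRNG_ID

    def expected_hits(self, mode: str) -> set[tuple[str, str]]:
        """(term_id, record_id) pairs a detector in ``mode`` must find.

        Partial plants carry ceil(3k/4) stems by construction, so they
        are found by the three-quarters rule but not by the exact rule
        (unless ceil(3k/4) == k, i.e. the plant was effectively full).
        """
        if mode == "partial":
            return {(p.term_id, p.record_id) for p in self.plants}
        if mode == "exact":
            return {(p.term_id, p.record_id) for p in self.plants if p.is_full}
        raise ValidationError(f"unknown mode {mode!r}")

    def term_records(self, mode: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for term_id, record_id in self.expected_hits(mode):
            out.setdefault(term_id, set()).add(record_id)
        return out

    def expected_pair_records(self, mode: str) -> dict[Pair, set[str]]:
        """Records where both terms of a pair are expected to hit."""
        by_record: dict[str, set[str]] = {}
        for term_id, record_id in self.expected_hits(mode):
            by_record.setdefault(record_id, set()).add(term_id)
        pairs: dict[Pair, set[str]] = {}
        for record_id, terms in by_record.items():
            for a in terms:
                for b in terms:
                    if a < b:
                        pairs.setdefault((a, b), set()).add(record_id)
        return pairs

    def expected_pair_counts(self, mode: str) -> dict[Pair, int]:
        return {p: len(r) for p, r in self.expected_pair_records(mode).items()}

    def expected_contingency(self, a: str, b: str, mode: str) -> tuple[int, int, int, int]:
        """(n_both, n_a_only, n_b_only, n_neither) against all records."""
        recs = self.term_records(mode)
        ra, rb = recs.get(a, set()), recs.get(b, set())
        both = len(ra & rb)
        return (both, len(ra - rb), len(rb - ra),
                self.n_records - len(ra | rb))

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "prng": self.prng, "stemmer_id": self.stemmer_id,
             "n_records": self.n_records,
             "plants": [[p.record_id, p.term_id, p.n_planted, p.n_total]
                        for p in self.plants]},
            indent=2, sort_keys=True,
        ) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(seed=d["seed"], prng=d["prng"], stemmer_id=d["stemmer_id"],
                   n_records=d["n_records"],
                   plants=tuple(Plant(*p) for p in d["plants"]))


def _content_tokens(label: str, stopwords, stemmer) -> list[tuple[str, str]]:
    """(surface token, stem) pairs for a label's content words."""
    out = []
    stemmed_stops = {stemmer.stem(w) for w in stopwords}
    for tok in tokenize(label):
        if tok in stopwords:
            continue
        stem = stemmer.stem(tok)
        if stem in stopwords or stem in stemmed_stops:
            continue
        out.append((tok, stem))
    return out


def _validate_terms(terms, stopwords, stemmer) -> dict[str, list[tuple[str, str]]]:
    """Check stem disjointness across terms and within each label."""
    tokens_by_term: dict[str, list[tuple[str, str]]] = {}
    stem_owner: dict[str, str] = {}
    for term in terms:
        variants = [term.label, *term.synonyms]
        label_tokens = _content_tokens(term.label, stopwords, stemmer)
        if not label_tokens:
            raise ValidationError(f"term {term.term_id!r}: label has no content words")
        stems = [s for _, s in label_tokens]
        if len(set(stems)) != len(stems):
            raise ValidationError(
                f"term {term.term_id!r}: label stems are not distinct"
            )
        tokens_by_term[term.term_id] = label_tokens
        for variant in variants:
            for _, stem in _content_tokens(variant, stopwords, stemmer):
                owner = stem_owner.get(stem)
                if owner is not None and owner != term.term_id:
                    raise ValidationError(
                        f"terms {owner!r} and {term.term_id!r} share stem {stem!r}"
                    )
                stem_owner[stem] = term.term_id
    for word in FILLER_VOCABULARY:
        stem = stemmer.stem(word)
        if stem in stem_owner:
            raise ValidationError(
                f"filler word {word!r} collides with term {stem_owner[stem]!r}"
            )
    return tokens_by_term


def generate_corpus(
    spec: CorpusSpec,
    stopwords: Optional[frozenset[str]] = None,
    stemmer_id: str = "porter",
) -> tuple[list[AbstractRecord], GroundTruth]:
    """Emit a corpus with the spec's planted structure plus ground truth."""
    stopwords = DEFAULT_STOPWORDS if stopwords is None else stopwords
    stemmer = get_stemmer(stemmer_id)
    tokens_by_term = _validate_terms(spec.terms, stopwords, stemmer)
    rng = np.random.default_rng(spec.seed)
    partial_fraction = dict(spec.partial_fraction_plants)

    # one task = the list of (term_id, planted surface tokens, j, k)
    tasks: list[list[tuple[str, list[str], int, int]]] = []
    for (a, b), count in spec.pair_counts:
        n_partial = int(round(partial_fraction.get((a, b), 0.0) * count))
        # the partial plant degrades the endpoint with more stems, where
        # the 3/4 rule actually bites; ties break to the later term id
        ka, kb = len(tokens_by_term[a]), len(tokens_by_term[b])
        degraded = a if ka > kb else b
        for i in range(count):
            plant = []
            for term_id in (a, b):
                tokens = tokens_by_term[term_id]
                k = len(tokens)
                if i < n_partial and term_id == degraded:
                    j = math.ceil(3 * k / 4)
                    idx = sorted(rng.choice(k, size=j, replace=False).tolist())
                    plant.append((term_id, [tokens[x][0] for x in idx], j, k))
                else:
                    plant.append((term_id, [t for t, _ in tokens], k, k))
            tasks.append(plant)
    for term_id, count in spec.singleton_counts:
        tokens = tokens_by_term[term_id]
        k = len(tokens)
        for _ in range(count):
            tasks.append([(term_id, [t for t, _ in tokens], k, k)])
    tasks.extend([[] for _ in range(spec.n_background)])

    order = rng.permutation(len(tasks))
    filler = list(FILLER_VOCABULARY)

    def fill(n: int) -> list[str]:
        return [filler[i] for i in rng.integers(0, len(filler), size=n)]

    records: list[AbstractRecord] = []
    plants: list[Plant] = []
    for position, task_index in enumerate(order):
        record_id = str(100001 + position)
        task = tasks[task_index]
        title = " ".join(fill(3)).capitalize() + "."
        sentences = [" ".join(fill(int(rng.integers(4, 9)))).capitalize() + "."]
        for term_id, tokens, j, k in task:
            words = fill(2) + list(tokens) + fill(2)
            sentences.append(" ".join(words).capitalize() + ".")
            plants.append(Plant(record_id=record_id, term_id=term_id,
                                n_planted=j, n_total=k))
        sentences.append(" ".join(fill(int(rng.integers(4, 9)))).capitalize() + ".")
        records.append(
            AbstractRecord(record_id=record_id, title=title,
                           body=" ".join(sentences),
                           year=int(rng.integers(1995, 2026)))
        )
    plants.sort(key=lambda p: (p.record_id, p.term_id))
    truth = GroundTruth(seed=spec.seed, n_records=len(records),
                        plants=tuple(plants), stemmer_id=stemmer_id)
    return records, truth


def generate_annotation_db(
    events: Iterable[TermEntry],
    plan: Mapping[str, Iterable[tuple[str, int]]],
    n_decoys: int = 3,
) -> list[AnnotationRecord]:
    """Emit annotation records keyed by event labels, per plan.

    ``plan`` maps term_id -> [(source_db, n), ...]; ``n_decoys`` extra
    records are keyed to labels matching no event (negative controls).
    """
    by_id = {t.term_id: t for t in events}
    out: list[AnnotationRecord] = []
    for term_id in sorted(plan):
        if term_id not in by_id:
            raise ValidationError(f"annotation plan references unknown term {term_id!r}")
        for source_db, n in plan[term_id]:
            for i in range(1, int(n) + 1):
                out.append(
                    AnnotationRecord(
                        source_db=source_db,
                        key_term=by_id[term_id].label,
                        annotation_id=f"{source_db}:{term_id}:{i}",
                        annotation_label=f"{by_id[term_id].label} "
                                         f"{_CLASS_BY_SOURCE[source_db]} {i}",
                        annotation_class=_CLASS_BY_SOURCE[source_db],
                    )
                )
    for i in range(1, n_decoys + 1):
        out.append(
            AnnotationRecord(
                source_db="KEGG",
                key_term=f"decoyentity{i}",
                annotation_id=f"KEGG:DECOY:{i}",
                annotation_label=f"decoy pathway {i}",
                annotation_class="pathway",
            )
        )
    return out


# -------------------------------------------------- canonical study spec

def study_terms() -> tuple[TermEntry, ...]:
    """The 12-term dictionary of the built-in planted study: two
    stressors and ten biological events spanning 1-4 content words."""
    return (
        TermEntry("S1", "radon", "stressor"),
        TermEntry("S2", "cadmium", "stressor"),
        TermEntry("E1", "oxidative stress", "KE", ("oxidant stress",)),
        TermEntry("E2", "dna double strand breaks", "MIE"),
        TermEntry("E3", "apoptosis", "KE", ("programmed apoptosis",)),
        TermEntry("E4", "cell cycle arrest", "KE"),
        TermEntry("E5", "genomic instability", "KE"),
        TermEntry("E6", "chronic inflammation", "KE"),
        TermEntry("E7", "tp53", "gene"),
        TermEntry("E8", "lung cancer", "AO"),
        TermEntry("E9", "mitochondrial dysfunction", "MIE"),
        TermEntry("E10", "chromosomal aberration", "KE"),
    )


#: Planted pair design: co-mention counts span 0..15.
STUDY_PAIR_COUNTS: tuple[tuple[Pair, int], ...] = (
    (("S1", "E1"), 15), (("S1", "E2"), 12), (("S1", "E3"), 10),
    (("S1", "E8"), 9), (("S1", "E7"), 8), (("S2", "E1"), 7),
    (("S2", "E5"), 6), (("E1", "E3"), 5), (("E2", "E5"), 5),
    (("E3", "E4"), 4), (("E1", "E6"), 4), (("E7", "E8"), 3),
    (("E3", "E9"), 3), (("E10", "E5"), 2), (("E6", "E8"), 2),
    (("S1", "E9"), 1), (("E10", "E2"), 1), (("S2", "E4"), 1),
    (("S1", "E10"), 0), (("E4", "E6"), 0),
)

STUDY_SINGLETON_COUNTS: tuple[tuple[str, int], ...] = (
    ("S1", 6), ("S2", 4), ("E1", 5), ("E2", 5), ("E3", 5), ("E4", 4),
    ("E5", 4), ("E6", 4), ("E7", 4), ("E8", 4), ("E9", 4), ("E10", 3),
)


def planted_study_spec(seed: int = 0, partial_fraction: float = 0.0) -> CorpusSpec:
    """The built-in study design: 12 terms, 200 abstracts (50 of them
    background), pair counts 0-15.  ``partial_fraction`` degrades that
    share of every pair's plants to ceil(3k/4)-stem partial plants."""
    partial = tuple(
        (pair, partial_fraction) for pair, n in STUDY_PAIR_COUNTS if n > 0
    ) if partial_fraction > 0 else ()
    return CorpusSpec(
        terms=study_terms(),
        pair_counts=STUDY_PAIR_COUNTS,
        singleton_counts=STUDY_SINGLETON_COUNTS,
        n_background=50,
        partial_fraction_plants=partial,
        seed=seed,
    )


def study_annotation_plan() -> dict[str, list[tuple[str, int]]]:
    """Per-source annotation counts for the built-in study events."""
    return {
        "E1": [("AOP-Wiki", 2), ("KEGG", 1)],
        "E2": [("AOP-Wiki", 1), ("Reactome", 2)],
        "E3": [("KEGG", 2), ("WikiPathways", 1)],
        "E4": [("Reactome", 1)],
        "E5": [("AOP-Wiki", 1)],
        "E6": [("DISEASES", 2)],
        "E7": [("DisGeNET", 3), ("UniProt", 2), ("HPA", 1)],
        "E8": [("DISEASES", 2), ("DisGeNET", 1)],
        "E9": [("Reactome", 1), ("KEGG", 1)],
        "E10": [("AOP-Wiki", 1)],
    }
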