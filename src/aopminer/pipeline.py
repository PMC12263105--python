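"""End-to-end orchestration: corpus -> normalize -> match -> link ->
score -> annotate -> network -> files.

``run`` is deterministic: identical inputs and configuration produce
byte-identical output files (all collections are emitted in sorted
order and no timestamps enter the outputs).  Wall time and per-stage
record counts are reported through logging only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .annotate import ANNOTATION_RULES, annotate_events
from .errors import ConfigError
from .io import (read_annotation_dir, read_corpus_tsv, read_dictionary,
                 read_medline)
from .linking import (CONFIDENCE_RANK, LINK_KINDS, ConfidenceConfig,
                      extract_links, score_links)
from .matcher import MODES, SCOPES, detect_terms, hits_by_term
from .network import (AOPNetwork, build_network, filter_network,
                      to_edge_table_tsv, to_network_json, to_node_table_tsv)
from .stopwords import DEFAULT_STOPWORDS, STOPWORDS_VERSION, load_stopwords
from .textnorm import expand_dictionary, normalize_document

logger = logging.getLogger("aopminer")

OUTPUT_FILES = ("network.json", "edges.tsv", "nodes.tsv",
                "annotations.tsv", "run_metadata.json")


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of one mining run."""

    corpus: str
    events: str
    out_dir: str
    stressors: Optional[str] = None
    corpus_format: str = "tsv"
    kinds: tuple[str, ...] = LINK_KINDS
    match_mode: str = "partial"
    scope: str = "abstract"
    alpha: float = 0.05
    count_moderate: int = 5
    count_high: int = 20
    p_adjust: str = "none"
    annotate_dir: Optional[str] = None
    annotation_rule: str = "exact-normalized"
    min_count: int = 1
    min_confidence: Optional[str] = None
    stopword_file: Optional[str] = None
    stemmer: str = "porter"

    def validate(self) -> None:
        if not self.kinds:
            raise ConfigError("kinds must be nonempty")
        for k in self.kinds:
            if k not in LINK_KINDS:
                raise ConfigError(f"unknown link kind {k!r}")
        if self.corpus_format not in ("tsv", "medline"):
            raise ConfigError(f"unknown corpus format {self.corpus_format!r}")
        if self.match_mode not in MODES:
            raise ConfigError(f"unknown match mode {self.match_mode!r}")
        if self.scope not in SCOPES:
            raise ConfigError(f"unknown scope {self.scope!r}")
        if self.p_adjust not in ("none", "BH"):
            raise ConfigError(f"unknown p-adjust method {self.p_adjust!r}")
        if self.annotation_rule not in ANNOTATION_RULES:
            raise ConfigError(f"unknown annotation rule {self.annotation_rule!r}")
        if self.min_confidence is not None and self.min_confidence not in CONFIDENCE_RANK:
            raise ConfigError(f"unknown confidence level {self.min_confidence!r}")
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if "stressor-event" in self.kinds and self.stressors is None:
            raise ConfigError("stressor-event search requires a stressor dictionary")
        paths = [self.corpus, self.events, self.stressors,
                 self.annotate_dir, self.stopword_file]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")
        # delegate range checks on alpha / count thresholds
        ConfidenceConfig(alpha=self.alpha, count_moderate=self.count_moderate,
                         count_high=self.count_high)


def run(cfg: RunConfig) -> AOPNetwork:
    """Execute the full pipeline and write the five output files.

    Output files are only written once every stage has succeeded, so a
    failing run leaves no partial outputs behind.
    """
    t0 = time.monotonic()
    cfg.validate()
    stopwords = (DEFAULT_STOPWORDS if cfg.stopword_file is None
                 else load_stopwords(cfg.stopword_file))

    reader = read_corpus_tsv if cfg.corpus_format == "tsv" else read_medline
    corpus = reader(cfg.corpus)
    logger.info("corpus: %d records", len(corpus))

    events = read_dictionary(cfg.events)
    stressors = read_dictionary(cfg.stressors) if cfg.stressors else []
    event_ids = {t.term_id for t in events}
    stressor_ids = {t.term_id for t in stressors}
    logger.info("dictionaries: %d stressors, %d events",
                len(stressors), len(events))

    docs = [normalize_document(r, stopwords, cfg.stemmer) for r in corpus]
    expanded = expand_dictionary([*stressors, *events], stopwords, cfg.stemmer)
    hits = detect_terms(docs, expanded, mode=cfg.match_mode, scope=cfg.scope)
    logger.info("detection: %d (term, record) hits", len(hits))

    links = extract_links(hits, stressor_ids, event_ids, kinds=cfg.kinds)
    scored = score_links(
        links, hits_by_term(hits), len(corpus),
        cfg=ConfidenceConfig(alpha=cfg.alpha, count_moderate=cfg.count_moderate,
                             count_high=cfg.count_high),
        p_adjust=cfg.p_adjust,
    )
    logger.info("linking: %d links", len(scored))

    detected_event_ids = {h.term_id for h in hits} & event_ids
    detected_events = [t for t in events if t.term_id in detected_event_ids]
    if cfg.annotate_dir and detected_events:
        db = read_annotation_dir(cfg.annotate_dir)
        annotation_sets = annotate_events(
            detected_events, db, stopwords, cfg.stemmer, cfg.annotation_rule)
        logger.info("annotation: %d annotations on %d events",
                    sum(s.n_annotations for s in annotation_sets),
                    len(annotation_sets))
    else:
        annotation_sets = []

    metadata = {
        "config": asdict(cfg),
        "package_version": __version__,
        "stemmer": cfg.stemmer,
        "stopwords_version": (STOPWORDS_VERSION if cfg.stopword_file is None
                              else str(cfg.stopword_file)),
        "corpus_size": len(corpus),
        "n_hits": len(hits),
        "n_links": len(scored),
    }
    net = build_network(scored, [*stressors, *events], annotation_sets,
                        metadata=metadata)
    net = filter_network(net, min_count=cfg.min_count,
                         min_confidence=cfg.min_confidence)
    logger.info("network: %d nodes, %d edges after filtering",
                net.n_nodes, net.n_edges)

    ann_lines = ["\t".join(["term_id", "source_db", "annotation_id",
                            "annotation_label", "annotation_class"])]
    for s in sorted(annotation_sets, key=lambda s: s.term_id):
        for rec in sorted(s.annotations,
                          key=lambda r: (r.source_db, r.annotation_id)):
            ann_lines.append("\t".join([s.term_id, rec.source_db, rec.annotation_id,
                                        rec.annotation_label, rec.annotation_class]))

    outputs = {
        "network.json": to_network_json(net),
        "edges.tsv": to_edge_table_tsv(net),
        "nodes.tsv": to_node_table_tsv(net),
        "annotations.tsv": "\n".join(ann_lines) + "\n",
        "run_metadata.json": json.dumps(net.metadata, indent=2, sort_keys=True,
                                        ensure_ascii=False) + "\n",
    }
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, text in outputs.items():
        (out_dir / name).write_text(text, encoding="utf-8")
    logger.info("run finished in %.2f s", time.monotonic() - t0)
    return net
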