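"""Construction, filtering and serialization of the AOP network.

The network is an undirected graph: nodes are stressors and biological
events that take part in at least one extracted link; edges carry the
co-occurrence weight (number of supporting abstracts), the Fisher
p-value and the confidence category.  Serializations are deterministic:
nodes and edges are emitted in sorted order with sorted JSON keys, so
identical networks produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .annotate import EventAnnotationSet
from .errors import ValidationError
from .linking import CONFIDENCE_RANK, Link
from .records import TermEntry

#: Display color per confidence category: (symbolic token, hex default).
#: Presentation metadata only — the category string is normative.
CONFIDENCE_COLORS: dict[str, tuple[str, str]] = {
    "Low": ("orange", "#E69F00"),
    "Moderate": ("yellow", "#F0E442"),
    "High": ("light-green", "#90EE90"),
    "Very High": ("dark-green", "#006400"),
}

EDGE_TABLE_COLUMNS = [
    "source", "target", "kind", "weight", "confidence", "p_value", "record_ids",
]
NODE_TABLE_COLUMNS = ["id", "label", "node_type", "category", "annotations"]


@dataclass
class AOPNetwork:
    """Undirected AOP network: a networkx graph plus run metadata."""

    graph: nx.Graph = dc_field(default_factory=nx.Graph)
    metadata: dict = dc_field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AOPNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and {frozenset(e): d for *e, d in self.graph.edges(data=True)}
            == {frozenset(e): d for *e, d in other.graph.edges(data=True)}
            and self.metadata == other.metadata
        )


def _annotation_dicts(ann: Optional[EventAnnotationSet]) -> list[dict]:
    if ann is None:
        return []
    return [
        {"source_db": r.source_db, "annotation_id": r.annotation_id,
         "annotation_label": r.annotation_label,
         "annotation_class": r.annotation_class}
        for r in sorted(ann.annotations,
                        key=lambda r: (r.source_db, r.annotation_id))
    ]


def build_network(
    links: Iterable[Link],
    dictionary: Iterable[TermEntry],
    annotations: Iterable[EventAnnotationSet] = (),
    metadata: Optional[Mapping] = None,
) -> AOPNetwork:
    """Assemble the network from scored links.

    Nodes are exactly the terms incident to at least one link; each
    carries its annotation set.  Raises on unscored links or on links
    referencing a term absent from the dictionary.
    """
    terms = {t.term_id: t for t in dictionary}
    ann_by_term = {a.term_id: a for a in annotations}
    g = nx.Graph()
    for link in links:
        for tid in (link.source_id, link.target_id):
            if tid not in terms:
                raise ValidationError(f"link references unknown term {tid!r}")
        if link.p_value is None or link.confidence is None:
            raise ValidationError(
                f"link {link.source_id!r}-{link.target_id!r} is not scored"
            )
        for tid in (link.source_id, link.target_id):
            if tid not in g:
                t = terms[tid]
                g.add_node(
                    tid,
                    label=t.label,
                    node_type="stressor" if t.category == "stressor" else "event",
                    category=t.category,
                    annotations=_annotation_dicts(ann_by_term.get(tid)),
                )
        if g.has_edge(link.source_id, link.target_id):
            raise ValidationError(
                f"duplicate edge {link.source_id!r}-{link.target_id!r}"
            )
        g.add_edge(
            link.source_id,
            link.target_id,
            kind=link.kind,
            weight=link.count,
            confidence=link.confidence,
            p_value=link.p_value,
            adjusted_p=link.adjusted_p,
            record_ids=sorted(link.record_ids),
        )
    return AOPNetwork(graph=g, metadata=dict(metadata or {}))


def filter_network(
    net: AOPNetwork,
    min_count: int = 1,
    min_confidence: Optional[str] = None,
) -> AOPNetwork:
    """Keep edges with weight >= min_count and confidence >= the floor,
    then drop isolated nodes.  The applied filter is appended to the
    metadata under ``filters``."""
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    if min_confidence is not None and min_confidence not in CONFIDENCE_RANK:
        raise ValidationError(f"unknown confidence level {min_confidence!r}")
    floor = -1 if min_confidence is None else CONFIDENCE_RANK[min_confidence]
    g = net.graph.copy()
    drop = [
        (u, v)
        for u, v, d in g.edges(data=True)
        if d["weight"] < min_count or CONFIDENCE_RANK[d["confidence"]] < floor
    ]
    g.remove_edges_from(drop)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    metadata = dict(net.metadata)
    metadata["filters"] = list(metadata.get("filters", [])) + [
        {"min_count": min_count, "min_confidence": min_confidence}
    ]
    return AOPNetwork(graph=g, metadata=metadata)


# ------------------------------------------------------------ JSON

def _edge_sort_key(item):
    u, v, _ = item
    a, b = sorted((u, v))
    return (a, b)


def to_network_json(
    net: AOPNetwork,
    colors: Mapping[str, tuple[str, str]] = CONFIDENCE_COLORS,
) -> str:
    """Serialize to the graph-viewer ``elements``/``data`` JSON shape."""
    nodes = [
        {"data": {"id": n, "label": d["label"], "node_type": d["node_type"],
                  "category": d["category"], "annotations": d["annotations"]}}
        for n, d in sorted(net.graph.nodes(data=True))
    ]
    edges = []
    for u, v, d in sorted(net.graph.edges(data=True), key=_edge_sort_key):
        a, b = sorted((u, v))
        token, hex_code = colors[d["confidence"]]
        edges.append(
            {"data": {"id": f"{a}--{b}", "source": a, "target": b,
                      "kind": d["kind"], "weight": d["weight"],
                      "confidence": d["confidence"],
                      "confidence_color": token,
                      "confidence_color_hex": hex_code,
                      "p_value": d["p_value"],
                      "adjusted_p": d["adjusted_p"],
                      "record_ids": list(d["record_ids"])}}
        )
    payload = {"elements": {"nodes": nodes, "edges": edges},
               "metadata": net.metadata}
    return json.dumps(payload, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def from_network_json(text: str) -> AOPNetwork:
    """Parse :func:`to_network_json` output back into an equal network."""
    payload = json.loads(text)
    g = nx.Graph()
    for node in payload["elements"]["nodes"]:
        d = node["data"]
        g.add_node(d["id"], label=d["label"], node_type=d["node_type"],
                   category=d["category"], annotations=d["annotations"])
    for edge in payload["elements"]["edges"]:
        d = edge["data"]
        g.add_edge(d["source"], d["target"], kind=d["kind"], weight=d["weight"],
                   confidence=d["confidence"], p_value=d["p_value"],
                   adjusted_p=d["adjusted_p"], record_ids=list(d["record_ids"]))
    return AOPNetwork(graph=g, metadata=payload["metadata"])


# ------------------------------------------------------------- tables

def _format_p(p: Optional[float]) -> str:
    return "" if p is None else repr(p)


def to_edge_table_tsv(net: AOPNetwork) -> str:
    """Cytoscape-readable edge table, sorted by (source, target)."""
    lines = ["\t".join(EDGE_TABLE_COLUMNS)]
    for u, v, d in sorted(net.graph.edges(data=True), key=_edge_sort_key):
        a, b = sorted((u, v))
        lines.append("\t".join([
            a, b, d["kind"], str(d["weight"]), d["confidence"],
            _format_p(d["p_value"]), "|".join(d["record_ids"]),
        ]))
    return "\n".join(lines) + "\n"


def to_node_table_tsv(net: AOPNetwork) -> str:
    """Companion node table; annotations joined as source:annotation_id."""
    lines = ["\t".join(NODE_TABLE_COLUMNS)]
    for n, d in sorted(net.graph.nodes(data=True)):
        ann = "|".join(
            f"{a['source_db']}:{a['annotation_id']}" for a in d["annotations"]
        )
        lines.append("\t".join([n, d["label"], d["node_type"], d["category"], ann]))
    return "\n".join(lines) + "\n"


def read_edge_table_tsv(text: str) -> list[dict]:
    """Parse an edge table back into edge dicts (fields typed)."""
    lines = [l for l in text.splitlines() if l]
    header = lines[0].split("\t")
    if header != EDGE_TABLE_COLUMNS:
        raise ValidationError(f"unexpected edge-table header: {header}")
    out = []
    for line in lines[1:]:
        vals = dict(zip(header, line.split("\t")))
        vals["weight"] = int(vals["weight"])
        vals["p_value"] = float(vals["p_value"]) if vals["p_value"] else None
        vals["record_ids"] = vals["record_ids"].split("|") if vals["record_ids"] else []
        out.append(vals)
    return out
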