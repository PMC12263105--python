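"""Network assembly, filtering and deterministic serialization."""

import json

import numpy as np
import pytest

from aopminer import (TermEntry, ValidationError, build_network,
                      filter_network, from_network_json, read_edge_table_tsv,
                      to_edge_table_tsv, to_network_json, to_node_table_tsv)
from aopminer.linking import CONFIDENCE_RANK, Link
from conftest import make_random_network

TERMS = [TermEntry("S1", "radon", "stressor"),
         TermEntry("E1", "oxidative stress", "KE"),
         TermEntry("E2", "apoptosis", "KE"),
         TermEntry("E3", "lung cancer", "AO"),
         TermEntry("E4", "unlinked event", "KE")]


def scored(a, b, kind, records, confidence="High", p=0.01):
    return Link(a, b, kind, frozenset(records), p_value=p, confidence=confidence)


LINKS = [
    scored("S1", "E1", "stressor-event", {"r1", "r2", "r3"}, "Very High", 0.001),
    scored("E1", "E2", "event-event", {"r2"}, "Moderate", 0.02),
    scored("E2", "E3", "event-event", {"r4", "r5"}, "Low", 0.6),
]


def test_nodes_are_exactly_incident_terms():
    net = build_network(LINKS, TERMS, metadata={"run": 1})
    assert net.n_nodes == 4 and net.n_edges == 3
    assert "E4" not in net.graph  # zero-link term absent
    assert net.graph.nodes["S1"]["node_type"] == "stressor"
    assert net.metadata == {"run": 1}


def test_unknown_term_rejected():
    with pytest.raises(ValidationError):
        build_network([scored("S1", "EX", "stressor-event", {"r"})], TERMS)


def test_unscored_link_rejected():
    with pytest.raises(ValidationError):
        build_network([Link("S1", "E1", "stressor-event", frozenset({"r"}))],
                      TERMS)


class TestFilter:
    def test_identity_filter(self):
        net = build_network(LINKS, TERMS)
        same = filter_network(net, min_count=1, min_confidence=None)
        assert same.n_nodes == net.n_nodes and same.n_edges == net.n_edges
        assert same.metadata["filters"] == [
            {"min_count": 1, "min_confidence": None}]

    def test_confidence_floor_and_isolation(self):
        net = build_network(LINKS, TERMS)
        kept = filter_network(net, min_confidence="High")
        assert set(kept.graph.edges) == {("S1", "E1")}
        assert set(kept.graph) == {"S1", "E1"}  # isolated E2/E3 dropped

    def test_count_threshold_composition(self):
        net = build_network(LINKS, TERMS)
        twice = filter_network(filter_network(net, min_count=2), min_count=3)
        once = filter_network(net, min_count=3)
        assert dict(twice.graph.edges) == dict(once.graph.edges)

    def test_monotone_under_threshold_increase(self):
        net = build_network(LINKS, TERMS)
        for level in CONFIDENCE_RANK:
            sub = filter_network(net, min_confidence=level)
            assert set(sub.graph) <= set(net.graph)
            assert set(sub.graph.edges) <= set(net.graph.edges)


class TestSerialization:
    def test_json_shape_and_colors(self):
        net = build_network(LINKS, TERMS, metadata={"m": 1})
        payload = json.loads(to_network_json(net))
        assert set(payload) == {"elements", "metadata"}
        edges = {e["data"]["id"]: e["data"] for e in payload["elements"]["edges"]}
        very_high = edges["E1--S1"]
        assert very_high["confidence"] == "Very High"
        assert very_high["confidence_color"] == "dark-green"
        low = edges["E2--E3"]
        assert low["confidence_color"] == "orange"

    def test_empty_network_serializes(self):
        net = build_network([], TERMS)
        payload = json.loads(to_network_json(net))
        assert payload["elements"] == {"nodes": [], "edges": []}

    def test_json_round_trip(self):
        net = build_network(LINKS, TERMS, metadata={"m": [1, 2]})
        assert from_network_json(to_network_json(net)) == net

    def test_edge_table_row_count_and_sorted(self):
        net = build_network(LINKS, TERMS)
        lines = to_edge_table_tsv(net).strip().split("\n")
        assert len(lines) == 4
        sources = [l.split("\t")[0] for l in lines[1:]]
        assert sources == sorted(sources)

    def test_edge_table_round_trip(self):
        net = build_network(LINKS, TERMS)
        rows = read_edge_table_tsv(to_edge_table_tsv(net))
        got = {(r["source"], r["target"]): (r["weight"], r["confidence"],
                                            r["p_value"], set(r["record_ids"]))
               for r in rows}
        for u, v, d in net.graph.edges(data=True):
            a, b = sorted((u, v))
            assert got[(a, b)] == (d["weight"], d["confidence"], d["p_value"],
                                   set(d["record_ids"]))

    def test_node_table_contains_all_nodes(self):
        net = build_network(LINKS, TERMS)
        lines = to_node_table_tsv(net).strip().split("\n")
        assert {l.split("\t")[0] for l in lines[1:]} == set(net.graph)

    def test_byte_stable_across_runs(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        n1, n2 = make_random_network(rng1), make_random_network(rng2)
        assert to_network_json(n1) == to_network_json(n2)
        assert to_edge_table_tsv(n1) == to_edge_table_tsv(n2)
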