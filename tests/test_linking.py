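"""Link extraction, Fisher scoring, BH adjustment and confidence."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import hypergeom_right_tail_exact
from aopminer import (ConfidenceConfig, ContingencyTable, ValidationError,
                      adjust_pvalues, assign_confidence, build_contingency,
                      extract_links, fisher_right_tail, score_links)
from aopminer.errors import ConfigError
from aopminer.linking import CONFIDENCE_RANK, Link
from aopminer.matcher import DetectionHit


def hits(*pairs):
    return [DetectionHit(term_id=t, record_id=r, best_fraction=1.0,
                         mode="partial") for t, r in pairs]


class TestExtractLinks:
    def test_intersection_support(self):
        links = extract_links(
            hits(("S", "d1"), ("S", "d2"), ("E", "d2"), ("E", "d3")),
            stressor_ids={"S"}, event_ids={"E"},
        )
        assert len(links) == 1
        assert links[0].record_ids == {"d2"} and links[0].count == 1
        assert links[0].kind == "stressor-event"

    def test_disjoint_records_no_link(self):
        links = extract_links(hits(("E1", "d1"), ("E2", "d2")),
                              stressor_ids=set(), event_ids={"E1", "E2"})
        assert links == []

    def test_kind_partition(self):
        h = hits(("S", "d1"), ("E1", "d1"), ("E2", "d1"))
        only_se = extract_links(h, {"S"}, {"E1", "E2"}, kinds=("stressor-event",))
        assert {l.kind for l in only_se} == {"stressor-event"}
        only_ee = extract_links(h, {"S"}, {"E1", "E2"}, kinds=("event-event",))
        assert [(l.source_id, l.target_id) for l in only_ee] == [("E1", "E2")]

    def test_undirected_and_order_independent(self):
        h = hits(("E1", "d1"), ("E2", "d1"))
        a = extract_links(h, set(), {"E1", "E2"}, kinds=("event-event",))
        b = extract_links(list(reversed(h)), set(), {"E2", "E1"},
                          kinds=("event-event",))
        assert a == b

    def test_empty_kinds_rejected(self):
        with pytest.raises(ValidationError):
            extract_links(hits(("E1", "d1")), set(), {"E1"}, kinds=())


class TestContingency:
    def test_set_arithmetic(self):
        link = Link("A", "B", "event-event", frozenset({"2", "3"}))
        table = build_contingency(
            link, {"A": {"1", "2", "3"}, "B": {"2", "3", "4"}}, 10)
        assert (table.n_both, table.n_a_only, table.n_b_only,
                table.n_neither) == (2, 1, 1, 6)

    def test_identical_sets(self):
        link = Link("A", "B", "event-event", frozenset({"1", "2"}))
        table = build_contingency(link, {"A": {"1", "2"}, "B": {"1", "2"}}, 2)
        assert (table.n_both, table.n_a_only, table.n_b_only,
                table.n_neither) == (2, 0, 0, 0)

    def test_corpus_smaller_than_union_rejected(self):
        link = Link("A", "B", "event-event", frozenset({"1"}))
        with pytest.raises(ValidationError):
            build_contingency(link, {"A": {"1", "2"}, "B": {"1", "3"}}, 2)


class TestFisher:
    def test_zero_overlap_is_exactly_one(self):
        assert fisher_right_tail(ContingencyTable(0, 5, 7, 10)) == 1.0

    def test_balanced_table_matches_enumeration(self):
        # N=4, margins 2/2: P(X >= 1) = 5/6 by enumerating all C(4,2) draws
        p = fisher_right_tail(ContingencyTable(1, 1, 1, 1))
        assert hypergeom_right_tail_exact(1, 1, 1, 1) == Fraction(5, 6)
        assert p == pytest.approx(5 / 6, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_exact_enumeration(self, a, b, c, d):
        got = fisher_right_tail(ContingencyTable(a, b, c, d))
        want = float(hypergeom_right_tail_exact(a, b, c, d)) if a + b + c + d else 1.0
        assert got == pytest.approx(want, abs=1e-10)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 0, 0, 0)


class TestAdjust:
    def _links(self, ps):
        return [
            Link(f"E{i}", f"F{i}", "event-event", frozenset({"r"}), p_value=p)
            for i, p in enumerate(ps)
        ]

    def test_single_link_unchanged(self):
        (link,) = adjust_pvalues(self._links([0.013]), "BH")
        assert link.adjusted_p == pytest.approx(0.013)

    def test_step_up_hand_example(self):
        adjusted = adjust_pvalues(self._links([0.01, 0.02, 0.03]), "BH")
        assert [l.adjusted_p for l in adjusted] == pytest.approx([0.03] * 3)

    def test_none_leaves_absent(self):
        assert all(l.adjusted_p is None
                   for l in adjust_pvalues(self._links([0.2, 0.5]), "none"))

    def test_adjustment_is_per_kind(self):
        links = self._links([0.01, 0.04]) + [
            Link("S", "E0", "stressor-event", frozenset({"r"}), p_value=0.04)
        ]
        adjusted = {(l.source_id, l.kind): l.adjusted_p
                    for l in adjust_pvalues(links, "BH")}
        # the stressor-event population has m=1: its p is unchanged
        assert adjusted[("S", "stressor-event")] == pytest.approx(0.04)
        assert adjusted[("E1", "event-event")] == pytest.approx(0.04 * 2 / 2)


class TestConfidence:
    @pytest.mark.parametrize("count,p,expected", [
        (25, 0.001, "Very High"),
        (5, 0.01, "High"),
        (2, 0.01, "Moderate"),
        (25, 0.5, "Moderate"),
        (2, 0.5, "Low"),
        (19, 0.04, "High"),
    ])
    def test_default_bins(self, count, p, expected):
        assert assign_confidence(count, p) == expected

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ConfidenceConfig(alpha=1.5)
        with pytest.raises(ConfigError):
            ConfidenceConfig(count_moderate=20, count_high=5)
        with pytest.raises(ConfigError):
            ConfidenceConfig(count_moderate=0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 60), st.floats(0.0, 1.0), st.integers(1, 10))
    def test_monotone_in_count_and_p(self, count, p, bump):
        up_count = CONFIDENCE_RANK[assign_confidence(count + bump, p)]
        base = CONFIDENCE_RANK[assign_confidence(count, p)]
        down_p = CONFIDENCE_RANK[assign_confidence(count, p / 2)]
        assert up_count >= base
        assert down_p >= base


def test_score_links_uses_adjusted_p_when_requested():
    """With BH the confidence rule reads the adjusted p-value."""
    by_term = {"E0": set("abc"), "F0": set("abc"),
               "E1": {"a"}, "F1": {"a", "b", "c"}}
    links = [Link("E0", "F0", "event-event", frozenset("abc")),
             Link("E1", "F1", "event-event", frozenset("a"))]
    raw = score_links(links, by_term, 30, p_adjust="none")
    adj = score_links(links, by_term, 30, p_adjust="BH")
    assert all(l.adjusted_p is None for l in raw)
    assert all(l.adjusted_p is not None and l.adjusted_p >= l.p_value
               for l in adj)
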