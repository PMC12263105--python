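"""Co-occurrence link extraction and Fisher-based confidence scoring.

A link between two terms is supported by the set of abstracts in which
both were detected.  Its significance is the one-sided (enrichment)
Fisher exact test on the 2x2 table of abstract counts

    both | A only
    B only | neither

against the closed-world background of the analyzed corpus.  Count and
significance together map to a four-level confidence category used for
network coloring and filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .matcher import DetectionHit
from .matcher import hits_by_term as _group_hits

LinkKind = Literal["stressor-event", "event-event"]
LINK_KINDS = ("stressor-event", "event-event")

#: Confidence categories in increasing order of support.
CONFIDENCE_LEVELS = ("Low", "Moderate", "High", "Very High")
CONFIDENCE_RANK = {c: i for i, c in enumerate(CONFIDENCE_LEVELS)}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 abstract counts underlying the Fisher exact test."""

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        for name in ("n_both", "n_a_only", "n_b_only", "n_neither"):
            if getattr(self, name) < 0:
                raise ValidationError(f"contingency cell {name} is negative")

    @property
    def total(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither


@dataclass(frozen=True)
class Link:
    """An undirected association between two terms, optionally scored."""

    source_id: str
    target_id: str
    kind: LinkKind
    record_ids: frozenset[str]
    p_value: Optional[float] = None
    adjusted_p: Optional[float] = None
    confidence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValidationError(f"self-link on term {self.source_id!r}")
        if not self.record_ids:
            raise ValidationError(
                f"link {self.source_id!r}-{self.target_id!r} has no supporting records"
            )
        object.__setattr__(self, "record_ids", frozenset(self.record_ids))

    @property
    def count(self) -> int:
        return len(self.record_ids)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.source_id, self.target_id})


@dataclass(frozen=True)
class ConfidenceConfig:
    """Thresholds of the count x significance confidence mapping.

    alpha: significance level on the Fisher p-value.
    count_moderate / count_high: co-occurrence counts opening the High
    and Very High categories for significant links.
    """

    alpha: float = 0.05
    count_moderate: int = 5
    count_high: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.count_moderate < 1 or self.count_high < 1:
            raise ConfigError("count thresholds must be positive")
        if self.count_high <= self.count_moderate:
            raise ConfigError(
                f"count_high ({self.count_high}) must exceed "
                f"count_moderate ({self.count_moderate})"
            )


def extract_links(
    hits: Iterable[DetectionHit],
    stressor_ids: set[str],
    event_ids: set[str],
    kinds: Iterable[LinkKind] = LINK_KINDS,
) -> list[Link]:
    """Aggregate detection hits into unscored co-occurrence links.

    For every unordered term pair of the requested kinds, the link's
    supporting records are the abstracts where both terms hit; pairs
    with no shared record are omitted.
    """
    kinds = tuple(kinds)
    if not kinds:
        raise ValidationError("kinds must be nonempty")
    for k in kinds:
        if k not in LINK_KINDS:
            raise ValidationError(f"unknown link kind {k!r}")
    if stressor_ids & event_ids:
        raise ValidationError(
            f"terms in both dictionaries: {sorted(stressor_ids & event_ids)}"
        )
    by_term = _group_hits(hits)
    links: list[Link] = []

    def _add(a: str, b: str, kind: LinkKind) -> None:
        shared = by_term.get(a, set()) & by_term.get(b, set())
        if shared:
            links.append(Link(source_id=a, target_id=b, kind=kind,
                              record_ids=frozenset(shared)))

    if "stressor-event" in kinds:
        for s in sorted(stressor_ids & by_term.keys()):
            for e in sorted(event_ids & by_term.keys()):
                _add(s, e, "stressor-event")
    if "event-event" in kinds:
        hit_events = sorted(event_ids & by_term.keys())
        for i, a in enumerate(hit_events):
            for b in hit_events[i + 1:]:
                _add(a, b, "event-event")
    links.sort(key=lambda l: (l.kind, l.source_id, l.target_id))
    return links


def build_contingency(
    link: Link, hits_by_term: Mapping[str, set[str]], n_corpus: int
) -> ContingencyTable:
    """2x2 abstract-count table for one link against corpus size N."""
    a = set(hits_by_term.get(link.source_id, set()))
    b = set(hits_by_term.get(link.target_id, set()))
    union = a | b
    if n_corpus < len(union):
        raise ValidationError(
            f"corpus size {n_corpus} smaller than |A union B| = {len(union)}"
        )
    return ContingencyTable(
        n_both=len(a & b),
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        n_neither=n_corpus - len(union),
    )


def fisher_right_tail(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p-value.

    P(X >= n_both) for X hypergeometric with population N, success count
    n_both + n_a_only and draw count n_both + n_b_only.  A table with
    n_both = 0 returns exactly 1.0.
    """
    if table.n_both == 0:
        return 1.0
    n_successes = table.n_both + table.n_a_only
    n_draws = table.n_both + table.n_b_only
    p = float(hypergeom.sf(table.n_both - 1, table.total, n_successes, n_draws))
    return min(max(p, 0.0), 1.0)


def adjust_pvalues(links: list[Link], method: Literal["none", "BH"]) -> list[Link]:
    """Benjamini-Hochberg step-up adjustment, separately per link kind.

    ``method="none"`` returns the links with ``adjusted_p`` absent.
    """
    if method not in ("none", "BH"):
        raise ConfigError(f"unknown p-adjust method {method!r}")
    if method == "none":
        return [replace(l, adjusted_p=None) for l in links]
    if any(l.p_value is None for l in links):
        raise ValidationError("adjust_pvalues requires scored links")
    adjusted: dict[tuple[str, str, str], float] = {}
    for kind in LINK_KINDS:
        group = [l for l in links if l.kind == kind]
        # stable order by (p, pair) so ties adjust deterministically
        group.sort(key=lambda l: (l.p_value, l.source_id, l.target_id))
        if not group:
            continue
        adj = multipletests([l.p_value for l in group], method="fdr_bh")[1]
        for l, q in zip(group, adj):
            adjusted[(l.kind, l.source_id, l.target_id)] = float(q)
    return [
        replace(l, adjusted_p=adjusted[(l.kind, l.source_id, l.target_id)])
        for l in links
    ]


def assign_confidence(
    count: int, p: float, cfg: ConfidenceConfig = ConfidenceConfig()
) -> str:
    """Map (co-occurrence count, p-value) to a confidence category.

    Significant links (p < alpha) rank Moderate / High / Very High as
    the count crosses the configured thresholds; non-significant links
    rank Low unless very frequently co-mentioned (count >= count_high),
    which earns Moderate.
    """
    if count < 1:
        raise ValidationError(f"count must be >= 1, got {count}")
    significant = p < cfg.alpha
    if significant:
        if count >= cfg.count_high:
            return "Very High"
        if count >= cfg.count_moderate:
            return "High"
        return "Moderate"
    return "Moderate" if count >= cfg.count_high else "Low"


def score_links(
    links: list[Link],
    hits_by_term: Mapping[str, set[str]],
    n_corpus: int,
    cfg: ConfidenceConfig = ConfidenceConfig(),
    p_adjust: Literal["none", "BH"] = "none",
) -> list[Link]:
    """Attach Fisher p-values, optional BH adjustment and confidence."""
    scored = [
        replace(l, p_value=fisher_right_tail(build_contingency(l, hits_by_term, n_corpus)))
        for l in links
    ]
    scored = adjust_pvalues(scored, p_adjust)
    out = []
    for l in scored:
        effective_p = l.adjusted_p if p_adjust == "BH" else l.p_value
        out.append(replace(l, confidence=assign_confidence(l.count, effective_p, cfg)))
    return out
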