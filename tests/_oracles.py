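"""Independent brute-force oracles used by the test suite.

These are deliberately naive (exact integer enumeration, linear scans)
and share no code with the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_right_tail_exact(n_both: int, n_a_only: int, n_b_only: int,
                               n_neither: int) -> Fraction:
    """P(X >= n_both) by exact enumeration of the hypergeometric mass.

    Population N, K = n_both + n_a_only marked items, n = n_both +
    n_b_only draws; summed as exact rationals over every outcome.
    """
    N = n_both + n_a_only + n_b_only + n_neither
    K = n_both + n_a_only
    n = n_both + n_b_only
    total = comb(N, n)
    numer = sum(comb(K, x) * comb(N - K, n - x)
                for x in range(n_both, min(K, n) + 1))
    return Fraction(numer, total)


def filter_edges_bruteforce(edges, min_count, min_confidence_rank, rank):
    """Linear scan over (u, v, data) edge triples."""
    kept = [
        (u, v, d) for u, v, d in edges
        if d["weight"] >= min_count and rank[d["confidence"]] >= min_confidence_rank
    ]
    incident = {n for u, v, _ in kept for n in (u, v)}
    return kept, incident
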