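"""Shared fixtures: tiny dictionaries, planted corpora, random networks."""

from __future__ import annotations

import numpy as np
import pytest

from aopminer import TermEntry, build_network
from aopminer.linking import CONFIDENCE_LEVELS, Link
from aopminer.synth import generate_corpus, planted_study_spec, study_terms


@pytest.fixture(scope="session")
def terms():
    return study_terms()


@pytest.fixture(scope="session")
def term_ids(terms):
    stressors = {t.term_id for t in terms if t.category == "stressor"}
    events = {t.term_id for t in terms if t.category != "stressor"}
    return stressors, events


@pytest.fixture(scope="session")
def planted_corpus():
    """The built-in 200-abstract planted study corpus (fixed seed)."""
    spec = planted_study_spec(seed=1234)
    records, truth = generate_corpus(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def planted_corpus_partial():
    """Same design with 30% of pair plants degraded to ceil(3k/4) stems."""
    spec = planted_study_spec(seed=1234, partial_fraction=0.3)
    records, truth = generate_corpus(spec)
    return spec, records, truth


def make_random_network(rng: np.random.Generator):
    """A small scored network with random weights and confidences."""
    n_terms = int(rng.integers(3, 9))
    entries = [TermEntry(f"T{i}", f"toyterm{i}", "stressor" if i == 0 else "KE")
               for i in range(n_terms)]
    links = []
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < 0.5:
                continue
            weight = int(rng.integers(1, 31))
            records = frozenset(f"r{i}_{j}_{k}" for k in range(weight))
            links.append(
                Link(
                    source_id=f"T{i}",
                    target_id=f"T{j}",
                    kind="stressor-event" if i == 0 else "event-event",
                    record_ids=records,
                    p_value=float(rng.random()),
                    adjusted_p=float(rng.random()) if rng.random() < 0.5 else None,
                    confidence=str(rng.choice(CONFIDENCE_LEVELS)),
                )
            )
    metadata = {"seed": int(rng.integers(0, 10**6)), "filters": []}
    return build_network(links, entries, metadata=metadata)
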