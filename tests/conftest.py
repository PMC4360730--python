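from __future__ import annotations

import pytest

from ontoslim import build_search_index, fixtures
from ontoslim.slims import TermIndexLookup


@pytest.fixture(scope="session")
def demo():
    """(graph, slim_sets, records) for the curated demo corpus."""
    return fixtures.demo_fixture()


@pytest.fixture(scope="session")
def demo_graph(demo):
    return demo[0]


@pytest.fixture(scope="session")
def demo_slim_sets(demo):
    return demo[1]


@pytest.fixture(scope="session")
def demo_records(demo):
    return demo[2]


@pytest.fixture(scope="session")
def demo_lookup(demo_graph, demo_slim_sets):
    return TermIndexLookup.from_graph(demo_graph, demo_slim_sets)


@pytest.fixture(scope="session")
def demo_search_index(demo_graph):
    return build_search_index(demo_graph)


def random_parts(seed: int, n_terms: int = 30, density: float = 0.12,
                 n_records: int = 0):
    """Raw (terms, rels, records) of a seeded random fixture, pre-merge, so
    oracles can consume the same edge list the graph was built from."""
    import random

    from ontoslim.facets import BIOSAMPLE_TYPES, AnnotationRecord
    from ontoslim.model import OntologyTerm, Relationship

    rng = random.Random(seed)
    ids = [f"RND:{i:04d}" for i in range(n_terms)]
    terms = [OntologyTerm(t, f"random term {i}") for i, t in enumerate(ids)]
    preds = ["derives_from", "is_a", "part_of"]
    rels = []
    for i in range(1, n_terms):
        for j in range(i):
            if rng.random() < density:
                rels.append(Relationship(ids[i], rng.choice(preds), ids[j]))
    records = [
        AnnotationRecord(
            f"REC{k:04d}",
            biosample_term=rng.choice(ids),
            biosample_type=rng.choice(BIOSAMPLE_TYPES),
        )
        for k in range(n_records)
    ]
    return terms, rels, records
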