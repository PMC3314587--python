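"""Shared fixtures: tiny hand-built networks and record factories."""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import pytest

from ppiloc.core import (
    AnnotationSet,
    EvidenceRecord,
    LocalizationVocabulary,
    Throughput,
    WeightedNetwork,
)


def make_records(
    pairs: Sequence[Tuple[str, str]],
    system: str = "Two-hybrid",
    throughput: Throughput = Throughput.LOW,
    pubs_per_pair: int = 2,
) -> List[EvidenceRecord]:
    """Evidence records with enough distinct publications to pass the filter."""
    records = []
    for i, (a, b) in enumerate(pairs):
        for j in range(pubs_per_pair):
            records.append(
                EvidenceRecord(a, b, system, throughput, f"pub{i}_{j}")
            )
    return records


def make_network(
    edges: Sequence[Tuple[str, str]],
    weights: Dict[Tuple[str, str], float] | None = None,
) -> WeightedNetwork:
    net = WeightedNetwork()
    for a, b in edges:
        w = 1.0
        if weights:
            w = weights.get((a, b), weights.get((b, a), 1.0))
        net.add_edge(a, b, weight=w, evidence=[("Two-hybrid/low", 2)])
    return net


@pytest.fixture
def abc_vocab() -> LocalizationVocabulary:
    return LocalizationVocabulary(("a", "b", "c", "d"))


@pytest.fixture
def star_net() -> WeightedNetwork:
    return make_network([("c", "x"), ("c", "y"), ("c", "z")])


@pytest.fixture
def path_net() -> WeightedNetwork:
    return make_network([("a", "b"), ("b", "c"), ("c", "d")])
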