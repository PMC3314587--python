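"""Network assembly from evidence records, and subgraph extraction."""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Set, Tuple

import networkx as nx

from .core import EvidenceRecord, Throughput, WeightedNetwork

__all__ = ["EmptyNetworkError", "build_network", "neighborhood_subgraph"]


class EmptyNetworkError(ValueError):
    """Raised when no records (or no surviving edges) are available."""


def _group_id(system: str, throughput: Throughput) -> str:
    return f"{system}/{throughput.value}"


def build_network(
    records: Iterable[EvidenceRecord],
    min_publications: int = 2,
    largest_component_only: bool = False,
) -> WeightedNetwork:
    """Build a deduplicated weighted PPI graph from evidence records.

    An edge is kept only if its unordered protein pair is supported by at
    least ``min_publications`` distinct publication identifiers (default 2,
    the conventional noise filter for literature-curated interactions).
    Duplicates and self-interactions never enter (self-interactions are
    already rejected at record construction).  With
    ``largest_component_only``, only the largest connected component is
    retained; ties between equal-size components are broken by the smallest
    lexicographic member identifier.  All edge weights start at 1; per-edge
    evidence lists ``(source_group_id, n_publications_in_group)`` are kept
    for later reliability weighting.
    """
    records = list(records)
    if not records:
        raise EmptyNetworkError("no evidence records supplied")
    if min_publications < 1:
        raise ValueError("min_publications must be >= 1")

    pubs_by_pair: Dict[Tuple[str, str], Set[str]] = defaultdict(set)
    pubs_by_pair_group: Dict[Tuple[str, str], Dict[str, Set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for rec in records:
        pair = rec.pair
        pubs_by_pair[pair].add(rec.publication)
        pubs_by_pair_group[pair][_group_id(rec.system, rec.throughput)].add(
            rec.publication
        )

    net = WeightedNetwork()
    for pair, pubs in pubs_by_pair.items():
        if len(pubs) < min_publications:
            continue
        evidence = sorted(
            (gid, len(gpubs)) for gid, gpubs in pubs_by_pair_group[pair].items()
        )
        net.add_edge(pair[0], pair[1], weight=1.0, evidence=evidence)

    if net.n_edges == 0:
        raise EmptyNetworkError(
            f"no interaction supported by >= {min_publications} publications"
        )

    if largest_component_only:
        components = list(nx.connected_components(net.graph))
        # largest component; equal sizes broken by smallest lexicographic member
        best_size = max(len(c) for c in components)
        best = min((c for c in components if len(c) == best_size), key=min)
        net = WeightedNetwork(net.graph.subgraph(best).copy())

    return net


def neighborhood_subgraph(
    net: WeightedNetwork, seeds: Iterable[str]
) -> WeightedNetwork:
    """Induced subgraph on the seeds and their immediate neighbors.

    Mirrors the case-study extraction: the proteins of interest together
    with every protein one interaction away, and all interactions among
    them, preserving weights and evidence.
    """
    seeds = set(seeds)
    for s in seeds:
        if s not in net.graph:
            raise KeyError(f"seed protein {s!r} is not in the network")
    keep: Set[str] = set(seeds)
    for s in seeds:
        keep.update(net.graph.neighbors(s))
    return WeightedNetwork(net.graph.subgraph(keep).copy())
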