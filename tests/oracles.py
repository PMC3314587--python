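"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive: plain dict/set arithmetic, exhaustive enumeration and a
literal step-by-step flow simulator, sharing no code with the package's
implementations.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

Adj = Mapping[str, Mapping[str, float]]  # node -> neighbor -> weight


def adjacency(net) -> Dict[str, Dict[str, float]]:
    adj: Dict[str, Dict[str, float]] = {u: {} for u in net.graph.nodes}
    for u, v, data in net.graph.edges(data=True):
        adj[u][v] = data["weight"]
        adj[v][u] = data["weight"]
    return adj


def majority_oracle(adj: Adj, labels: Mapping[str, FrozenSet[int]], K: int,
                    weighted: bool, max_labels: int = 3):
    """Neighbor label voting with the higher-score-then-lower-index cut."""
    out_scores, out_calls = {}, {}
    for u in adj:
        if labels.get(u):
            continue
        score = [0.0] * K
        for v, w in adj[u].items():
            for k in labels.get(v, frozenset()):
                score[k] += w if weighted else 1.0
        order = sorted(range(K), key=lambda k: (-score[k], k))
        calls = set()
        for k in order[:max_labels]:
            if score[k] > 0:
                calls.add(k)
        out_scores[u], out_calls[u] = score, calls
    return out_scores, out_calls


def merged_oracle(adj: Adj, labels: Mapping[str, FrozenSet[int]]):
    return {
        u: set().union(*(labels.get(v, frozenset()) for v in adj[u]))
        if adj[u] else set()
        for u in adj
        if not labels.get(u)
    }


def common_oracle(adj: Adj, labels: Mapping[str, FrozenSet[int]]):
    out = {}
    for u in adj:
        if labels.get(u):
            continue
        sets = [labels[v] for v in adj[u] if labels.get(v)]
        out[u] = set(frozenset.intersection(*sets)) if sets else set()
    return out


def chi2_oracle(adj: Adj, labels: Mapping[str, FrozenSet[int]], K: int,
                sigma: int):
    """Direct evaluation of the over-representation score via BFS."""
    labeled = [p for p in adj if labels.get(p)]
    freq = [0.0] * K
    for p in labeled:
        for k in labels[p]:
            freq[k] += 1
    if labeled:
        freq = [f / len(labeled) for f in freq]
    out = {}
    for u in adj:
        if labels.get(u):
            continue
        # BFS distances
        dist = {u: 0}
        frontier = [u]
        while frontier:
            nxt = []
            for x in frontier:
                for y in adj[x]:
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        if dist[y] < sigma:
                            nxt.append(y)
            frontier = nxt
        members = [v for v, d in dist.items() if 1 <= d <= sigma and labels.get(v)]
        score = [0.0] * K
        if members:
            for k in range(K):
                n_k = sum(1 for v in members if k in labels[v])
                e_k = len(members) * freq[k]
                if e_k > 0 and n_k > e_k:
                    score[k] = (n_k - e_k) ** 2 / e_k
        out[u] = score
    return out


def gmc_objective_oracle(adj: Adj, labels: Mapping[str, FrozenSet[int]],
                         k: int, targets: Sequence[str],
                         x: Mapping[str, int], include_negative: bool = True) -> float:
    """Literal evaluation of the per-label agreement objective."""
    tset = set(targets)
    val = 0.0
    for u in targets:
        for v, w in adj[u].items():
            if labels.get(v):
                if k in labels[v]:
                    val += w * x[u]
                elif include_negative:
                    val += w * (1 - x[u])
            elif v in tset and u < v:
                if x[u] == x[v]:
                    val += w
    return val


def gmc_best_objective(adj: Adj, labels: Mapping[str, FrozenSet[int]],
                       k: int, targets: Sequence[str],
                       include_negative: bool = True) -> float:
    best = -math.inf
    for bits in itertools.product((0, 1), repeat=len(targets)):
        x = dict(zip(targets, bits))
        best = max(best, gmc_objective_oracle(adj, labels, k, targets, x,
                                              include_negative))
    return best


def funflow_oracle(adj: Adj, labels: Mapping[str, FrozenSet[int]], K: int,
                   d: int) -> Dict[str, List[float]]:
    """Step-by-step simulation with explicit infinity bookkeeping."""
    INF = float("inf")
    deg = {u: sum(adj[u].values()) for u in adj}
    out = {u: [0.0] * K for u in adj}
    for k in range(K):
        R = {u: (INF if k in labels.get(u, frozenset()) else 0.0) for u in adj}
        for _ in range(d):
            g: Dict[Tuple[str, str], float] = {}
            for u in adj:
                for v, w in adj[u].items():
                    if R[u] <= R[v]:
                        g[(u, v)] = 0.0
                    elif R[u] == INF:
                        g[(u, v)] = w
                    else:
                        g[(u, v)] = min(w, (w / deg[u]) * R[u])
            newR = {}
            for u in adj:
                if k in labels.get(u, frozenset()):
                    newR[u] = INF
                else:
                    newR[u] = R[u] + sum(
                        g[(v, u)] - g[(u, v)] for v in adj[u]
                    )
                for v in adj[u]:
                    pass
            for u in adj:
                if not labels.get(u):
                    out[u][k] += sum(g[(v, u)] for v in adj[u])
            R = newR
    return out


def average_precision_oracle(pairs: Sequence[Tuple[float, bool]]) -> float:
    """AP by literal definition, stable ties."""
    ranked = sorted(enumerate(pairs), key=lambda t: (-t[1][0], t[0]))
    P = sum(1 for _, (s, y) in ranked if y)
    hits, acc = 0, 0.0
    for i, (idx, (s, y)) in enumerate(ranked, start=1):
        if y:
            hits += 1
            acc += hits / i
    return acc / P
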