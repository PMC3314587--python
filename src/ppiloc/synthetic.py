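"""Synthetic partially labeled PPI networks with planted co-localization structure.

The generator emulates a yeast-scale interaction network: 22 localization
classes with the empirical yeast class frequencies, a 1/2/3+ label
multiplicity mix of about 69/30/2%, edges placed so that a target fraction
(default 0.5, the empirically observed 0.4-0.6 band) joins co-localized
proteins, per-edge evidence from 28 experiment source groups whose planted
reliabilities bias which edges they report, and a fraction of proteins
masked to uncharacterized.  Everything flows from one seeded generator, so
networks are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    AnnotationSet,
    DEFAULT_LOCALIZATION_COUNTS,
    EvidenceRecord,
    LocalizationVocabulary,
    Throughput,
)

__all__ = ["GeneratorConfig", "generate", "reference_fixture", "coloc_fraction"]

_DEFAULT_FREQS = tuple(float(c) for _, c in DEFAULT_LOCALIZATION_COUNTS)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic network.

    Defaults emulate the yeast reference proteome: 22 classes with the
    empirical class sizes, multiplicity mix 68.8/29.6/2.2%, target
    co-localized edge fraction 0.5, 28 evidence source groups with planted
    reliabilities in [0.3, 0.7], and 17% of proteins uncharacterized.
    """

    n_proteins: int = 1000
    K: int = 22
    label_frequencies: Optional[Sequence[float]] = None  # default: yeast class sizes
    multiplicity_mix: Tuple[float, float, float] = (0.688, 0.296, 0.022)
    target_coloc_fraction: float = 0.5
    mean_degree: float = 8.0
    n_source_groups: int = 28
    source_reliability_range: Tuple[float, float] = (0.3, 0.7)
    frac_unlabeled: float = 0.17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 < self.target_coloc_fraction < 1.0):
            raise ValueError("target_coloc_fraction must be in (0, 1)")
        if not (0.0 <= self.frac_unlabeled < 1.0):
            raise ValueError("frac_unlabeled must be in [0, 1)")
        if any(m < 0 for m in self.multiplicity_mix) or sum(self.multiplicity_mix) <= 0:
            raise ValueError("multiplicity_mix must be non-negative, not all zero")
        if self.label_frequencies is not None:
            if len(self.label_frequencies) != self.K:
                raise ValueError("label_frequencies length must equal K")
            if any(f < 0 for f in self.label_frequencies) or sum(self.label_frequencies) <= 0:
                raise ValueError("label_frequencies must be non-negative, not all zero")

    def frequencies(self) -> np.ndarray:
        if self.label_frequencies is not None:
            f = np.asarray(self.label_frequencies, dtype=float)
        elif self.K == 22:
            f = np.asarray(_DEFAULT_FREQS)
        else:
            f = np.ones(self.K)
        return f / f.sum()

    def vocabulary(self) -> LocalizationVocabulary:
        if self.K == 22 and self.label_frequencies is None:
            return LocalizationVocabulary()
        return LocalizationVocabulary(tuple(f"loc{k:02d}" for k in range(self.K)))


class UnreachableColocalizationError(ValueError):
    """The target co-localized edge fraction is below the random baseline."""


def _draw_labels(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> List[FrozenSet[int]]:
    freqs = cfg.frequencies()
    mix = np.asarray(cfg.multiplicity_mix, dtype=float)
    mix = mix / mix.sum()
    n_nonzero = int((freqs > 0).sum())
    # Draw each protein's label multiplicity, then deal labels from a
    # quota pool holding each label in exact proportion to its target
    # frequency: realized label shares then match label_frequencies up to
    # rounding, independent of the multiplicity mix (per-protein sampling
    # schemes distort the marginals of the largest classes).
    ms = [
        min(int(m), n_nonzero)
        for m in rng.choice((1, 2, 3), size=cfg.n_proteins, p=mix)
    ]
    total_slots = int(sum(ms))
    quota = freqs * total_slots
    pool: List[int] = []
    for k in range(cfg.K):
        pool.extend([k] * int(round(quota[k])))
    while len(pool) < total_slots:  # rounding shortfall
        pool.append(int(rng.choice(cfg.K, p=freqs)))
    pool = [int(x) for x in rng.permutation(pool)]

    out: List[FrozenSet[int]] = []
    for m in ms:
        picked: List[int] = []
        skipped: List[int] = []
        while len(picked) < m and pool:
            x = pool.pop()
            (skipped if x in picked else picked).append(x)
        pool[:0] = skipped  # return duplicates to the far end of the pool
        while len(picked) < m:  # pool exhausted of distinct labels
            x = int(rng.choice(cfg.K, p=freqs))
            if x not in picked:
                picked.append(x)
        out.append(frozenset(picked))
    return out


def _random_pair_coloc_baseline(
    rng: np.random.Generator, labels: Sequence[FrozenSet[int]], n_samples: int = 20000
) -> float:
    n = len(labels)
    i = rng.integers(0, n, size=n_samples)
    j = rng.integers(0, n, size=n_samples)
    ok = i != j
    share = sum(1 for a, b in zip(i[ok], j[ok]) if labels[a] & labels[b])
    return share / int(ok.sum())


def coloc_fraction(
    edges: Sequence[Tuple[int, int]], labels: Sequence[FrozenSet[int]]
) -> float:
    """Fraction of edges whose endpoints share at least one true label."""
    if not edges:
        return 0.0
    return sum(1 for u, v in edges if labels[u] & labels[v]) / len(edges)


def generate(
    config: GeneratorConfig,
) -> Tuple[List[EvidenceRecord], AnnotationSet, AnnotationSet]:
    """Generate (evidence records, released annotations, ground truth).

    Edge placement is a two-component mixture: with probability ``p_mix`` an
    edge joins two proteins sharing a true label, otherwise a uniform pair;
    ``p_mix`` is solved from the random-pair co-localization baseline so the
    expected co-localized edge fraction equals the target.  Each edge gets
    evidence from 1-3 of the source groups; a group reports co-localized
    edges with probability proportional to its planted reliability and
    non-co-localized edges proportionally to its unreliability, so the
    empirical per-group reliability recovers the planted value under the
    default symmetric conditions.  Every edge carries at least two distinct
    synthetic publications, surviving the standard publication filter.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    vocab = cfg.vocabulary()
    labels = _draw_labels(rng, cfg)
    n = cfg.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]

    # members per label for co-localized pair sampling
    members: Dict[int, List[int]] = {k: [] for k in range(cfg.K)}
    for i, ls in enumerate(labels):
        for k in ls:
            members[k].append(i)

    baseline = (
        1.0
        if cfg.K == 1
        else _random_pair_coloc_baseline(rng, labels)
    )
    target = cfg.target_coloc_fraction
    if cfg.K == 1:
        p_mix = 0.0
    else:
        if baseline >= target:
            raise UnreachableColocalizationError(
                f"target co-localized fraction {target} is not above the random "
                f"baseline {baseline:.3f}; feasible range is ({baseline:.3f}, 1)"
            )
        p_mix = (target - baseline) / (1.0 - baseline)

    # Co-localized edges are drawn inside small modules: each label's
    # member list is partitioned (once, seeded) into blocks of 4-9
    # proteins, emulating the dense complexes and compartment modules of
    # real PPI networks.  The mixture probability still controls only the
    # pairwise co-localization fraction; the module structure decides
    # *which* co-localized pairs interact.
    module_of: Dict[int, Dict[int, List[int]]] = {}
    for k in range(cfg.K):
        perm = [int(i) for i in rng.permutation(members[k])]
        module_of[k] = {}
        start = 0
        while start < len(perm):
            size = int(rng.integers(4, 10))
            block = perm[start : start + size]
            for p in block:
                module_of[k][p] = block
            start += size

    m_edges = int(round(n * cfg.mean_degree / 2.0))
    edge_set: Set[Tuple[int, int]] = set()
    edges: List[Tuple[int, int]] = []
    max_tries = 200 * m_edges
    tries = 0
    while len(edges) < m_edges and tries < max_tries:
        tries += 1
        # choose the branch once, then rejection-sample *within* it: a
        # failed draw (self pair or existing edge) must not re-roll the
        # branch, or edge placement drifts toward the uniform branch as
        # modules fill up and the co-localized fraction comes out low
        coloc_branch = rng.random() < p_mix
        key = None
        for _attempt in range(50):
            if coloc_branch:
                # co-localized pair: a protein, one of its labels, a
                # co-member of its module for that label
                u = int(rng.integers(0, n))
                ks = sorted(labels[u])
                k = ks[int(rng.integers(0, len(ks)))]
                block = module_of[k][u]
                if len(block) < 2:
                    continue
                v = block[int(rng.integers(0, len(block)))]
            else:
                u = int(rng.integers(0, n))
                v = int(rng.integers(0, n))
            if u == v:
                continue
            cand = (u, v) if u < v else (v, u)
            if cand in edge_set:
                continue
            key = cand
            break
        if key is None:
            continue
        edge_set.add(key)
        edges.append(key)
    if len(edges) < m_edges:
        raise RuntimeError("edge placement failed to reach the requested count")

    # planted source groups: evenly spaced reliabilities across the range,
    # 16 systems of which 12 split by throughput (28 groups at the default)
    lo, hi = cfg.source_reliability_range
    G = cfg.n_source_groups
    planted = np.linspace(lo, hi, G)
    # emulate the source structure of the reference data: most systems split
    # into high/low throughput, a few stand alone (16 systems -> 28 groups
    # at the default: 12 split + 4 unsplit)
    n_unsplit = 4 if G >= 6 and (G - 4) % 2 == 0 else G % 2
    n_split = (G - n_unsplit) // 2
    systems: List[Tuple[str, Throughput]] = []
    for s in range(n_split):
        systems.append((f"System-{s:02d}", Throughput.HIGH))
        systems.append((f"System-{s:02d}", Throughput.LOW))
    for s in range(n_split, n_split + n_unsplit):
        systems.append((f"System-{s:02d}", Throughput.UNSPLIT))

    coloc_flags = np.array([1 if labels[u] & labels[v] else 0 for u, v in edges])
    slots_per_edge = rng.integers(1, 4, size=len(edges))
    # Quota allocation plants each group's co-localized reported-edge
    # fraction at its reliability exactly, not merely in expectation: group
    # g receives a total slot quota t_g (tilted so the quotas are jointly
    # consistent with the realized co-localized / other slot totals), of
    # which a fraction r_g is reserved for co-localized edges.  Slots are
    # dealt greedily to the groups with the largest remaining quota of the
    # edge's class, in a seeded random edge order.
    S_c = int(slots_per_edge[coloc_flags == 1].sum())
    S_n = int(slots_per_edge[coloc_flags == 0].sum())
    T = S_c + S_n
    if S_c > 0 and S_n > 0 and G > 1:
        from scipy.optimize import brentq

        def imbalance(theta: float) -> float:
            x = np.exp(-theta * planted)
            return float((x * planted).sum() / x.sum() - S_c / T)

        if imbalance(-80.0) * imbalance(80.0) < 0:
            theta = brentq(imbalance, -80.0, 80.0)
        else:  # class imbalance outside the achievable tilt range
            theta = 0.0
        x = np.exp(-theta * planted)
    else:
        x = np.ones(G)
    t = T * x / x.sum()
    quota_c = t * planted  # co-localized slots owed to each group
    quota_n = t * (1.0 - planted)

    slot_groups: List[np.ndarray] = [np.empty(0, dtype=int)] * len(edges)
    order = rng.permutation(len(edges))
    for e_idx in order:
        s = int(slots_per_edge[e_idx])
        quota = quota_c if coloc_flags[e_idx] else quota_n
        chosen = np.argsort(-quota, kind="stable")[:s]
        quota[chosen] -= 1.0
        slot_groups[e_idx] = chosen

    records: List[EvidenceRecord] = []
    pub_counter = 0
    for e_idx, (u, v) in enumerate(edges):
        chosen = slot_groups[e_idx]
        n_groups = len(chosen)
        # distribute >= 2 distinct publications across the chosen groups
        n_pubs = max(2, n_groups)
        pubs = [f"PUB{pub_counter + j:07d}" for j in range(n_pubs)]
        pub_counter += n_pubs
        for j, pub in enumerate(pubs):
            gi = int(chosen[j % n_groups])
            system, thr = systems[gi]
            records.append(
                EvidenceRecord(ids[u], ids[v], system, thr, pub)
            )

    truth = AnnotationSet(
        vocab, {ids[i]: labels[i] for i in range(n)}
    )
    n_mask = int(round(cfg.frac_unlabeled * n))
    masked_ids = set(
        ids[i] for i in rng.choice(n, size=n_mask, replace=False)
    )
    released = truth.mask(masked_ids)
    return records, released, truth


# ---------------------------------------------------------------------------
# frozen reference fixture
# ---------------------------------------------------------------------------

#: pinned sizes of the frozen fixture (asserted by regression tests)
REFERENCE_FIXTURE_N_NODES = 58
REFERENCE_FIXTURE_N_EDGES = 161

_FIXTURE_VOCAB = LocalizationVocabulary(
    ("Nucleus", "ER", "ER to Golgi", "Bud", "Cytoplasm")
)


def reference_fixture() -> Tuple[List[EvidenceRecord], AnnotationSet, AnnotationSet]:
    """A small frozen network exercising the local-vs-global behavioral contrast.

    Three motifs, mirroring the case-study topologies of the yeast network:

    * two dense communities (labels "Nucleus" and "ER") forming an
      assortative core;
    * a transit-like bridge motif: six "ER to Golgi" proteins scattered
      between the communities rather than forming their own community, plus
      a held-out bridge protein whose neighbors are mostly negative — local
      neighborhood counting recovers the bridge label, the global cut does
      not;
    * a "Bud"-like hub whose same-label clique partners are all masked to
      uncharacterized, leaving no annotated carrier of the label — the
      data-sparsity failure mode in which every predictor misses.

    Deterministically constructed; node and edge counts are pinned.
    Returns (records, released annotations, ground truth).
    """
    rng = np.random.default_rng(20120625)  # frozen; never change
    vocab = _FIXTURE_VOCAB
    NUC, ER, BRIDGE, BUD, CYT = range(5)

    truth_labels: Dict[str, Set[int]] = {}
    edges: List[Tuple[str, str]] = []

    nuc = [f"NUC{i:02d}" for i in range(15)]
    er = [f"ER{i:02d}" for i in range(15)]
    for p in nuc:
        truth_labels[p] = {NUC}
    for p in er:
        truth_labels[p] = {ER}

    def dense(nodes: List[str], p_edge: float) -> None:
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                if rng.random() < p_edge:
                    edges.append((nodes[a], nodes[b]))

    dense(nuc, 0.45)
    dense(er, 0.45)

    # bridge motif: 6 transit proteins scattered between the two communities
    bridge = [f"BRG{i:02d}" for i in range(6)]
    for p in bridge:
        truth_labels[p] = {BRIDGE}
    for i, p in enumerate(bridge):
        # each bridge protein touches both communities, sparse among itself
        picks_n = rng.choice(15, size=2, replace=False)
        picks_e = rng.choice(15, size=2, replace=False)
        for j in picks_n:
            edges.append((p, nuc[int(j)]))
        for j in picks_e:
            edges.append((p, er[int(j)]))
    edges.append((bridge[0], bridge[1]))
    edges.append((bridge[2], bridge[3]))

    # held-out bridge protein: 2 bridge neighbors vs 4 same-community
    # negatives — the local method sees the bridge label among its
    # neighbors, the global cut is swamped by the negatives
    holdout = "BRGHELD"
    truth_labels[holdout] = {BRIDGE}
    edges += [(holdout, bridge[0]), (holdout, bridge[1])]
    edges += [(holdout, er[0]), (holdout, er[1]), (holdout, er[2]), (holdout, er[3])]

    # bud-like clique, all masked, plus a hub with heterogeneous neighbors
    bud = [f"BUD{i:02d}" for i in range(5)]
    for p in bud:
        truth_labels[p] = {BUD}
    for a in range(len(bud)):
        for b in range(a + 1, len(bud)):
            edges.append((bud[a], bud[b]))
    hub = "BUDHUB"
    truth_labels[hub] = {BUD}
    edges += [(hub, bud[0]), (hub, bud[1])]
    # heterogeneous non-bud neighborhood of the hub
    cyt = [f"CYT{i:02d}" for i in range(15)]
    for p in cyt:
        truth_labels[p] = {CYT}
    ring = list(rng.permutation(15))
    for a, b in zip(ring, ring[1:] + ring[:1]):
        edges.append((cyt[int(a)], cyt[int(b)]))
    for j in range(8):
        edges.append((hub, cyt[j]))
    edges += [(hub, nuc[0]), (hub, er[0])]
    # connect the cytoplasm ring into the core so the graph is connected
    edges += [(cyt[0], nuc[1]), (cyt[1], er[1])]

    # dedupe, keep deterministic order
    seen: Set[Tuple[str, str]] = set()
    uniq: List[Tuple[str, str]] = []
    for a, b in edges:
        key = (a, b) if a < b else (b, a)
        if key not in seen and a != b:
            seen.add(key)
            uniq.append(key)

    records: List[EvidenceRecord] = []
    for i, (a, b) in enumerate(sorted(uniq)):
        for j in range(2):  # two publications so the default filter keeps it
            records.append(
                EvidenceRecord(
                    a, b, "Two-hybrid", Throughput.LOW, f"FIXPUB{i:04d}_{j}"
                )
            )

    truth = AnnotationSet(vocab, truth_labels)
    masked = set(bud) | {hub, holdout}
    released = truth.mask(masked)
    return records, released, truth
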