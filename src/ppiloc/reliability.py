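"""Interaction reliability: source grouping, noisy-OR edge weights, co-localization stats.

Every experiment source (an experiment system, optionally split into
high- and low-throughput variants) gets an empirical reliability ``r_i``:
the fraction of its interacting pairs, both endpoints annotated, that share
at least one subcellular localization.  Independent sources combine by
noisy-OR into a per-edge weight

    w_uv = 1 - prod_i (1 - r_i) ** n_i,uv

where ``n_i,uv`` counts the distinct publications in which source ``i``
observed the pair.  Guilt-by-association predictors then run either on the
unweighted topology ("ppi_only") or on these weights ("ppi_weight").
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import AnnotationSet, EvidenceRecord, Throughput, WeightedNetwork

__all__ = [
    "SourceGroup",
    "ColocalizationTable",
    "ZeroEligiblePairsError",
    "group_sources",
    "estimate_reliability",
    "estimate_reliabilities",
    "colocalization_table",
    "edge_weight",
    "weight_network",
    "overlap_correlation",
]

log = logging.getLogger(__name__)

_THROUGHPUT_ORDER = {Throughput.HIGH: 0, Throughput.LOW: 1, Throughput.UNSPLIT: 2}


class ZeroEligiblePairsError(ValueError):
    """A source group has no pair with both endpoints annotated."""


@dataclass
class SourceGroup:
    """One experiment source: an (experiment system, throughput) key."""

    group_id: str
    system: str
    throughput: Throughput
    reliability: Optional[float] = None
    n_pairs: int = 0

    @property
    def key(self) -> Tuple[str, Throughput]:
        return (self.system, self.throughput)


@dataclass
class ColocalizationTable:
    """Per-source distinct-pair counts and shared-localization fractions."""

    rows: List[Tuple[str, int, float, float]] = field(default_factory=list)
    # each row: (group_id, n_interactions, frac_share_ge1, frac_share_ge2)

    def __post_init__(self) -> None:
        for gid, n, f1, f2 in self.rows:
            if not (0.0 <= f2 <= f1 <= 1.0) and n > 0:
                raise ValueError(f"inconsistent fractions for group {gid}")

    def as_dict(self) -> Dict[str, Tuple[int, float, float]]:
        return {gid: (n, f1, f2) for gid, n, f1, f2 in self.rows}


def make_group_id(system: str, throughput: Throughput) -> str:
    return f"{system}/{throughput.value}"


def group_sources(records: Iterable[EvidenceRecord]) -> List[SourceGroup]:
    """One group per observed (system, throughput) key.

    Systems reported without a throughput split stand alone as a single
    ``unsplit`` group.  Ordering is deterministic: system name, then
    high / low / unsplit.
    """
    pairs_by_key: Dict[Tuple[str, Throughput], set] = defaultdict(set)
    for rec in records:
        pairs_by_key[rec.group_key].add(rec.pair)
    keys = sorted(pairs_by_key, key=lambda k: (k[0], _THROUGHPUT_ORDER[k[1]]))
    return [
        SourceGroup(
            group_id=make_group_id(sys, thr),
            system=sys,
            throughput=thr,
            n_pairs=len(pairs_by_key[(sys, thr)]),
        )
        for sys, thr in keys
    ]


def _eligible_pairs_by_group(
    records: Iterable[EvidenceRecord], ann: AnnotationSet
) -> Dict[Tuple[str, Throughput], List[Tuple[FrozenSet[int], FrozenSet[int]]]]:
    """Distinct pairs per group where both endpoints are annotated."""
    pair_sets: Dict[Tuple[str, Throughput], set] = defaultdict(set)
    for rec in records:
        pair_sets[rec.group_key].add(rec.pair)
    out: Dict[Tuple[str, Throughput], List[Tuple[FrozenSet[int], FrozenSet[int]]]] = {}
    for key, pairs in pair_sets.items():
        rows = []
        for a, b in pairs:
            la, lb = ann.labels_of(a), ann.labels_of(b)
            if la and lb:
                rows.append((la, lb))
        out[key] = rows
    return out


def estimate_reliability(
    group: SourceGroup,
    records: Iterable[EvidenceRecord],
    ann: AnnotationSet,
) -> float:
    """Fraction of the group's annotated pairs sharing >= 1 localization.

    Distinct pairs only (repeated observations of a pair count once);
    pairs with an uncharacterized endpoint are excluded from numerator and
    denominator.  Raises :class:`ZeroEligiblePairsError` when no pair is
    eligible (callers may fall back via :func:`estimate_reliabilities`).
    """
    eligible = _eligible_pairs_by_group(records, ann).get(group.key, [])
    if not eligible:
        raise ZeroEligiblePairsError(
            f"group {group.group_id!r} has no annotated interaction pair"
        )
    shared = sum(1 for la, lb in eligible if la & lb)
    return shared / len(eligible)


def estimate_reliabilities(
    groups: Sequence[SourceGroup],
    records: Iterable[EvidenceRecord],
    ann: AnnotationSet,
) -> Dict[str, float]:
    """Per-group reliabilities with mean fallback for unestimable groups.

    Groups without any annotated pair receive the mean reliability over the
    estimable groups (logged).  Reliabilities are also written back onto the
    ``SourceGroup`` objects.
    """
    records = list(records)
    by_group = _eligible_pairs_by_group(records, ann)
    out: Dict[str, float] = {}
    missing: List[SourceGroup] = []
    for g in groups:
        eligible = by_group.get(g.key, [])
        if eligible:
            shared = sum(1 for la, lb in eligible if la & lb)
            out[g.group_id] = shared / len(eligible)
        else:
            missing.append(g)
    if missing:
        if not out:
            raise ZeroEligiblePairsError("no group has any annotated pair")
        fallback = sum(out.values()) / len(out)
        for g in missing:
            log.warning(
                "group %s has no annotated pair; falling back to mean "
                "reliability %.4f",
                g.group_id,
                fallback,
            )
            out[g.group_id] = fallback
    for g in groups:
        g.reliability = out[g.group_id]
    return out


def colocalization_table(
    groups: Sequence[SourceGroup],
    records: Iterable[EvidenceRecord],
    ann: AnnotationSet,
) -> ColocalizationTable:
    """Per-source pair counts and fractions sharing >= 1 and >= 2 labels."""
    by_group = _eligible_pairs_by_group(list(records), ann)
    rows: List[Tuple[str, int, float, float]] = []
    for g in groups:
        eligible = by_group.get(g.key, [])
        n = len(eligible)
        if n == 0:
            rows.append((g.group_id, 0, 0.0, 0.0))
            continue
        ge1 = sum(1 for la, lb in eligible if len(la & lb) >= 1)
        ge2 = sum(1 for la, lb in eligible if len(la & lb) >= 2)
        rows.append((g.group_id, n, ge1 / n, ge2 / n))
    return ColocalizationTable(rows)


def edge_weight(
    edge_evidence: Sequence[Tuple[str, int]],
    reliabilities: Mapping[str, float],
) -> float:
    """Noisy-OR combination of independent source reliabilities.

    ``edge_evidence`` lists ``(group_id, n_i_uv)`` with ``n_i_uv >= 1``;
    returns ``1 - prod_i (1 - r_i) ** n_i_uv`` clamped to [0, 1].
    """
    log_surv = 0.0
    for gid, n in edge_evidence:
        if n < 1:
            raise ValueError(f"observation count must be >= 1, got {n} for {gid}")
        try:
            r = reliabilities[gid]
        except KeyError:
            raise KeyError(f"unknown source group {gid!r}") from None
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"reliability out of [0, 1] for group {gid}: {r}")
        if r >= 1.0:
            return 1.0
        log_surv += n * math.log1p(-r)
    return float(min(1.0, max(0.0, -math.expm1(log_surv))))


def weight_network(
    net: WeightedNetwork,
    mode: str,
    reliabilities: Optional[Mapping[str, float]] = None,
) -> WeightedNetwork:
    """Return a copy of the network with edge weights set by ``mode``.

    ``ppi_only`` keeps the topology qualitative (all weights 1);
    ``ppi_weight`` applies the noisy-OR weight per edge.  An edge whose
    noisy-OR weight collapses to 0 (all contributing sources fully
    unreliable) falls back to weight 1 so it stays usable, as in the
    unweighted scheme.
    """
    if mode not in ("ppi_only", "ppi_weight"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    out = net.copy()
    if mode == "ppi_only":
        for u, v in out.graph.edges:
            out.graph[u][v]["weight"] = 1.0
        return out
    if reliabilities is None:
        raise ValueError("ppi_weight mode requires estimated reliabilities")
    for u, v, data in out.graph.edges(data=True):
        w = edge_weight(data["evidence"], reliabilities)
        data["weight"] = w if w > 0.0 else 1.0
    return out


def overlap_correlation(
    net: WeightedNetwork,
    ann: AnnotationSet,
    series: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
) -> float:
    """Pearson correlation between two per-edge overlap series.

    By default the first series is the localization overlap
    ``|labels(u) & labels(v)|`` over edges with both endpoints annotated and
    the second is ``min(|labels(u)|, |labels(v)|)``; any alternative pair of
    equally long per-edge series may be injected via ``series``.
    """
    if series is None:
        xs: List[float] = []
        ys: List[float] = []
        for u, v in net.edges:
            lu, lv = ann.labels_of(u), ann.labels_of(v)
            if lu and lv:
                xs.append(float(len(lu & lv)))
                ys.append(float(min(len(lu), len(lv))))
    else:
        xs, ys = list(series[0]), list(series[1])
        if len(xs) != len(ys):
            raise ValueError("series lengths differ")
    if len(xs) < 2:
        raise ValueError("need >= 2 edges with both endpoints annotated")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(x, y)[0, 1])
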