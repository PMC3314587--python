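"""Core domain types: label vocabulary, annotations, evidence records, weighted network.

The package models a partially labeled protein-protein interaction (PPI)
network ``G = (V, E, W)``.  Nodes are proteins; a subset ``L`` carries one or
more subcellular localization labels out of a fixed vocabulary of ``K``
classes, the rest (``U``) are uncharacterized and are the prediction targets.
Edge weights ``w_uv`` in (0, 1] encode interaction reliability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx

__all__ = [
    "Throughput",
    "LocalizationVocabulary",
    "AnnotationSet",
    "EvidenceRecord",
    "WeightedNetwork",
    "DEFAULT_LOCALIZATIONS",
    "DEFAULT_LOCALIZATION_COUNTS",
    "default_vocabulary",
]

#: The 22 yeast GFP-fusion compartments, in their conventional order, with the
#: number of annotated proteins per compartment in the reference proteome.
DEFAULT_LOCALIZATION_COUNTS: Tuple[Tuple[str, int], ...] = (
    ("Actin", 30),
    ("Bud", 12),
    ("Bud neck", 51),
    ("Cell periphery", 59),
    ("Cytoplasm", 1195),
    ("Early Golgi", 40),
    ("Endosome", 39),
    ("ER", 125),
    ("ER to Golgi", 6),
    ("Golgi", 29),
    ("Late Golgi", 36),
    ("Lipid particle", 9),
    ("Microtubule", 15),
    ("Mitochondrion", 206),
    ("Nuclear periphery", 51),
    ("Nucleolus", 145),
    ("Nucleus", 1071),
    ("Peroxisome", 18),
    ("Punctate composite", 96),
    ("Spindle pole", 57),
    ("Vacuolar membrane", 31),
    ("Vacuole", 48),
)

DEFAULT_LOCALIZATIONS: Tuple[str, ...] = tuple(n for n, _ in DEFAULT_LOCALIZATION_COUNTS)


class Throughput(str, enum.Enum):
    """Throughput level of an experiment system observation."""

    HIGH = "high"
    LOW = "low"
    UNSPLIT = "unsplit"

    @classmethod
    def parse(cls, token: str) -> "Throughput":
        t = token.strip().lower()
        if t in ("high", "high throughput", "high-throughput"):
            return cls.HIGH
        if t in ("low", "low throughput", "low-throughput", "low throughout"):
            return cls.LOW
        # absent / unrecognized throughput collapses into the unsplit group
        return cls.UNSPLIT


@dataclass(frozen=True)
class LocalizationVocabulary:
    """Ordered vocabulary of K localization names plus a reserved token.

    The reserved token (``"ambiguous"`` by default) marks annotations that
    carry no localization information; it is never a member of ``labels``.
    """

    labels: Tuple[str, ...] = DEFAULT_LOCALIZATIONS
    reserved_token: str = "ambiguous"

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("vocabulary needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vocabulary labels must be unique")
        if any(not l for l in self.labels):
            raise ValueError("vocabulary labels must be non-empty strings")
        if self.reserved_token in self.labels:
            raise ValueError(
                f"reserved token {self.reserved_token!r} may not be a label"
            )
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    @property
    def size(self) -> int:
        return len(self.labels)

    K = size  # field-standard alias

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown localization label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.labels)


def default_vocabulary() -> LocalizationVocabulary:
    """The 22-compartment yeast vocabulary."""
    return LocalizationVocabulary()


@dataclass(frozen=True)
class EvidenceRecord:
    """One experimental observation of a physical interaction.

    Unordered pair semantics: ``(a, b)`` and ``(b, a)`` denote the same
    interaction; ``pair`` is the canonical sorted form.
    """

    protein_a: str
    protein_b: str
    system: str
    throughput: Throughput
    publication: str

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction rejected: {self.protein_a!r}")

    @property
    def pair(self) -> Tuple[str, str]:
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)

    @property
    def group_key(self) -> Tuple[str, Throughput]:
        return (self.system, self.throughput)


class AnnotationSet:
    """Per-protein localization label sets over a fixed vocabulary.

    A protein with a non-empty label set is *labeled* (member of ``L``); a
    protein with an empty set — including one annotated only with the
    reserved token — is *uncharacterized* (member of ``U``).
    """

    def __init__(
        self,
        vocabulary: LocalizationVocabulary,
        assignments: Mapping[str, Iterable[int]],
    ) -> None:
        self.vocabulary = vocabulary
        K = vocabulary.size
        self._assignments: Dict[str, FrozenSet[int]] = {}
        for pid, idxs in assignments.items():
            s = frozenset(int(i) for i in idxs)
            for i in s:
                if not (0 <= i < K):
                    raise ValueError(
                        f"label index {i} out of range [0, {K}) for protein {pid!r}"
                    )
            self._assignments[pid] = s

    @classmethod
    def from_names(
        cls,
        vocabulary: LocalizationVocabulary,
        named: Mapping[str, Iterable[str]],
    ) -> "AnnotationSet":
        return cls(
            vocabulary,
            {
                pid: {vocabulary.index(n) for n in names}
                for pid, names in named.items()
            },
        )

    @property
    def assignments(self) -> Mapping[str, FrozenSet[int]]:
        return self._assignments

    def labels_of(self, pid: str) -> FrozenSet[int]:
        return self._assignments.get(pid, frozenset())

    def label_names_of(self, pid: str) -> Tuple[str, ...]:
        return tuple(self.vocabulary.labels[i] for i in sorted(self.labels_of(pid)))

    @property
    def labeled_ids(self) -> Set[str]:
        return {p for p, s in self._assignments.items() if s}

    @property
    def unlabeled_ids(self) -> Set[str]:
        return {p for p, s in self._assignments.items() if not s}

    @property
    def protein_ids(self) -> Set[str]:
        return set(self._assignments)

    def is_labeled(self, pid: str) -> bool:
        return bool(self._assignments.get(pid))

    def mask(self, hidden: Iterable[str]) -> "AnnotationSet":
        """Return a copy with every protein in ``hidden`` made uncharacterized.

        All labels of a hidden protein are removed jointly (atomic masking),
        so a multi-label protein never leaks a subset of its labels.
        """
        hidden = set(hidden)
        return AnnotationSet(
            self.vocabulary,
            {
                p: (frozenset() if p in hidden else s)
                for p, s in self._assignments.items()
            },
        )

    def label_counts(self) -> List[int]:
        """Number of labeled proteins carrying each label."""
        counts = [0] * self.vocabulary.size
        for s in self._assignments.values():
            for i in s:
                counts[i] += 1
        return counts

    def __len__(self) -> int:
        return len(self._assignments)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AnnotationSet(K={self.vocabulary.size}, "
            f"n={len(self)}, labeled={len(self.labeled_ids)})"
        )


class WeightedNetwork:
    """Deduplicated undirected PPI graph with per-edge reliability weights.

    Thin wrapper over :class:`networkx.Graph`; every edge carries a ``weight``
    in (0, 1] and an ``evidence`` list of ``(source_group_id, n_observations)``
    pairs recording which experiment sources reported it and how often.
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------------
    def add_edge(
        self,
        u: str,
        v: str,
        weight: float = 1.0,
        evidence: Optional[List[Tuple[str, int]]] = None,
    ) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        if not (0.0 < weight <= 1.0):
            raise ValueError(f"edge weight must be in (0, 1], got {weight}")
        self.graph.add_edge(u, v, weight=float(weight), evidence=list(evidence or []))

    # -- queries -------------------------------------------------------------
    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def weight(self, u: str, v: str) -> float:
        return float(self.graph[u][v]["weight"])

    def set_weight(self, u: str, v: str, w: float) -> None:
        if not (0.0 < w <= 1.0):
            raise ValueError(f"edge weight must be in (0, 1], got {w}")
        self.graph[u][v]["weight"] = float(w)

    def evidence(self, u: str, v: str) -> List[Tuple[str, int]]:
        return list(self.graph[u][v]["evidence"])

    def neighbors(self, u: str) -> List[str]:
        return sorted(self.graph.neighbors(u))

    def degree_weight(self, u: str) -> float:
        """Sum of incident edge weights (weighted degree)."""
        return float(sum(d["weight"] for _, _, d in self.graph.edges(u, data=True)))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.graph.copy())

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
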