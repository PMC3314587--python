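"""Graph-based semi-supervised predictors for multi-label node classification.

Four families, each scoring every uncharacterized protein against every
localization and emitting binary calls:

* **Majority** (with Merged and Common variants) — neighborhood counting
  over immediate labeled neighbors; local.
* **chi2** — over-representation of a label in the sigma-hop neighborhood
  relative to its global frequency, scored as (n_k - e_k)^2 / e_k; local.
* **GenMultiCut (GMC)** — per-label binary assignment over all
  uncharacterized nodes maximizing edge agreement plus labeled-neighbor
  support, solved exactly as an ILP or approximately by seeded local
  search; global.
* **FunctionalFlow** — iterative simulation in which annotated proteins
  act as infinite label reservoirs and labels flow downhill along
  capacity-limited edges for ``d`` rounds; a node's score is its cumulative
  inflow; both local and global in character.

All predictors are deterministic given (network, annotations, seed).
Tie-breaking for top-``m`` calls is: higher score first, then lower label
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import coo_matrix

from .core import AnnotationSet, LocalizationVocabulary, WeightedNetwork

__all__ = [
    "ScoreMatrix",
    "majority_predict",
    "majority_merged",
    "majority_common",
    "chi2_predict",
    "gmc_predict",
    "funflow_predict",
    "PREDICTOR_NAMES",
]

log = logging.getLogger(__name__)

PREDICTOR_NAMES = ("majority", "merged", "common", "chi2", "gmc", "funflow")


@dataclass
class ScoreMatrix:
    """Per-predictor confidence scores and binary calls over proteins x K."""

    proteins: List[str]
    vocabulary: LocalizationVocabulary
    scores: np.ndarray  # float, (n_proteins, K)
    calls: np.ndarray  # int8 0/1, (n_proteins, K)
    predictor_name: str = ""

    def __post_init__(self) -> None:
        n, K = len(self.proteins), self.vocabulary.size
        self.scores = np.asarray(self.scores, dtype=float)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.scores.shape != (n, K) or self.calls.shape != (n, K):
            raise ValueError(
                f"matrix shapes {self.scores.shape}/{self.calls.shape} do not "
                f"match {n} proteins x {K} labels"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def row_of(self, pid: str) -> int:
        return self.proteins.index(pid)

    def called_labels(self, pid: str) -> Tuple[str, ...]:
        i = self.row_of(pid)
        return tuple(
            self.vocabulary.labels[k]
            for k in range(self.vocabulary.size)
            if self.calls[i, k]
        )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _targets(net: WeightedNetwork, ann: AnnotationSet) -> List[str]:
    """Prediction targets: network nodes without annotation, sorted by ID."""
    return sorted(u for u in net.graph.nodes if not ann.is_labeled(u))


def _top_calls(scores: np.ndarray, max_labels: int) -> np.ndarray:
    """Binary calls for the top ``max_labels`` strictly positive scores.

    Ranking: higher score first, ties by lower label index.
    """
    n, K = scores.shape
    calls = np.zeros((n, K), dtype=np.int8)
    for i in range(n):
        order = sorted(range(K), key=lambda k: (-scores[i, k], k))
        taken = 0
        for k in order:
            if taken >= max_labels or scores[i, k] <= 0.0:
                break
            calls[i, k] = 1
            taken += 1
    return calls


# ---------------------------------------------------------------------------
# Majority and variants
# ---------------------------------------------------------------------------

def majority_predict(
    net: WeightedNetwork,
    ann: AnnotationSet,
    weighted: bool = False,
    max_labels: int = 3,
) -> ScoreMatrix:
    """Neighborhood counting: sum (weighted) neighbor votes per label.

    Each uncharacterized protein is assigned up to ``max_labels`` (default 3)
    localizations common among its labeled immediate neighbors; in the
    weighted variant a neighbor's vote counts its edge weight.
    """
    targets = _targets(net, ann)
    K = ann.vocabulary.size
    scores = np.zeros((len(targets), K))
    for i, u in enumerate(targets):
        for v in net.graph.neighbors(u):
            lv = ann.labels_of(v)
            if not lv:
                continue
            w = net.weight(u, v) if weighted else 1.0
            for k in lv:
                scores[i, k] += w
    return ScoreMatrix(
        targets, ann.vocabulary, scores, _top_calls(scores, max_labels),
        predictor_name="majority",
    )


def majority_merged(net: WeightedNetwork, ann: AnnotationSet) -> ScoreMatrix:
    """Merged variant: call the union of all labeled neighbors' label sets."""
    targets = _targets(net, ann)
    K = ann.vocabulary.size
    scores = np.zeros((len(targets), K))
    calls = np.zeros((len(targets), K), dtype=np.int8)
    for i, u in enumerate(targets):
        for v in net.graph.neighbors(u):
            for k in ann.labels_of(v):
                scores[i, k] += 1.0  # neighbor count, used only for ranking
                calls[i, k] = 1
    return ScoreMatrix(targets, ann.vocabulary, scores, calls, "merged")


def majority_common(net: WeightedNetwork, ann: AnnotationSet) -> ScoreMatrix:
    """Common variant: call only labels shared by every labeled neighbor."""
    targets = _targets(net, ann)
    K = ann.vocabulary.size
    scores = np.zeros((len(targets), K))
    calls = np.zeros((len(targets), K), dtype=np.int8)
    for i, u in enumerate(targets):
        common: Optional[frozenset] = None
        for v in net.graph.neighbors(u):
            lv = ann.labels_of(v)
            if not lv:
                continue
            for k in lv:
                scores[i, k] += 1.0
            common = lv if common is None else (common & lv)
        if common:
            for k in common:
                calls[i, k] = 1
    return ScoreMatrix(targets, ann.vocabulary, scores, calls, "common")


# ---------------------------------------------------------------------------
# chi-square over-representation score
# ---------------------------------------------------------------------------

def chi2_predict(
    net: WeightedNetwork,
    ann: AnnotationSet,
    sigma: int = 1,
    max_labels: int = 3,
) -> ScoreMatrix:
    """Label over-representation in the sigma-hop neighborhood.

    For protein ``u`` let ``N`` be the labeled proteins within unweighted hop
    distance <= sigma (u excluded), ``n_k`` the members of ``N`` carrying
    label ``k`` and ``e_k = |N| * freq(k)`` the expectation under the global
    label frequency among labeled proteins.  The score is
    ``(n_k - e_k)^2 / e_k`` when ``n_k > e_k`` (over-representation only),
    else 0.  Neighborhoods are unweighted by construction; the statistic has
    no natural weighted extension.
    """
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    targets = _targets(net, ann)
    K = ann.vocabulary.size

    labeled = [p for p in net.graph.nodes if ann.is_labeled(p)]
    n_labeled = len(labeled)
    freq = np.zeros(K)
    for p in labeled:
        for k in ann.labels_of(p):
            freq[k] += 1.0
    if n_labeled:
        freq /= n_labeled
    absent = [k for k in range(K) if freq[k] == 0.0]
    if absent:
        log.info(
            "chi2: %d label(s) absent from the training annotations score 0",
            len(absent),
        )

    adj = net.graph.adj
    scores = np.zeros((len(targets), K))
    for i, u in enumerate(targets):
        # BFS to hop distance sigma
        seen = {u}
        frontier = [u]
        members: List[str] = []
        for _ in range(sigma):
            nxt: List[str] = []
            for x in frontier:
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        nxt.append(y)
            members.extend(nxt)
            frontier = nxt
            if not frontier:
                break
        lab_members = [v for v in members if ann.is_labeled(v)]
        if not lab_members:
            continue
        n_k = np.zeros(K)
        for v in lab_members:
            for k in ann.labels_of(v):
                n_k[k] += 1.0
        e_k = len(lab_members) * freq
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(
                (n_k > e_k) & (e_k > 0.0), (n_k - e_k) ** 2 / e_k, 0.0
            )
        scores[i] = s
    return ScoreMatrix(
        targets, ann.vocabulary, scores, _top_calls(scores, max_labels),
        predictor_name="chi2",
    )


# ---------------------------------------------------------------------------
# GenMultiCut
# ---------------------------------------------------------------------------

def _gmc_instance(
    net: WeightedNetwork, ann: AnnotationSet, k: int, include_negative: bool
) -> Tuple[List[str], Dict[str, int], List[Tuple[int, int, float]], np.ndarray, np.ndarray]:
    """Per-label GMC data: targets, U-U edges, labeled-neighbor masses.

    ``h[u]`` is the weighted count of labeled neighbors carrying label ``k``,
    ``hbar[u]`` the weighted count of labeled neighbors not carrying it
    (zeroed when the negative term is excluded).
    """
    targets = _targets(net, ann)
    idx = {u: i for i, u in enumerate(targets)}
    h = np.zeros(len(targets))
    hbar = np.zeros(len(targets))
    uu_edges: List[Tuple[int, int, float]] = []
    for u in targets:
        i = idx[u]
        for v in net.graph.neighbors(u):
            lv = ann.labels_of(v)
            w = net.weight(u, v)
            if lv:
                if k in lv:
                    h[i] += w
                elif include_negative:
                    hbar[i] += w
            else:
                j = idx[v]
                if i < j:
                    uu_edges.append((i, j, w))
    return targets, idx, uu_edges, h, hbar


def gmc_objective(
    x: np.ndarray,
    uu_edges: Sequence[Tuple[int, int, float]],
    h: np.ndarray,
    hbar: np.ndarray,
) -> float:
    """Agreement objective: sum_{U-U edges} w * [x_i == x_j] + sum_u x_u h_u + (1-x_u) hbar_u."""
    val = float(x @ h + (1 - x) @ hbar)
    for i, j, w in uu_edges:
        if x[i] == x[j]:
            val += w
    return val


def _gmc_solve_ilp(
    uu_edges: Sequence[Tuple[int, int, float]],
    h: np.ndarray,
    hbar: np.ndarray,
    time_limit: Optional[float],
) -> np.ndarray:
    n = len(h)
    m = len(uu_edges)
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    # variables: x_0..x_{n-1} binary, a_0..a_{m-1} continuous in [0, 1]
    # maximize sum w_e a_e + sum x h + (1-x) hbar
    #   s.t. a_e <= 1 - x_i + x_j and a_e <= 1 + x_i - x_j  for e = (i, j)
    c = np.concatenate([-(h - hbar), -np.array([w for _, _, w in uu_edges])])
    integrality = np.concatenate([np.ones(n), np.zeros(m)])
    lb = np.zeros(n + m)
    ub = np.ones(n + m)
    constraints = []
    if m:
        rows, cols, vals = [], [], []
        for e, (i, j, _) in enumerate(uu_edges):
            # a_e + x_i - x_j <= 1
            rows += [2 * e] * 3
            cols += [n + e, i, j]
            vals += [1.0, 1.0, -1.0]
            # a_e - x_i + x_j <= 1
            rows += [2 * e + 1] * 3
            cols += [n + e, i, j]
            vals += [1.0, -1.0, 1.0]
        A = coo_matrix((vals, (rows, cols)), shape=(2 * m, n + m))
        constraints.append(LinearConstraint(A, -np.inf, np.ones(2 * m)))
    options = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=(lb, ub),
        options=options,
    )
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"GMC ILP did not reach optimality: {res.message}")
    return np.round(res.x[:n]).astype(np.int8)


def _gmc_solve_local_search(
    uu_edges: Sequence[Tuple[int, int, float]],
    h: np.ndarray,
    hbar: np.ndarray,
    x0: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Seeded single-flip hill climbing from a warm start."""
    rng = np.random.default_rng(seed)
    n = len(h)
    x = x0.astype(np.int8).copy()
    nbrs: Dict[int, List[Tuple[int, float]]] = {i: [] for i in range(n)}
    for i, j, w in uu_edges:
        nbrs[i].append((j, w))
        nbrs[j].append((i, w))
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            delta = (1 - 2 * int(x[i])) * (h[i] - hbar[i])
            for j, w in nbrs[i]:
                delta += w * (1.0 - 2.0 * (x[i] == x[j]))
            if delta > 1e-12:
                x[i] = 1 - x[i]
                improved = True
    return x


def _zero_unanchored_components(
    x: np.ndarray,
    uu_edges: Sequence[Tuple[int, int, float]],
    h: np.ndarray,
    hbar: np.ndarray,
) -> np.ndarray:
    """Resolve the degenerate tie: components with no labeled anchor take 0.

    A connected component of the unlabeled-unlabeled subgraph in which no
    member has any labeled neighbor scores identically under the all-zero
    and all-one assignments; the all-zero solution is returned.
    """
    n = len(h)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j, _ in uu_edges:
        parent[find(i)] = find(j)
    anchored = set()
    for i in range(n):
        if h[i] != 0.0 or hbar[i] != 0.0:
            anchored.add(find(i))
    out = x.copy()
    for i in range(n):
        if find(i) not in anchored:
            out[i] = 0
    return out


def gmc_predict(
    net: WeightedNetwork,
    ann: AnnotationSet,
    solver: str = "ilp",
    seed: int = 0,
    include_negative: bool = True,
    time_limit: Optional[float] = None,
) -> ScoreMatrix:
    """Cut-based global assignment, one binary problem per localization.

    Maximizes, over assignments ``x_u`` of the uncharacterized proteins,
    the weighted number of agreeing edges among them plus the weighted
    agreement with annotated neighbors.  With ``include_negative`` (default)
    a protein kept out of the label is rewarded for annotated neighbors not
    carrying it, making the problem the standard binary cut; without it only
    positive agreement counts.  ``solver="ilp"`` is exact (HiGHS
    mixed-integer solve); ``solver="local_search"`` runs seeded single-flip
    hill climbing warm-started from the Majority calls.  On an exact tie
    (e.g. a fully unannotated component) the all-zero assignment is
    returned.  Ranking scores are the agreement mass
    ``h_u + sum_{U-U neighbors v} w_uv x_v``.
    """
    if solver not in ("ilp", "local_search"):
        raise ValueError(f"unknown GMC solver {solver!r}")
    K = ann.vocabulary.size
    targets = _targets(net, ann)
    n = len(targets)
    scores = np.zeros((n, K))
    calls = np.zeros((n, K), dtype=np.int8)
    warm_majority = majority_predict(net, ann, weighted=True) if solver == "local_search" else None
    for k in range(K):
        tk, idx, uu_edges, h, hbar = _gmc_instance(net, ann, k, include_negative)
        try:
            if solver == "ilp":
                x = _gmc_solve_ilp(uu_edges, h, hbar, time_limit)
            else:
                x0 = warm_majority.calls[:, k].astype(np.int8)
                x = _gmc_solve_local_search(uu_edges, h, hbar, x0, seed + k)
        except RuntimeError as exc:
            raise RuntimeError(
                f"GMC solve failed for label {ann.vocabulary.labels[k]!r}: {exc}"
            ) from exc
        x = _zero_unanchored_components(x, uu_edges, h, hbar)
        calls[:, k] = x
        agree = h.copy()
        for i, j, w in uu_edges:
            agree[i] += w * x[j]
            agree[j] += w * x[i]
        scores[:, k] = agree
    return ScoreMatrix(targets, ann.vocabulary, scores, calls, "gmc")


# ---------------------------------------------------------------------------
# FunctionalFlow
# ---------------------------------------------------------------------------

def _edge_flow_capacity(
    w_uv: np.ndarray, deg_u: np.ndarray, reservoir_u: np.ndarray
) -> np.ndarray:
    """Downhill flow allowance along one directed edge per entry.

    min(w_uv, (w_uv / deg_u) * R_u): an infinite reservoir saturates the
    edge at its weight; a finite reservoir is split across incident edges
    in proportion to their weights.  This is the one place the capacity
    rule lives, for easy substitution.
    """
    with np.errstate(invalid="ignore"):
        frac = np.where(np.isinf(reservoir_u), 1.0, 0.0)
        finite = ~np.isinf(reservoir_u)
        frac[finite] = np.minimum(1.0, reservoir_u[finite] / deg_u[finite])
    return w_uv * frac


def funflow_predict(
    net: WeightedNetwork,
    ann: AnnotationSet,
    d: int = 6,
    threshold: float = 0.0,
) -> ScoreMatrix:
    """Functional-flow propagation: labels flow downhill for ``d`` rounds.

    Annotated carriers of a label hold an infinite reservoir for it; in each
    synchronous round, flow moves along each directed edge from the higher
    reservoir to the lower, capped by the edge weight and by the sender's
    reservoir split proportionally over its incident edge weights.  The
    score of an uncharacterized protein is its cumulative inflow over the
    ``d`` rounds; it is called positive when the score exceeds ``threshold``
    (default 0, the conventional decision boundary).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    nodes = sorted(net.graph.nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    K = ann.vocabulary.size

    # directed edge arrays (both directions of every undirected edge)
    src: List[int] = []
    dst: List[int] = []
    wts: List[float] = []
    for u, v, data in net.graph.edges(data=True):
        w = float(data["weight"])
        src += [pos[u], pos[v]]
        dst += [pos[v], pos[u]]
        wts += [w, w]
    src_a = np.asarray(src, dtype=np.int64)
    dst_a = np.asarray(dst, dtype=np.int64)
    w_a = np.asarray(wts, dtype=float)
    deg = np.zeros(n)
    np.add.at(deg, src_a, w_a)

    carrier = np.zeros((n, K), dtype=bool)
    for u in nodes:
        for k in ann.labels_of(u):
            carrier[pos[u], k] = True

    targets = _targets(net, ann)
    inflow_total = np.zeros((n, K))
    for k in range(K):
        if not carrier[:, k].any():
            continue  # no source: scores stay 0
        R = np.zeros(n)
        R[carrier[:, k]] = np.inf
        for _ in range(d):
            R_src = R[src_a]
            downhill = R_src > R[dst_a]
            g = np.zeros(len(src_a))
            if downhill.any():
                g[downhill] = _edge_flow_capacity(
                    w_a[downhill], deg[src_a[downhill]], R_src[downhill]
                )
            inflow = np.zeros(n)
            outflow = np.zeros(n)
            np.add.at(inflow, dst_a, g)
            np.add.at(outflow, src_a, g)
            R = R + inflow - outflow
            R[carrier[:, k]] = np.inf  # carriers remain infinite sources
            inflow_total[:, k] += inflow

    rows = [pos[u] for u in targets]
    scores = inflow_total[rows, :]
    calls = (scores > threshold).astype(np.int8)
    return ScoreMatrix(targets, ann.vocabulary, scores, calls, "funflow")
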