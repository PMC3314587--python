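"""Cross-validation harness, ranking/threshold metrics, prediction audit categories.

Per-label ranking quality is measured by average precision (AP); the mean
over labels with at least one test positive is the MAP.  Binary calls are
summarized per label by pooled precision, recall and the F1 score
``F1(k) = 2 p_k r_k / (p_k + r_k)``.  A predicted label set is audited
against a reference set as Correct (equal), Partial Correct (some but not
all shared), Mismatch (disjoint) or Unknown (no prediction).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .core import AnnotationSet, WeightedNetwork
from .predictors import ScoreMatrix

__all__ = [
    "FoldAssignment",
    "EvalReport",
    "PredictionCategory",
    "make_folds",
    "average_precision",
    "f1_micro",
    "cross_validate",
    "categorize",
    "categorize_cohort",
]

log = logging.getLogger(__name__)

Predictor = Callable[[WeightedNetwork, AnnotationSet], ScoreMatrix]
Reweighter = Callable[[WeightedNetwork, AnnotationSet], WeightedNetwork]


@dataclass
class FoldAssignment:
    """Partition of the labeled proteins into cross-validation folds."""

    n_folds: int
    fold_of: Dict[str, int]
    seed: int

    def members(self, fold: int) -> List[str]:
        return sorted(p for p, f in self.fold_of.items() if f == fold)

    def __post_init__(self) -> None:
        sizes = [len(self.members(f)) for f in range(self.n_folds)]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")


class PredictionCategory(str, enum.Enum):
    CORRECT = "Correct"
    PARTIAL_CORRECT = "PartialCorrect"
    MISMATCH = "Mismatch"
    UNKNOWN = "Unknown"


@dataclass
class EvalReport:
    """Cross-validation results for one predictor."""

    labels: Tuple[str, ...]
    ap_per_label: np.ndarray  # NaN for labels without pooled test positives
    map_score: float
    precision: np.ndarray
    recall: np.ndarray
    f1_per_label: np.ndarray
    per_fold_ap: np.ndarray  # (n_folds, K), NaN where undefined
    skipped_labels: Tuple[str, ...]
    folds: FoldAssignment
    predictor_name: str = ""

    def summary_rows(self) -> List[Tuple[str, float, float, float, float]]:
        return [
            (
                self.labels[k],
                float(self.ap_per_label[k]),
                float(self.precision[k]),
                float(self.recall[k]),
                float(self.f1_per_label[k]),
            )
            for k in range(len(self.labels))
        ]


def make_folds(
    ann: AnnotationSet,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> FoldAssignment:
    """Split the labeled proteins into folds of near-equal size.

    Deterministic given ``seed``.  The stratified mode uses greedy iterative
    stratification: proteins are visited rarest-label first and placed in
    the fold that most needs their rarest label, subject to the size-balance
    constraint.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labeled = sorted(ann.labeled_ids)
    if len(labeled) < n_folds:
        raise ValueError(f"{len(labeled)} labeled proteins < {n_folds} folds")
    rng = np.random.default_rng(seed)

    if not stratified:
        order = list(rng.permutation(len(labeled)))
        fold_of = {labeled[i]: pos % n_folds for pos, i in enumerate(order)}
        return FoldAssignment(n_folds, fold_of, seed)

    K = ann.vocabulary.size
    label_total = np.array(ann.label_counts(), dtype=float)
    # desired per-fold positives for each label
    desired = np.tile(label_total / n_folds, (n_folds, 1))
    remaining = set(labeled)
    fold_of: Dict[str, int] = {}
    fold_sizes = np.zeros(n_folds, dtype=int)
    cap = int(np.ceil(len(labeled) / n_folds))
    order = list(rng.permutation(len(labeled)))
    # visit proteins rarest-label first for tighter balance on sparse labels
    rarity = {
        p: min(label_total[k] for k in ann.labels_of(p)) for p in labeled
    }
    visit = sorted(remaining, key=lambda p: (rarity[p], p))
    for p in visit:
        ks = sorted(ann.labels_of(p), key=lambda k: label_total[k])
        k0 = ks[0]
        open_folds = [f for f in range(n_folds) if fold_sizes[f] < cap]
        f_best = max(
            open_folds,
            key=lambda f: (desired[f, k0], -fold_sizes[f], -f),
        )
        fold_of[p] = f_best
        fold_sizes[f_best] += 1
        for k in ann.labels_of(p):
            desired[f_best, k] -= 1.0
    return FoldAssignment(n_folds, fold_of, seed)


def average_precision(ranked_scores: Sequence[Tuple[float, bool]]) -> float:
    """AP of a scored list: mean precision at each positive's rank.

    Items are sorted by descending score with ties kept in stable input
    order.  Raises when the list has no positive.
    """
    items = sorted(
        range(len(ranked_scores)), key=lambda i: -ranked_scores[i][0]
    )  # stable: ties keep input order
    P = sum(1 for _, pos in ranked_scores if pos)
    if P == 0:
        raise ValueError("average precision undefined without positives")
    hits = 0
    total = 0.0
    for rank, i in enumerate(items, start=1):
        if ranked_scores[i][1]:
            hits += 1
            total += hits / rank
    return total / P


def f1_micro(
    calls: np.ndarray, truth: np.ndarray, k: int
) -> Tuple[float, float, float]:
    """Pooled precision, recall and F1 for label ``k``.

    Precision is 0 when nothing is called; recall is reported 0 (and the
    condition logged) when the label has no true positive.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth shapes differ")
    f = calls[:, k].astype(float)
    y = truth[:, k].astype(float)
    tp = float(y @ f)
    n_called = float(f.sum())
    n_pos = float(y.sum())
    p = tp / n_called if n_called > 0 else 0.0
    if n_pos > 0:
        r = tp / n_pos
    else:
        log.info("label column %d has no true positive; recall reported 0", k)
        r = 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def cross_validate(
    net: WeightedNetwork,
    ann: AnnotationSet,
    predictor: Predictor,
    folds: FoldAssignment,
    reweighter: Optional[Reweighter] = None,
    predictor_name: str = "",
) -> EvalReport:
    """K-fold evaluation with joint (atomic) masking of test proteins.

    Per fold, the test proteins are made uncharacterized (all labels hidden
    together), the network is optionally re-weighted from the training
    labels only, and the predictor runs on the masked annotation set.
    Scores and calls are collected for the masked proteins and pooled
    across folds; AP is computed per label on the pooled ranking (per-fold
    AP is reported as well) and MAP averages over labels with at least one
    pooled test positive.
    """
    K = ann.vocabulary.size
    labels = ann.vocabulary.labels
    pooled: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}  # pid -> (scores, calls)
    per_fold_ap = np.full((folds.n_folds, K), np.nan)

    for f in range(folds.n_folds):
        test_ids = [p for p in folds.members(f) if p in net.graph]
        masked = ann.mask(folds.members(f))
        run_net = reweighter(net, masked) if reweighter is not None else net
        try:
            sm = predictor(run_net, masked)
        except Exception as exc:
            raise RuntimeError(
                f"predictor {predictor_name or predictor!r} failed on fold {f}: {exc}"
            ) from exc
        row = {p: i for i, p in enumerate(sm.proteins)}
        fold_scores = []
        fold_truth = []
        for p in test_ids:
            if p not in row:
                continue
            i = row[p]
            pooled[p] = (sm.scores[i].copy(), sm.calls[i].copy())
            fold_scores.append(sm.scores[i])
            truth_vec = np.zeros(K)
            for k in ann.labels_of(p):
                truth_vec[k] = 1.0
            fold_truth.append(truth_vec)
        if fold_scores:
            fs = np.vstack(fold_scores)
            ft = np.vstack(fold_truth)
            for k in range(K):
                if ft[:, k].sum() > 0:
                    per_fold_ap[f, k] = average_precision(
                        [(fs[i, k], bool(ft[i, k])) for i in range(len(fs))]
                    )

    pids = sorted(pooled)  # protein-ID order: stable, reproducible ranking
    if not pids:
        raise ValueError("no labeled protein of the fold assignment is in the network")
    scores = np.vstack([pooled[p][0] for p in pids])
    calls = np.vstack([pooled[p][1] for p in pids])
    truth = np.zeros((len(pids), K))
    for i, p in enumerate(pids):
        for k in ann.labels_of(p):
            truth[i, k] = 1.0

    ap = np.full(K, np.nan)
    skipped: List[str] = []
    for k in range(K):
        if truth[:, k].sum() > 0:
            ap[k] = average_precision(
                [(scores[i, k], bool(truth[i, k])) for i in range(len(pids))]
            )
        else:
            skipped.append(labels[k])
    if skipped:
        log.info("MAP skips %d label(s) without pooled test positives", len(skipped))
    map_score = float(np.nanmean(ap))

    precision = np.zeros(K)
    recall = np.zeros(K)
    f1 = np.zeros(K)
    for k in range(K):
        precision[k], recall[k], f1[k] = f1_micro(calls, truth, k)

    return EvalReport(
        labels=labels,
        ap_per_label=ap,
        map_score=map_score,
        precision=precision,
        recall=recall,
        f1_per_label=f1,
        per_fold_ap=per_fold_ap,
        skipped_labels=tuple(skipped),
        folds=folds,
        predictor_name=predictor_name,
    )


def categorize(
    predicted: Iterable[int], reference: Iterable[int]
) -> PredictionCategory:
    """Audit one prediction against a reference label set.

    Empty prediction -> Unknown; exact match -> Correct; partial overlap ->
    PartialCorrect; disjoint -> Mismatch.  The four outcomes partition all
    (predicted, reference) pairs.
    """
    pred = frozenset(predicted)
    ref = frozenset(reference)
    if not pred:
        return PredictionCategory.UNKNOWN
    if pred == ref:
        return PredictionCategory.CORRECT
    if pred & ref:
        return PredictionCategory.PARTIAL_CORRECT
    return PredictionCategory.MISMATCH


def categorize_cohort(
    predictions: Mapping[str, FrozenSet[int]],
    references: Mapping[str, FrozenSet[int]],
) -> Dict[PredictionCategory, int]:
    """Tally audit categories over a cohort of proteins."""
    tally = {c: 0 for c in PredictionCategory}
    for pid, pred in predictions.items():
        tally[categorize(pred, references.get(pid, frozenset()))] += 1
    return tally
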