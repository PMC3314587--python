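"""AP-weighted fusion of the four base predictors.

The ensemble combines Majority, chi2, GenMultiCut and FunctionalFlow per
label: each base classifier's weight for label ``k`` is its cross-validated
average precision normalized over the four classifiers,

    w_ck = AP_k^c / sum_c AP_k^c,

and the fused confidence is the weighted vote of the base binary calls.  A
protein is assigned label ``k`` when the fused score exceeds the call
threshold (default 0.5, weighted-majority semantics); a protein with no
fused call is audited as Unknown downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import AnnotationSet, WeightedNetwork
from .evaluation import FoldAssignment, cross_validate, make_folds
from .predictors import (
    ScoreMatrix,
    chi2_predict,
    funflow_predict,
    gmc_predict,
    majority_predict,
)

__all__ = ["EnsembleModel", "fit_weights", "fuse", "run_ensemble", "BASE_NAMES"]

log = logging.getLogger(__name__)

BASE_NAMES: Tuple[str, str, str, str] = ("majority", "chi2", "gmc", "funflow")


@dataclass
class EnsembleModel:
    """Per-label fusion weights derived from base-classifier AP."""

    base_names: Tuple[str, ...]
    weights: np.ndarray  # (4, K), columns sum to 1
    source_ap: np.ndarray  # (4, K)


def fit_weights(ap_by_classifier: np.ndarray) -> EnsembleModel:
    """Normalize per-label AP into fusion weights (uniform on all-zero columns)."""
    ap = np.asarray(ap_by_classifier, dtype=float)
    if ap.ndim != 2 or ap.shape[0] != len(BASE_NAMES):
        raise ValueError(f"expected a {len(BASE_NAMES)} x K AP matrix, got {ap.shape}")
    if np.any(ap < 0):
        raise ValueError("AP values must be non-negative")
    if np.any(ap > 1):
        raise ValueError("AP values must be <= 1")
    col_sums = ap.sum(axis=0)
    weights = np.empty_like(ap)
    zero_cols = col_sums <= 0
    if zero_cols.any():
        log.info(
            "%d label(s) have all-zero AP; using uniform fusion weights",
            int(zero_cols.sum()),
        )
    weights[:, zero_cols] = 1.0 / len(BASE_NAMES)
    nz = ~zero_cols
    weights[:, nz] = ap[:, nz] / col_sums[nz]
    return EnsembleModel(BASE_NAMES, weights, ap)


def fuse(
    model: EnsembleModel,
    base_outputs: Sequence[ScoreMatrix],
    call_threshold: float = 0.5,
    use_normalized_scores: bool = False,
) -> ScoreMatrix:
    """Weighted per-label fusion of the base classifiers' outputs.

    By default the fused score is the weighted vote of binary calls (the
    four raw score scales — neighbor counts, chi-square statistics, cut
    indicators, flow units — are incommensurable); with
    ``use_normalized_scores`` the per-label min-max-normalized raw scores
    are fused instead.
    """
    if len(base_outputs) != len(model.base_names):
        raise ValueError("one ScoreMatrix per base classifier required")
    first = base_outputs[0]
    for sm in base_outputs[1:]:
        if sm.proteins != first.proteins or sm.vocabulary.labels != first.vocabulary.labels:
            raise ValueError("base outputs disagree on protein order or vocabulary")
    n, K = len(first.proteins), first.vocabulary.size
    fused = np.zeros((n, K))
    for c, sm in enumerate(base_outputs):
        if use_normalized_scores:
            s = sm.scores.astype(float)
            lo = s.min(axis=0, keepdims=True)
            rng = s.max(axis=0, keepdims=True) - lo
            with np.errstate(invalid="ignore", divide="ignore"):
                b = np.where(rng > 0, (s - lo) / rng, 0.0)
        else:
            b = sm.calls.astype(float)
        fused += model.weights[c][None, :] * b
    calls = (fused > call_threshold).astype(np.int8)
    return ScoreMatrix(list(first.proteins), first.vocabulary, fused, calls, "ensemble")


def _default_bases(
    seed: int,
    sigma: int = 1,
    d: int = 6,
    flow_threshold: float = 0.0,
    gmc_solver: str = "ilp",
) -> Dict[str, Callable[[WeightedNetwork, AnnotationSet], ScoreMatrix]]:
    return {
        "majority": lambda net, ann: majority_predict(net, ann, weighted=True),
        "chi2": lambda net, ann: chi2_predict(net, ann, sigma=sigma),
        "gmc": lambda net, ann: gmc_predict(net, ann, solver=gmc_solver, seed=seed),
        "funflow": lambda net, ann: funflow_predict(net, ann, d=d, threshold=flow_threshold),
    }


def run_ensemble(
    net: WeightedNetwork,
    ann: AnnotationSet,
    seed: int = 0,
    n_folds: int = 5,
    call_threshold: float = 0.5,
    reweighter=None,
    folds: Optional[FoldAssignment] = None,
    gmc_solver: str = "ilp",
    sigma: int = 1,
    d: int = 6,
) -> Tuple[ScoreMatrix, EnsembleModel, Dict[str, object]]:
    """Fit per-label AP weights by cross-validation, then predict U.

    The fusion weights are estimated from ``n_folds``-fold cross-validation
    on the labeled proteins and frozen before the base classifiers are rerun
    on the full annotation set to score the uncharacterized proteins.
    Returns the fused ScoreMatrix, the fitted model, and the per-base CV
    reports.
    """
    bases = _default_bases(seed, sigma=sigma, d=d, gmc_solver=gmc_solver)
    if folds is None:
        folds = make_folds(ann, n_folds=n_folds, seed=seed)
    K = ann.vocabulary.size
    ap = np.zeros((len(BASE_NAMES), K))
    reports: Dict[str, object] = {}
    for c, name in enumerate(BASE_NAMES):
        report = cross_validate(
            net, ann, bases[name], folds, reweighter=reweighter, predictor_name=name
        )
        reports[name] = report
        ap[c] = np.nan_to_num(report.ap_per_label, nan=0.0)
    model = fit_weights(ap)
    final_net = reweighter(net, ann) if reweighter is not None else net
    outputs = [bases[name](final_net, ann) for name in BASE_NAMES]
    fused = fuse(model, outputs, call_threshold=call_threshold)
    return fused, model, reports
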