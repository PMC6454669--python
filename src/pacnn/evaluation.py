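"""Classification and drug-rediscovery evaluation.

Covers precision / recall / F-score from confusion counts, stratified
ten-fold cross-validation over labelled triplet features, the rediscovery
metrics (mean rank and hit@10 of the known therapeutic drug among 100
candidates, with *not found* drugs excluded from both), and the feature
ablations that replace PRA path probabilities with random or binary values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .scoring import CandidateRanking

__all__ = [
    "ConfusionCounts",
    "PRFResult",
    "RediscoveryReport",
    "precision_recall_f",
    "confusion_from_predictions",
    "cross_validate",
    "ten_fold_cv",
    "rediscovery_eval",
    "ablate_features",
    "feature_ablation",
    "HIT_AT_K",
]

HIT_AT_K = 10


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PRFResult:
    precision: float
    recall: float
    f_score: float
    degenerate: bool = False  # some 0/0 denominator was coerced to 0


def precision_recall_f(c: ConfusionCounts) -> PRFResult:
    """P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R).

    A zero denominator yields 0 for that metric with the ``degenerate``
    flag set, so cross-validation aggregation never aborts on an empty
    prediction class.
    """
    degenerate = False
    if c.tp + c.fp == 0:
        p, degenerate = 0.0, True
    else:
        p = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        r, degenerate = 0.0, True
    else:
        r = c.tp / (c.tp + c.fn)
    if p + r == 0:
        f, degenerate = 0.0, True
    else:
        f = 2 * p * r / (p + r)
    return PRFResult(p, r, f, degenerate)


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    factory: Callable[[], object],
    seed: int,
    n_splits: int = 10,
) -> dict:
    """Stratified k-fold cross-validation of a fit/predict estimator.

    ``factory`` returns a fresh estimator with ``fit(X, y)`` and
    ``predict(X)`` for each fold.  Returns per-fold P/R/F and their
    arithmetic means.  Fold assignment is seeded and stratified so class
    proportions are preserved in every fold.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int).ravel()
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_splits:
        raise ValueError(
            f"need at least {n_splits} examples per class, have {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = []
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        est = factory()
        est.fit(X[tr], y[tr])
        y_pred = est.predict(X[te])
        prf = precision_recall_f(confusion_from_predictions(y[te], y_pred))
        folds.append(
            {
                "fold": fold_idx,
                "n_test": len(te),
                "precision": prf.precision,
                "recall": prf.recall,
                "f_score": prf.f_score,
                "degenerate": prf.degenerate,
            }
        )
    return {
        "folds": folds,
        "precision": float(np.mean([f["precision"] for f in folds])),
        "recall": float(np.mean([f["recall"] for f in folds])),
        "f_score": float(np.mean([f["f_score"] for f in folds])),
    }


def ten_fold_cv(
    X: np.ndarray, y: np.ndarray, factory: Callable[[], object], seed: int
) -> dict:
    """The standard ten-fold protocol: mean P/R/F over 10 stratified folds."""
    return cross_validate(X, y, factory, seed, n_splits=10)


@dataclass
class RediscoveryReport:
    """Per-disease known-drug ranks plus the aggregate rediscovery metrics."""

    ranks: dict[str, Optional[float]] = field(default_factory=dict)
    mean_rank: Optional[float] = None  # over found known drugs; None if none found
    hit_at_10: Optional[float] = None  # percentage in [0, 100]; None if none found
    not_found: int = 0

    @property
    def n_found(self) -> int:
        return sum(1 for r in self.ranks.values() if r is not None)


def rediscovery_eval(
    rankings: Mapping[str, CandidateRanking],
    known: Mapping[str, str],
) -> RediscoveryReport:
    """Mean rank and hit@10 of the known therapeutic drug per disease.

    A known drug that is not found (all its cases filtered, or unreachable
    for the random-walk baseline) is excluded from both the mean rank and
    the hit@10 denominator and counted in ``not_found``.
    """
    ranks: dict[str, Optional[float]] = {}
    for disease, drug in known.items():
        if disease not in rankings:
            raise KeyError(f"no ranking supplied for disease {disease!r}")
        ranks[disease] = rankings[disease].rank_of(drug)
    found = [r for r in ranks.values() if r is not None]
    report = RediscoveryReport(ranks=ranks, not_found=len(ranks) - len(found))
    if found:
        report.mean_rank = float(np.mean(found))
        report.hit_at_10 = float(
            100.0 * np.mean([r <= HIT_AT_K for r in found])
        )
    return report


AblationMode = Literal["pra", "random", "binary"]


def ablate_features(
    X: np.ndarray, mode: AblationMode, seed: int = 0
) -> np.ndarray:
    """Replace nonzero PRA feature entries per the ablation mode.

    ``random``: nonzero entries become Uniform(0,1) draws (seeded);
    ``binary``: nonzero entries become 1; ``pra``: untouched copy.  The
    zero pattern (which relation paths connect the pair at all) is always
    preserved — the ablations destroy only the walk-probability magnitudes.
    """
    X = np.array(X, dtype=np.float64, copy=True)
    if mode == "pra":
        return X
    mask = X != 0
    if mode == "binary":
        X[mask] = 1.0
    elif mode == "random":
        rng = np.random.default_rng(seed)
        X[mask] = rng.uniform(0.0, 1.0, size=int(mask.sum()))
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    return X


def feature_ablation(
    X: np.ndarray,
    y: np.ndarray,
    factory: Callable[[], object],
    mode: AblationMode,
    seed: int,
    n_splits: int = 10,
) -> dict:
    """Cross-validated P/R/F with the chosen feature ablation applied."""
    Xa = ablate_features(X, mode, seed)
    return cross_validate(Xa, y, factory, seed, n_splits=n_splits)
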