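"""Classifier evaluation: LOOCV with optional nested model selection,
confusion metrics, 3-fold ROC/AUC, Spearman rank correlation, and
Fisher's-exact overlap tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist  # noqa: F401  (re-export convenience)
from scipy.stats import hypergeom, rankdata
from sklearn.model_selection import StratifiedKFold

from stemsvm.classify import train_svm


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    """Derived rates; a component is None when its denominator is zero."""

    accuracy: float
    tpr: float | None
    fpr: float | None
    precision: float | None
    recall: float | None
    f1: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(c: ConfusionCounts) -> EvalMetrics:
    """Accuracy, TPR/recall, FPR, precision, and F1 from raw counts."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    return EvalMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        tpr=_ratio(c.tp, c.tp + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


@dataclass
class LoocvResult:
    confusion: ConfusionCounts
    predictions: pd.DataFrame  # gene_id, score, true, predicted, chosen
    accuracy: float


def _loocv_scores(K: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Held-out decision score for every sample under plain LOOCV."""
    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold lost one class entirely")
        model = train_svm(K[np.ix_(tr, tr)], y[tr], C=C, validate=False)
        scores[i] = model.decision(K[i : i + 1, tr])[0]
    return scores


def loocv(
    candidates: Sequence[tuple[str, np.ndarray]],
    y: np.ndarray,
    C: float = 1.0,
    nested: bool = True,
    gene_ids=None,
) -> LoocvResult:
    """Leave-one-out CV over precomputed Gram candidates.

    ``candidates`` is an ordered list of (name, full n x n Gram). With a
    single candidate the protocol is plain LOOCV. With several and
    ``nested=True`` each outer fold selects the candidate maximizing an
    inner LOOCV accuracy on its n-1 training genes (ties -> earliest
    candidate, so pass sigma grids in ascending order). ``nested=False``
    reproduces the single-loop reading: the candidate with the best
    plain LOOCV accuracy is selected and its own LOOCV counts reported.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 samples for LOOCV")
    if min(np.sum(y == 1), np.sum(y == -1)) < 2:
        raise ValueError("need at least 2 samples per class")
    if not candidates:
        raise ValueError("no kernel candidates supplied")
    names = [name for name, _ in candidates]
    grams = [np.asarray(K, dtype=float) for _, K in candidates]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]

    if len(grams) == 1:
        scores = _loocv_scores(grams[0], y, C)
        chosen = [names[0]] * n
    elif not nested:
        per_cand = [_loocv_scores(K, y, C) for K in grams]
        accs = [np.mean((s > 0) == (y == 1)) for s in per_cand]
        best = int(np.argmax(accs))
        scores = per_cand[best]
        chosen = [names[best]] * n
    else:
        scores = np.empty(n)
        chosen = []
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            accs = []
            for K in grams:
                inner = _loocv_scores(K[np.ix_(tr, tr)], y[tr], C)
                accs.append(np.mean((inner > 0) == (y[tr] == 1)))
            best = int(np.argmax(accs))
            chosen.append(names[best])
            model = train_svm(
                grams[best][np.ix_(tr, tr)], y[tr], C=C, validate=False
            )
            scores[i] = model.decision(grams[best][i : i + 1, tr])[0]

    pred = np.where(scores > 0, 1, -1)
    confusion = confusion_from_predictions(y, pred)
    return LoocvResult(
        confusion=confusion,
        predictions=pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "score": scores,
                "true": y,
                "predicted": pred,
                "chosen": chosen,
            }
        ),
        accuracy=confusion_metrics(confusion).accuracy,
    )


def roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Staircase ROC by sweeping the decision threshold (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], y[order]
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(lab[j] == 1)
            fp += int(lab[j] == -1)
            j += 1
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    return np.asarray(fpr), np.asarray(tpr)


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


@dataclass
class ROCResult:
    folds: list[dict]  # each: fpr, tpr, auc, test_index
    auc_mean: float


def roc_threefold(
    K: np.ndarray, y: np.ndarray, C: float = 1.0, seed: int = 0, n_folds: int = 3
) -> ROCResult:
    """Stratified 3-fold ROC: train on two folds, sweep scores on the third."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < 2 * n_folds:
        raise ValueError("too few samples for the fold count")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a fold is missing one class; stratification failed")
        model = train_svm(K[np.ix_(tr, tr)], y[tr], C=C, validate=False)
        scores = model.decision(K[np.ix_(te, tr)])
        fpr, tpr = roc_points(scores, y[te])
        folds.append(
            {"fpr": fpr, "tpr": tpr, "auc": auc_trapezoid(fpr, tpr), "test_index": te}
        )
    return ROCResult(folds=folds, auc_mean=float(np.mean([f["auc"] for f in folds])))


def rank_correlation(u: Sequence[float], v: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average ranks."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) != len(v):
        raise ValueError("inputs must have equal length")
    if len(u) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(u == u[0]) or np.all(v == v[0]):
        raise ValueError("rank correlation undefined for a constant input")
    ru, rv = rankdata(u), rankdata(v)
    return float(np.corrcoef(ru, rv)[0, 1])


def fisher_overlap(
    listA: Sequence[str], listB: Sequence[str], universe_size: int
) -> float:
    """Upper-tail hypergeometric p for the observed overlap of two sets."""
    sa, sb = set(listA), set(listB)
    if len(sa | sb) > universe_size:
        raise ValueError("universe smaller than the union of the lists")
    overlap = len(sa & sb)
    return float(hypergeom.sf(overlap - 1, universe_size, len(sa), len(sb)))
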