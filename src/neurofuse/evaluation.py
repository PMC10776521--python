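"""ROC/AUC and accuracy metrics, cross-fold ROC averaging, model comparison.

AUC is the Mann-Whitney concordance probability (ties count one half),
computed from the trapezoidal area under the empirical ROC curve.  Fold
curves are averaged vertically — TPR interpolated on a fixed FPR grid — while
the summary AUC mean/SD always comes from the per-fold AUCs, not from the
averaged curve.  Two models sharing the same outer folds are compared with a
paired permutation test on their pooled out-of-fold scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def auc_roc(scores, labels) -> ROCCurve:
    """Empirical ROC curve and its trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    return float(np.mean((scores > threshold).astype(float) == labels))


def mean_roc(fold_curves: list[ROCCurve]) -> dict:
    """Vertical average of fold ROC curves on a fixed FPR grid.

    Returns the grid, the pointwise mean/SD TPR, and the mean and sample SD
    of the per-fold AUCs.
    """
    if len(fold_curves) < 2:
        raise ValueError("need at least two fold curves")
    tprs = []
    for c in fold_curves:
        # ROC points start at (0,0); interpolation is well defined on [0,1]
        tprs.append(np.interp(FPR_GRID, c.fpr, c.tpr))
    tprs = np.array(tprs)
    aucs = np.array([c.auc for c in fold_curves])
    return {
        "fpr": FPR_GRID.copy(),
        "tpr_mean": tprs.mean(axis=0),
        "tpr_sd": tprs.std(axis=0, ddof=1),
        "auc_mean": float(aucs.mean()),
        "auc_sd": float(aucs.std(ddof=1)),
        "fold_aucs": aucs,
    }


def compare_models(results_a, results_b, n_permutations: int = 1000, seed: int = 0) -> dict:
    """Paired permutation test for AUC difference between two CV results.

    Both results must come from the same outer folds (same held-out subjects
    in the same order).  Under the null the two models' scores for a subject
    are exchangeable: each permutation swaps the score assignment per subject
    and recomputes the pooled-AUC difference.  One-sided p for A > B.
    """
    folds_a, folds_b = results_a.folds, results_b.folds
    if len(folds_a) != len(folds_b) or any(
        list(fa.test_ids) != list(fb.test_ids) for fa, fb in zip(folds_a, folds_b)
    ):
        raise ValueError("fold structures differ between the two results")
    sa = np.concatenate([f.scores for f in folds_a])
    sb = np.concatenate([f.scores for f in folds_b])
    y = np.concatenate([f.labels for f in folds_a])
    obs = auc_roc(sa, y).auc - auc_roc(sb, y).auc
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        swap = rng.random(len(y)) < 0.5
        pa = np.where(swap, sb, sa)
        pb = np.where(swap, sa, sb)
        if auc_roc(pa, y).auc - auc_roc(pb, y).auc >= obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {"auc_diff": float(obs), "p_value": float(p), "n_permutations": n_permutations}
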