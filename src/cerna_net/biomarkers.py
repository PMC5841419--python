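"""lncRNA biomarker panel selection.

Three stages mirror the classification workflow of the pipeline:

1. *Iterative random-forest elimination.*  A bagged ensemble of
   decision trees is fitted; each feature's importance is the mean
   accuracy drop on per-tree out-of-bag samples after permuting that
   feature (one permutation per feature per tree).  Each iteration
   discards the max(1, floor(k/3)) least-important features until at
   most ``target_k`` remain.
2. *Exhaustive subset evaluation.*  All 2^k - 1 non-empty subsets of
   the retained features (guarded at k <= 20) are scored by an RBF
   support-vector machine under leave-one-out cross-validation, with
   per-fold standardization fitted on the training fold only.
3. *Panel choice.*  The subset with the highest LOOCV accuracy wins;
   ties break by higher AUC, then fewer features, then lexicographic
   order.  AUC is the Mann-Whitney statistic of the pooled held-out
   decision values, with half credit for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

DEFAULT_KERNEL = {"kernel": "rbf", "C": 1.0, "gamma": "scale", "tol": 1e-6}


@dataclass
class RFSelectionTrace:
    """Per-iteration record of the random-forest elimination."""

    seed: int
    iterations: list[dict] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return list(self.iterations[-1]["retained"])


def _check_xy(x: pd.DataFrame, labels: pd.Series):
    labels = labels.reindex(x.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.to_numpy(dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    return x.to_numpy(dtype=float).T, y  # samples x features


def _oob_permutation_importance(
    xs: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_trees: int
) -> np.ndarray:
    """Mean OOB accuracy drop per feature over a bagged tree ensemble."""
    n, k = xs.shape
    drops = np.zeros((n_trees, k))
    used = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0 or len(np.unique(y[idx])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(xs[idx], y[idx])
        base = (tree.predict(xs[oob]) == y[oob]).mean()
        used[t] = True
        for j in range(k):
            perm = xs[oob].copy()
            perm[:, j] = perm[rng.permutation(len(oob)), j]
            drops[t, j] = base - (tree.predict(perm) == y[oob]).mean()
    if not used.any():
        raise ValueError("no usable out-of-bag samples; too few samples")
    return drops[used].mean(axis=0)


def rf_iterative_selection(
    expr_lnc: pd.DataFrame,
    labels: pd.Series,
    target_k: int,
    seed: int,
    n_trees: int = 300,
) -> RFSelectionTrace:
    """Iteratively discard the least important features until <= target_k.

    ``expr_lnc`` is features x samples.  Deterministic given ``seed``.
    When ``target_k`` is at least the initial feature count a single
    trivial iteration records all features.
    """
    if expr_lnc.shape[0] < 2:
        raise ValueError("need at least 2 features")
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    xs_all, y = _check_xy(expr_lnc, labels)
    features = list(expr_lnc.index)
    rng = np.random.default_rng(seed)
    trace = RFSelectionTrace(seed=seed)
    if target_k >= len(features):
        trace.iterations.append(
            {"retained": tuple(features), "importance": {}, "discarded": ()}
        )
        return trace
    while len(features) > target_k:
        current = list(features)
        cols = [expr_lnc.index.get_loc(f) for f in current]
        imp = _oob_permutation_importance(xs_all[:, cols], y, rng, n_trees)
        n_drop = max(1, len(current) // 3)
        order = sorted(zip(imp, current))  # ascending importance, id tiebreak
        dropped = tuple(f for _, f in order[:n_drop])
        features = [f for f in current if f not in dropped]
        trace.iterations.append(
            {
                "retained": tuple(features),
                "importance": {f: float(i) for i, f in zip(imp, current)},
                "discarded": dropped,
            }
        )
    return trace


def enumerate_subsets(features) -> list[tuple[str, ...]]:
    """All 2^k - 1 non-empty subsets, ordered by size then lexicographic."""
    feats = sorted(features)
    if not 1 <= len(feats) <= 20:
        raise ValueError("subset enumeration limited to 1..20 features")
    out: list[tuple[str, ...]] = []
    for size in range(1, len(feats) + 1):
        out.extend(combinations(feats, size))
    return out


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic U / (n1 * n0), ties half-credited."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class PanelResult:
    """LOOCV outcome of one feature subset."""

    features: tuple[str, ...]
    accuracy: float
    auc: float
    scores: pd.Series  # per-sample held-out decision values
    predictions: pd.Series
    confusion: dict[str, int]
    degenerate_folds: int = 0


def loocv_svm(
    expr_subset: pd.DataFrame,
    labels: pd.Series,
    kernel_cfg: dict | None = None,
) -> PanelResult:
    """Leave-one-out SVM evaluation of one feature subset.

    Features are standardized with training-fold statistics only.  A
    training fold that loses one class predicts the remaining
    (majority) class for its held-out sample and is counted in
    ``degenerate_folds``.
    """
    cfg = dict(DEFAULT_KERNEL, **(kernel_cfg or {}))
    xs, y = _check_xy(expr_subset, labels)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 samples for LOOCV")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    degenerate = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if len(np.unique(y_tr)) < 2:
            cls = int(y_tr[0])
            preds[i] = cls
            scores[i] = math.inf if cls == 1 else -math.inf
            degenerate += 1
            continue
        scaler = StandardScaler().fit(xs[mask])
        clf = SVC(**cfg)
        clf.fit(scaler.transform(xs[mask]), y_tr)
        xt = scaler.transform(xs[i : i + 1])
        scores[i] = float(clf.decision_function(xt)[0])
        preds[i] = int(clf.predict(xt)[0])
    accuracy = float((preds == y).mean())
    confusion = {
        "tp": int(((preds == 1) & (y == 1)).sum()),
        "fp": int(((preds == 1) & (y == 0)).sum()),
        "tn": int(((preds == 0) & (y == 0)).sum()),
        "fn": int(((preds == 0) & (y == 1)).sum()),
    }
    return PanelResult(
        features=tuple(expr_subset.index),
        accuracy=accuracy,
        auc=roc_auc(scores, y),
        scores=pd.Series(scores, index=expr_subset.columns),
        predictions=pd.Series(preds, index=expr_subset.columns),
        confusion=confusion,
        degenerate_folds=degenerate,
    )


def select_optimal_panel(
    expr_lnc: pd.DataFrame,
    labels: pd.Series,
    target_k: int,
    seed: int,
    kernel_cfg: dict | None = None,
    n_trees: int = 300,
) -> tuple[PanelResult, pd.DataFrame, RFSelectionTrace]:
    """Full panel search: RF elimination, exhaustive subsets, LOOCV SVM.

    Returns the winning panel, the ranked table of every evaluated
    subset (accuracy, AUC, size), and the elimination trace.
    """
    trace = rf_iterative_selection(expr_lnc, labels, target_k, seed)
    retained = trace.retained
    subsets = enumerate_subsets(retained)
    results: list[PanelResult] = []
    rows = []
    for sub in subsets:
        r = loocv_svm(expr_lnc.loc[list(sub)], labels, kernel_cfg)
        results.append(r)
        rows.append(
            {
                "subset": "+".join(sub),
                "n_features": len(sub),
                "accuracy": r.accuracy,
                "auc": r.auc,
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(results)),
        key=lambda i: (
            -results[i].accuracy,
            -results[i].auc,
            len(results[i].features),
            results[i].features,
        ),
    )
    best = results[order[0]]
    table = table.iloc[order].reset_index(drop=True)
    return best, table, trace


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) from held-out scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    p = (labels == 1).sum()
    n = (labels == 0).sum()
    rows = [{"fpr": 0.0, "tpr": 0.0, "threshold": math.inf}]
    tp = fp = 0
    for i in range(len(y)):
        tp += y[i] == 1
        fp += y[i] == 0
        if i + 1 < len(y) and s[i + 1] == s[i]:
            continue
        rows.append({"fpr": fp / n, "tpr": tp / p, "threshold": float(s[i])})
    return pd.DataFrame(rows)
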