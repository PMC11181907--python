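"""Repeated stratified cross-validation and the performance-metric suite.

Implements the six classification metrics plus RMSE from first principles
(so they can be cross-checked against independent oracles), repeated
stratified fold plans, profit-matrix threshold analysis, probability-decile
consistency binning, and a multi-learner screening harness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold

from .dtm import DocumentTermMatrix
from .modeling import BoosterConfig, _check_labels, _make_estimator

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fold plans


@dataclass
class FoldPlan:
    """R repeated stratified k-fold partitions of one corpus.

    ``assignment[r, i]`` is the fold index (0..k-1) of document i in set r.
    """

    k: int
    R: int
    seed: int
    assignment: np.ndarray

    @property
    def n_docs(self) -> int:
        return self.assignment.shape[1]

    def split(self, r: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, validation_indices) for one set and fold."""
        mask = self.assignment[r] == fold
        return np.flatnonzero(~mask), np.flatnonzero(mask)

    def max_fold_jaccard(self) -> float:
        """Max Jaccard overlap between folds of different sets (orthogonality
        diagnostic — lower means the repeated partitions share less)."""
        best = 0.0
        folds = [
            [set(np.flatnonzero(self.assignment[r] == f)) for f in range(self.k)]
            for r in range(self.R)
        ]
        for r1 in range(self.R):
            for r2 in range(r1 + 1, self.R):
                for a in folds[r1]:
                    for b in folds[r2]:
                        inter = len(a & b)
                        if inter:
                            best = max(best, inter / len(a | b))
        return best


def make_fold_plan(labels, k: int = 5, R: int = 10, seed: int = 0) -> FoldPlan:
    """R independent stratified k-fold partitions with derived seeds."""
    labels = _check_labels(labels)
    for cls in (0, 1):
        n_cls = int((labels == cls).sum())
        if n_cls < k:
            raise ValueError(
                f"class {cls} has {n_cls} documents, fewer than k={k} folds"
            )
    rng = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(R)]
    assignment = np.empty((R, len(labels)), dtype=np.int64)
    for r in range(R):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=child_seeds[r])
        for f, (_, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignment[r, va] = f
    plan = FoldPlan(k=k, R=R, seed=seed, assignment=assignment)
    if R > 1:
        logger.info("fold plan: max inter-set fold Jaccard %.3f", plan.max_fold_jaccard())
    return plan


# ---------------------------------------------------------------------------
# metric primitives


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Counts with predicted 1 iff score >= threshold (ties round up)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    pred = (scores >= threshold).astype(np.int64)
    return ConfusionCounts(
        TP=int(((pred == 1) & (labels == 1)).sum()),
        FP=int(((pred == 1) & (labels == 0)).sum()),
        TN=int(((pred == 0) & (labels == 0)).sum()),
        FN=int(((pred == 0) & (labels == 1)).sum()),
    )


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    """ACC, MCC, sensitivity, specificity, precision.

    Zero-denominator metrics are reported as NaN (undefined), never 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(fn + tn)
    )
    return {
        "ACC": (tp + tn) / c.total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "MCC": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan"),
    }


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """ROC points (FPR, TPR) at every distinct threshold, by descending score."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    distinct = np.flatnonzero(np.diff(s, append=-np.inf))
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    thr = np.concatenate([[np.inf], s[distinct]])
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def roc_auc(scores, labels, return_curve: bool = False):
    """AUC by trapezoidal integration over the ROC curve.

    Tied scores land on one ROC vertex, so the trapezoid contributes 1/2
    per tied positive-negative pair (rank-sum equivalence).
    """
    curve = roc_curve_points(scores, labels)
    auc = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    if return_curve:
        return auc, curve
    return auc


def rmse(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((scores - labels) ** 2)))


def score_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """All seven metrics for one score vector."""
    out = metrics_from_confusion(confusion(scores, labels, threshold))
    out["AUC"] = roc_auc(scores, labels)
    out["RMSE"] = rmse(scores, labels)
    return out


def corpus_summary(labels) -> dict[str, float]:
    """Class-balance summary: counts, fraction, and rounded percentage."""
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    if n == 0:
        raise ValueError("empty label vector")
    n_pos = int((labels == 1).sum())
    return {
        "n_docs": n,
        "n_positive": n_pos,
        "n_negative": n - n_pos,
        "positive_fraction": n_pos / n,
        "positive_percent": round(100.0 * n_pos / n),
    }


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class MetricsReport:
    """Per-fold metrics and their mean/std summary, train vs validation."""

    per_fold: pd.DataFrame  # columns: set, fold, split, <metrics...>
    summary: pd.DataFrame  # index: split; columns: <metric>_mean, <metric>_std

    def mean(self, metric: str, split: str = "validation") -> float:
        return float(self.summary.loc[split, f"{metric}_mean"])


_METRICS = ["ACC", "AUC", "MCC", "RMSE", "sensitivity", "specificity", "precision"]


def _summarize(per_fold: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for split, grp in per_fold.groupby("split"):
        row = {}
        for m in _METRICS:
            row[f"{m}_mean"] = float(grp[m].mean())
            row[f"{m}_std"] = float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0
        rows[split] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def cross_validate(
    dtm: DocumentTermMatrix,
    labels,
    config: BoosterConfig | None = None,
    plan: FoldPlan | None = None,
    threshold: float = 0.5,
) -> tuple[np.ndarray, MetricsReport]:
    """Repeated stratified k-fold CV of the boosted classifier.

    Returns out-of-fold scores, one row per fold set (shape (R, n_docs)),
    and a MetricsReport aggregating per-fold training and validation metrics.
    """
    config = config or BoosterConfig()
    labels = _check_labels(labels)
    if plan is None:
        plan = make_fold_plan(labels, seed=config.seed)
    if plan.n_docs != dtm.weights.shape[0]:
        raise ValueError("fold plan does not cover the DTM rows")
    X = sp.csr_matrix(dtm.weights)
    oof = np.full((plan.R, plan.n_docs), np.nan)
    rows = []
    for r in range(plan.R):
        for f in range(plan.k):
            tr, va = plan.split(r, f)
            est = _make_estimator(config)
            try:
                est.fit(X[tr], labels[tr])
            except Exception as exc:  # pragma: no cover - context passthrough
                raise RuntimeError(f"training failed in set {r}, fold {f}: {exc}")
            p_tr = est.predict_proba(X[tr])[:, 1]
            p_va = est.predict_proba(X[va])[:, 1]
            oof[r, va] = p_va
            rows.append(
                {"set": r, "fold": f, "split": "training"}
                | score_metrics(p_tr, labels[tr], threshold)
            )
            rows.append(
                {"set": r, "fold": f, "split": "validation"}
                | score_metrics(p_va, labels[va], threshold)
            )
    per_fold = pd.DataFrame(rows)
    return oof, MetricsReport(per_fold=per_fold, summary=_summarize(per_fold))


# ---------------------------------------------------------------------------
# threshold and consistency analyses


def profit_analysis(
    scores, labels, thresholds: tuple[float, ...] = (0.25, 0.5, 0.75)
) -> pd.DataFrame:
    """Misclassification counts per probability threshold.

    FN counts positives pushed below the threshold (the costlier clinical
    error); FP counts negatives at or above it.  By construction FN is
    non-decreasing and FP non-increasing in the threshold.
    """
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0, 1]")
    rows = []
    for t in sorted(thresholds):
        c = confusion(scores, labels, t)
        rows.append(
            {
                "threshold": t,
                "n_predicted_positive": c.TP + c.FP,
                "FN": c.FN,
                "FP": c.FP,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConsistencyReport:
    """Agreement between rounded-up predictions and labels, by decile bin."""

    overall: float
    bins: pd.DataFrame  # columns: lo, hi, count, consistent, fraction

    @property
    def inconsistency(self) -> float:
        return 1.0 - self.overall


def consistency_report(scores, labels, threshold: float = 0.5) -> ConsistencyReport:
    """Consistent iff |roundup(score) - label| = 0; binned into deciles."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    pred = (scores >= threshold).astype(np.int64)
    consistent = pred == labels
    bin_idx = np.clip((scores * 10).astype(int), 0, 9)
    rows = []
    for b in range(10):
        mask = bin_idx == b
        n = int(mask.sum())
        n_ok = int(consistent[mask].sum())
        rows.append(
            {
                "lo": b / 10,
                "hi": (b + 1) / 10,
                "count": n,
                "consistent": n_ok,
                "fraction": n_ok / n if n else float("nan"),
            }
        )
    overall = float(consistent.mean()) if len(scores) else float("nan")
    return ConsistencyReport(overall=overall, bins=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# model screening


def _screen_families(seed: int) -> dict[str, object]:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "boosted_tree": None,  # handled separately (inner-CV iteration pick)
        "random_forest": RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "neural_net": make_pipeline(
            StandardScaler(with_mean=False),
            MLPClassifier(
                hidden_layer_sizes=(16,), max_iter=500, random_state=seed
            ),
        ),
        "svm": make_pipeline(StandardScaler(with_mean=False), SVC(random_state=seed)),
    }


def screen_models(
    dtm: DocumentTermMatrix,
    labels,
    k: int = 10,
    L: int = 5,
    seed: int = 0,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Nested-CV screening of learner families (outer k folds, inner L).

    The boosted-tree family picks its iteration count by inner L-fold CV on
    each outer training set; the other families use library defaults.
    Returns mean held-out AUC per family.
    """
    labels = _check_labels(labels)
    X = sp.csr_matrix(dtm.weights)
    available = _screen_families(seed)
    families = families or list(available)
    unknown = [f for f in families if f not in available]
    if unknown:
        raise ValueError(f"unknown model families: {unknown}")
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    outer_splits = list(outer.split(X, labels))
    rows = []
    for fam in families:
        fold_aucs = []
        for tr, va in outer_splits:
            if fam == "boosted_tree":
                inner_plan = make_fold_plan(labels[tr], k=L, R=1, seed=seed)
                from .modeling import iteration_history, select_iterations

                sub = DocumentTermMatrix(
                    doc_ids=[dtm.doc_ids[i] for i in tr],
                    terms=list(dtm.terms),
                    weights=sp.csr_matrix(X[tr]),
                    n_docs=dtm.n_docs,
                    doc_freq=dtm.doc_freq,
                )
                cfg = BoosterConfig(seed=seed)
                hist = iteration_history(
                    sub, labels[tr], cfg, inner_plan, max_iterations=cfg.iterations
                )
                cfg = cfg.replace(iterations=select_iterations(hist))
                est = _make_estimator(cfg)
                est.fit(X[tr], labels[tr])
                scores = est.predict_proba(X[va])[:, 1]
            else:
                est = available[fam]
                import sklearn.base

                est = sklearn.base.clone(est)
                est.fit(X[tr], labels[tr])
                if hasattr(est, "predict_proba"):
                    scores = est.predict_proba(X[va])[:, 1]
                else:
                    scores = est.decision_function(X[va])
            fold_aucs.append(roc_auc(scores, labels[va]))
        rows.append({"family": fam, "validation_auc": float(np.mean(fold_aucs))})
    return pd.DataFrame(rows)
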