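"""Gradient-boosted classification: training, iteration selection, autotune,
and splits/gain/cover importance.

Tree induction is delegated to scikit-learn's gradient boosting; this
module owns the configuration surface, iteration-history-based selection,
Latin-hypercube autotuning, and importance accounting extracted from the
fitted trees.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import qmc, spearmanr
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import log_loss

from .dtm import CountMatrix, DocumentTermMatrix

logger = logging.getLogger(__name__)

#: default value and tuning range per hyperparameter
DEFAULTS_AND_RANGES: dict[str, tuple[float, float, float]] = {
    "max_depth": (3, 1, 7),
    "subsample": (1.0, 0.5, 1.0),
    "colsample_bytree": (1.0, 0.5, 1.0),
    "min_child_weight": (1.0, 1.0, 3.0),
    "alpha": (0.0, 0.0, 0.5),
    "lambda_": (1.0, 0.0, 2.0),
    "learning_rate": (0.1, 0.05, 0.2),
    "iterations": (30, 20, 50),
}

_INTEGER_PARAMS = {"max_depth", "iterations"}


@dataclass(frozen=True)
class BoosterConfig:
    """Hyperparameters of the boosted binary-logistic classifier.

    ``alpha``/``lambda_`` (L1/L2 leaf penalties) are accepted for interface
    compatibility but are not supported by the scikit-learn backend; they
    are recorded and ignored at fit time.
    """

    max_depth: int = 3
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    min_child_weight: float = 1.0
    alpha: float = 0.0
    lambda_: float = 1.0
    learning_rate: float = 0.1
    iterations: int = 30
    seed: int = 0

    def replace(self, **kw) -> "BoosterConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BoosterConfig":
        return cls(**d)


def default_ranges() -> dict[str, tuple[float, float]]:
    return {k: (lo, hi) for k, (_, lo, hi) in DEFAULTS_AND_RANGES.items()}


def _make_estimator(config: BoosterConfig, n_estimators: int | None = None):
    if config.alpha != 0.0 or config.lambda_ != 1.0:
        logger.debug(
            "alpha/lambda penalties (%s/%s) are not supported by the "
            "sklearn backend and are ignored",
            config.alpha,
            config.lambda_,
        )
    max_features = (
        None if config.colsample_bytree >= 1.0 else config.colsample_bytree
    )
    return GradientBoostingClassifier(
        loss="log_loss",
        n_estimators=n_estimators or config.iterations,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        subsample=config.subsample,
        max_features=max_features,
        min_samples_leaf=max(1, round(config.min_child_weight)),
        random_state=config.seed,
    )


@dataclass
class TrainedModel:
    """Fitted booster plus everything needed to score new documents."""

    estimator: GradientBoostingClassifier
    vocabulary: list[str]
    config: BoosterConfig
    threshold: float = 0.5
    n_docs: int = 0
    doc_freq: dict[str, int] = field(default_factory=dict)

    def predict_proba(self, X: sp.spmatrix | np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.vocabulary):
            raise ValueError(
                f"feature count {X.shape[1]} != vocabulary size "
                f"{len(self.vocabulary)}"
            )
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class IterationHistory:
    """Per-iteration log-loss curves: shape (n_sets, k, n_iterations)."""

    train_curves: np.ndarray
    valid_curves: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.train_curves.shape[2]

    @property
    def mean_valid(self) -> np.ndarray:
        return self.valid_curves.mean(axis=(0, 1))

    @property
    def mean_train(self) -> np.ndarray:
        return self.train_curves.mean(axis=(0, 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_iterations + 1),
                "train_loss": self.mean_train,
                "valid_loss": self.mean_valid,
            }
        )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate labels: only one class present")
    return labels


def train_booster(
    dtm: DocumentTermMatrix, labels, config: BoosterConfig | None = None
) -> TrainedModel:
    """Fit the boosted classifier on a TF-IDF matrix.

    The training corpus's size and per-term document frequencies are frozen
    into the returned model so saved models score new documents with stable
    IDF weights.
    """
    config = config or BoosterConfig()
    labels = _check_labels(labels)
    if len(labels) != dtm.weights.shape[0]:
        raise ValueError("labels length != number of documents")
    est = _make_estimator(config)
    est.fit(sp.csr_matrix(dtm.weights), labels)
    return TrainedModel(
        estimator=est,
        vocabulary=list(dtm.terms),
        config=config,
        n_docs=dtm.n_docs,
        doc_freq={t: int(df) for t, df in zip(dtm.terms, dtm.doc_freq)},
    )


def _staged_losses(est, X, y, n_iter: int) -> np.ndarray:
    losses = np.empty(n_iter)
    for i, proba in enumerate(est.staged_predict_proba(X)):
        losses[i] = log_loss(y, proba[:, 1], labels=[0, 1])
    return losses


def iteration_history(
    dtm: DocumentTermMatrix,
    labels,
    config: BoosterConfig,
    fold_plan,
    max_iterations: int | None = None,
) -> IterationHistory:
    """Held-out log-loss per boosting iteration across a fold plan."""
    labels = _check_labels(labels)
    n_iter = max_iterations or max(config.iterations, 50)
    X = sp.csr_matrix(dtm.weights)
    n_sets, k = fold_plan.R, fold_plan.k
    train_curves = np.empty((n_sets, k, n_iter))
    valid_curves = np.empty((n_sets, k, n_iter))
    for r in range(n_sets):
        for f in range(k):
            tr, va = fold_plan.split(r, f)
            est = _make_estimator(config, n_estimators=n_iter)
            est.fit(X[tr], labels[tr])
            train_curves[r, f] = _staged_losses(est, X[tr], labels[tr], n_iter)
            valid_curves[r, f] = _staged_losses(est, X[va], labels[va], n_iter)
    return IterationHistory(train_curves=train_curves, valid_curves=valid_curves)


def select_iterations(history: IterationHistory) -> int:
    """1-based iteration minimizing mean validation loss; ties -> earliest."""
    if history.n_iterations == 0:
        raise ValueError("empty iteration history")
    return int(np.argmin(history.mean_valid)) + 1


def sample_design(
    ranges: dict[str, tuple[float, float]], n_design_points: int, seed: int
) -> list[BoosterConfig]:
    """Latin-hypercube sample of booster configs over the given ranges."""
    if n_design_points < 1:
        raise ValueError("n_design_points must be >= 1")
    names = list(ranges)
    for name, (lo, hi) in ranges.items():
        if name not in DEFAULTS_AND_RANGES:
            raise ValueError(f"unknown hyperparameter: {name!r}")
        if lo > hi:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_design_points)
    configs = []
    for row in unit:
        kw = {}
        for j, name in enumerate(names):
            lo, hi = ranges[name]
            val = lo + row[j] * (hi - lo)
            kw[name] = int(round(val)) if name in _INTEGER_PARAMS else float(val)
        configs.append(BoosterConfig(seed=seed, **kw))
    return configs


def autotune(
    dtm: DocumentTermMatrix,
    labels,
    ranges: dict[str, tuple[float, float]] | None = None,
    n_design_points: int = 10,
    inner_folds: int = 2,
    seed: int = 0,
    return_trials: bool = False,
):
    """Pick the best config among a space-filling design, by inner-CV loss."""
    from sklearn.model_selection import StratifiedKFold

    labels = _check_labels(labels)
    ranges = ranges or default_ranges()
    candidates = sample_design(ranges, n_design_points, seed)
    X = sp.csr_matrix(dtm.weights)
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, labels))
    scores = []
    for cand in candidates:
        fold_losses = []
        for tr, va in splits:
            est = _make_estimator(cand)
            est.fit(X[tr], labels[tr])
            proba = est.predict_proba(X[va])[:, 1]
            fold_losses.append(log_loss(labels[va], proba, labels=[0, 1]))
        scores.append(float(np.mean(fold_losses)))
    best = int(np.argmin(scores))
    logger.info(
        "autotune: best of %d design points has inner-CV loss %.4f",
        n_design_points,
        scores[best],
    )
    if return_trials:
        return candidates[best], list(zip(candidates, scores))
    return candidates[best]


@dataclass
class ImportanceTable:
    """Per-term splits, gain (mean objective improvement per split), cover."""

    table: pd.DataFrame  # columns: term, splits, gain, total_gain, cover, gain_rank

    def __len__(self) -> int:
        return len(self.table)

    def top(self, n: int) -> list[str]:
        return self.table.nsmallest(n, "gain_rank")["term"].tolist()


def _tree_accounting(tree, splits, total_gain, cover) -> None:
    left, right = tree.children_left, tree.children_right
    w = tree.weighted_n_node_samples
    imp = tree.impurity
    for node in range(tree.node_count):
        if left[node] == -1:  # leaf
            continue
        f = tree.feature[node]
        gain = w[node] * imp[node] - w[left[node]] * imp[left[node]] - w[
            right[node]
        ] * imp[right[node]]
        splits[f] += 1
        total_gain[f] += max(gain, 0.0)
        cover[f] += w[node]


def importance(model: TrainedModel) -> ImportanceTable:
    """splits/gain/cover per used term, ranked by gain descending.

    Gain is the average objective-function improvement over the splits that
    use the term; cover the average number of observations those splits see.
    Terms never used to split are omitted.
    """
    n_features = len(model.vocabulary)
    splits = np.zeros(n_features, dtype=np.int64)
    total_gain = np.zeros(n_features)
    cover = np.zeros(n_features)
    for stage in model.estimator.estimators_:
        for est in stage:
            _tree_accounting(est.tree_, splits, total_gain, cover)
    used = np.flatnonzero(splits > 0)
    frame = pd.DataFrame(
        {
            "term": [model.vocabulary[j] for j in used],
            "splits": splits[used],
            "total_gain": total_gain[used],
            "gain": total_gain[used] / splits[used],
            "cover": cover[used] / splits[used],
        }
    )
    frame = frame.sort_values(
        ["gain", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["gain_rank"] = np.arange(1, len(frame) + 1)
    return ImportanceTable(table=frame)


def gain_vs_count(
    imp: ImportanceTable, m: CountMatrix, keywords: set[str] | None = None
) -> pd.DataFrame:
    """Join importance with raw corpus counts; report rank correlation.

    The returned frame carries a ``count_gain_spearman`` attribute (NaN when
    undefined, i.e. fewer than two terms).
    """
    keywords = keywords or set()
    totals = dict(zip(m.terms, m.term_totals))
    missing = [t for t in imp.table["term"] if t not in totals]
    if missing:
        raise ValueError(f"importance terms absent from count matrix: {missing[:5]}")
    frame = imp.table[["term", "gain", "gain_rank"]].copy()
    frame["count"] = [int(totals[t]) for t in frame["term"]]
    frame["keyword"] = [t in keywords for t in frame["term"]]
    if len(frame) >= 2:
        rho = spearmanr(frame["count"], frame["gain"]).statistic
    else:
        rho = float("nan")
    frame.attrs["count_gain_spearman"] = float(rho) if rho == rho else float("nan")
    return frame


def save_model(model: TrainedModel, prefix: str | Path) -> None:
    """Persist booster (joblib) + JSON sidecar (vocabulary, config, IDF)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, prefix.with_suffix(".joblib"))
    sidecar = {
        "vocabulary": model.vocabulary,
        "config": model.config.to_dict(),
        "threshold": model.threshold,
        "n_docs": model.n_docs,
        "doc_freq": model.doc_freq,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_model(prefix: str | Path) -> TrainedModel:
    prefix = Path(prefix)
    sidecar_path = prefix.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"model sidecar missing: {sidecar_path}")
    booster_path = prefix.with_suffix(".joblib")
    if not booster_path.exists():
        raise FileNotFoundError(f"model file missing: {booster_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    return TrainedModel(
        estimator=joblib.load(booster_path),
        vocabulary=list(sidecar["vocabulary"]),
        config=BoosterConfig.from_dict(sidecar["config"]),
        threshold=float(sidecar["threshold"]),
        n_docs=int(sidecar["n_docs"]),
        doc_freq={t: int(v) for t, v in sidecar["doc_freq"].items()},
    )
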