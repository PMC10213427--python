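"""Feature ranking, top-N selection sweep, and SVM classification.

The selection stage ranks features by recursive feature elimination (RFE):
a linear support-vector regressor is fit repeatedly, and at each iteration
the feature with the smallest absolute coefficient is removed; the reverse
elimination order is the ranking.  A top-N sweep then classifies with the N
highest-ranked features for every N and keeps the N with the best
cross-validated accuracy — those features are the "discriminative" set.
Classification is a support-vector machine whose kernel and regularisation
are chosen by grid search over 22 standard combinations, evaluated by
repeated stratified k-fold cross-validation.

Two workflows are offered.  The rank-once workflow (ranking and sweep on the
full sample, as selection-then-classification studies typically report) is
optimistic because the test folds inform the selection.  The nested workflow
(:func:`nested_cv_accuracy`) ranks and sweeps inside each training partition
and is the honest generalisation estimate; use it for null calibration.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVR

__all__ = [
    "FeatureRanking",
    "ClassificationReport",
    "ConfusionMetrics",
    "default_grid",
    "rfe_rank",
    "topn_accuracy_sweep",
    "svm_classify",
    "nested_cv_accuracy",
    "metrics_from_confusion",
]


def default_grid() -> list[dict]:
    """The 22 standard SVM hyperparameter combinations.

    linear C in {1, 10, 100, 1000} (4); poly C=1, degree in {2, 3} (2);
    rbf C in {1, 10, 100, 1000} x gamma in {1, 0.1, 0.01, 0.001} (16).
    """
    grid: list[dict] = []
    for c in (1, 10, 100, 1000):
        grid.append({"kernel": "linear", "C": c})
    for degree in (2, 3):
        grid.append({"kernel": "poly", "C": 1, "degree": degree})
    for c in (1, 10, 100, 1000):
        for gamma in (1, 0.1, 0.01, 0.001):
            grid.append({"kernel": "rbf", "C": c, "gamma": gamma})
    return grid


@dataclass
class FeatureRanking:
    """Feature order from most to least important, with elimination weights."""

    order: list[int]  # column indices, most -> least important
    weights: np.ndarray  # |coefficient| at elimination, aligned with `order`
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.order) != len(self.weights):
            raise ValueError("order and weights must align")
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("ranking must be a permutation of all feature indices")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def top(self, n: int) -> list[int]:
        return self.order[:n]

    def to_tsv(self, index_labels: Sequence[str] | None = None) -> str:
        labels = index_labels or self.feature_ids or [str(i) for i in self.order]
        lines = ["rank\tfeature\tweight"]
        for rank, (col, w) in enumerate(zip(self.order, self.weights), start=1):
            name = labels[col] if index_labels or self.feature_ids else str(col)
            lines.append(f"{rank}\t{name}\t{w:.4f}")
        return "\n".join(lines) + "\n"


@dataclass
class ConfusionMetrics:
    """Accuracy, precision, recall and f1 from one confusion table.

    Undefined rates (zero denominators) are NaN, never silently 0.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Standard binary-classification rates from TP/TN/FP/FN counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ConfusionMetrics(acc, precision, recall, f1)


@dataclass
class ClassificationReport:
    """Aggregate and per-repeat metrics of repeated cross-validated SVM."""

    auc: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    per_repeat: list[dict] = field(default_factory=list)
    chosen_params: dict | None = None
    n_repeats: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "chosen_params": self.chosen_params,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "per_repeat": self.per_repeat,
        }


def _ranking_estimator() -> LinearSVR:
    # the linear ranking estimator whose coefficients weight the features;
    # tolerance is loose — only the coefficient ORDER matters for elimination
    return LinearSVR(C=1.0, dual=True, max_iter=3000, tol=1e-3, random_state=0)


def rfe_rank(
    features: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 10,
    seed: int = 0,
    step_fraction: float = 0.0,
    feature_ids: Sequence[str] | None = None,
) -> FeatureRanking:
    """Rank features by recursive elimination under a linear SV regressor.

    At each iteration the estimator is fit on each of ``cv_folds`` training
    partitions (deterministic given ``seed``) and the absolute coefficients
    are averaged across folds; the feature with the smallest averaged
    magnitude is eliminated (ties break by ascending column index).  The
    reverse elimination order is the ranking, and each feature's weight is
    its averaged |coefficient| at the iteration it was eliminated.
    ``cv_folds=1`` fits on the full sample instead.  ``step_fraction > 0``
    eliminates that fraction of the remaining features per iteration (speed
    option); the default removes one at a time.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be subjects x features aligned with labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels are constant; need two classes")
    counts = Counter(y.tolist())
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 subjects per class")
    if cv_folds > 1 and cv_folds > min(counts.values()):
        raise ValueError(
            f"cv_folds={cv_folds} exceeds minority class size {min(counts.values())}"
        )

    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    n_features = X.shape[1]
    remaining = list(range(n_features))
    eliminated: list[int] = []
    elim_weights: list[float] = []
    est = _ranking_estimator()

    if cv_folds > 1:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        train_sets = [tr for tr, _ in splitter.split(Xs)]
    else:
        train_sets = [np.arange(X.shape[0])]

    while remaining:
        sub = Xs[:, remaining]
        coef = np.zeros(len(remaining))
        for tr in train_sets:
            model = clone(est)
            model.fit(sub[tr], y[tr])
            coef += np.abs(np.ravel(model.coef_))
        coef /= len(train_sets)
        if len(remaining) == 1:
            eliminated.append(remaining[0])
            elim_weights.append(float(coef[0]))
            break
        n_drop = 1
        if step_fraction > 0:
            n_drop = max(1, int(step_fraction * len(remaining)))
        # np.argsort is stable: ties break by ascending column position
        drop_pos = np.argsort(coef, kind="stable")[:n_drop]
        for p in sorted(drop_pos, key=lambda p: coef[p]):
            eliminated.append(remaining[p])
            elim_weights.append(float(coef[p]))
        remaining = [r for i, r in enumerate(remaining) if i not in set(drop_pos)]

    order = eliminated[::-1]
    weights = np.asarray(elim_weights[::-1])
    ids = list(feature_ids) if feature_ids is not None else None
    return FeatureRanking(order=order, weights=weights, feature_ids=ids)


def _svc_from_params(params: Mapping) -> SVC:
    return SVC(**params)


def _grid_search_fit(
    X: np.ndarray, y: np.ndarray, grid: Sequence[Mapping], inner_cv: int, seed: int
) -> Pipeline:
    """Standardise + SVC, hyperparameters chosen by inner CV accuracy."""
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC())])
    if len(grid) == 1:
        pipe.set_params(**{f"svc__{k}": v for k, v in grid[0].items()})
        pipe.fit(X, y)
        pipe.best_params_ = dict(grid[0])  # type: ignore[attr-defined]
        return pipe
    param_grid = [{f"svc__{k}": [v] for k, v in combo.items()} for combo in grid]
    cv = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    gs = GridSearchCV(pipe, param_grid, scoring="accuracy", cv=cv, n_jobs=1)
    gs.fit(X, y)
    best = gs.best_estimator_
    best.best_params_ = {  # type: ignore[attr-defined]
        k.removeprefix("svc__"): v for k, v in gs.best_params_.items()
    }
    return best


def svm_classify(
    features: np.ndarray,
    labels: np.ndarray,
    grid: Sequence[Mapping] | None = None,
    cv_folds: int = 10,
    n_repeats: int = 50,
    seed: int = 0,
    inner_cv: int = 3,
) -> ClassificationReport:
    """Repeated stratified k-fold SVM classification with grid search.

    Per repeat the fold assignment is reshuffled (seeded); within each outer
    training fold the grid search picks the combination with the best inner
    CV accuracy, and metrics are computed on pooled held-out predictions.
    The aggregate is the mean over repeats; AUC uses continuous decision
    scores, not thresholded labels.
    """
    if grid is None:
        grid = default_grid()
    if len(grid) == 0:
        raise ValueError("hyperparameter grid must be nonempty")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    counts = Counter(y.tolist())
    if len(counts) < 2:
        raise ValueError("labels are constant; need two classes")
    if cv_folds > min(counts.values()):
        raise ValueError(
            f"cv_folds={cv_folds} exceeds minority class size {min(counts.values())}"
        )

    per_repeat: list[dict] = []
    chosen: Counter = Counter()
    for rep in range(n_repeats):
        rep_seed = seed + rep
        outer = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rep_seed)
        y_true = np.empty(y.size, dtype=int)
        y_pred = np.empty(y.size, dtype=int)
        scores = np.empty(y.size)
        for tr, te in outer.split(X, y):
            model = _grid_search_fit(X[tr], y[tr], grid, inner_cv, rep_seed)
            y_true[te] = y[te]
            y_pred[te] = model.predict(X[te])
            scores[te] = model.decision_function(X[te])
            chosen[tuple(sorted(model.best_params_.items()))] += 1
        tp = int(np.sum((y_pred == 1) & (y_true == 1)))
        tn = int(np.sum((y_pred == 0) & (y_true == 0)))
        fp = int(np.sum((y_pred == 1) & (y_true == 0)))
        fn = int(np.sum((y_pred == 0) & (y_true == 1)))
        m = metrics_from_confusion(tp, tn, fp, fn)
        auc = float(roc_auc_score(y_true, scores))
        per_repeat.append(
            {
                "auc": auc,
                "accuracy": m.accuracy,
                "f1": m.f1,
                "precision": m.precision,
                "recall": m.recall,
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
            }
        )

    def _mean(key: str) -> float:
        vals = [r[key] for r in per_repeat]
        return float(np.nanmean(vals)) if vals else math.nan

    most_common = dict(chosen.most_common(1)[0][0]) if chosen else None
    return ClassificationReport(
        auc=_mean("auc"),
        accuracy=_mean("accuracy"),
        f1=_mean("f1"),
        precision=_mean("precision"),
        recall=_mean("recall"),
        per_repeat=per_repeat,
        chosen_params=most_common,
        n_repeats=n_repeats,
        seed=seed,
    )


def topn_accuracy_sweep(
    features: np.ndarray,
    labels: np.ndarray,
    ranking: FeatureRanking,
    grid: Sequence[Mapping] | None = None,
    n_max: int | None = None,
    cv_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    inner_cv: int = 3,
) -> tuple[np.ndarray, int, list[int]]:
    """Mean repeated-CV accuracy using the top-N ranked features, N = 1..n_max.

    Returns (accuracy_per_n, best_n, selected_columns) where ``best_n`` is
    the smallest N attaining the maximal accuracy and ``selected_columns``
    the corresponding feature columns (the "discriminative" set).
    """
    if grid is None:
        grid = default_grid()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    p = X.shape[1]
    if len(ranking.order) != p:
        raise ValueError("ranking does not cover the feature columns")
    if n_max is None:
        n_max = p
    if n_max > p:
        raise ValueError(f"n_max={n_max} exceeds feature count {p}")
    accs = np.empty(n_max)
    for n in range(1, n_max + 1):
        cols = ranking.top(n)
        rep = svm_classify(
            X[:, cols],
            y,
            grid=grid,
            cv_folds=cv_folds,
            n_repeats=n_repeats,
            seed=seed,
            inner_cv=inner_cv,
        )
        accs[n - 1] = rep.accuracy
    best_n = int(np.argmax(accs)) + 1
    return accs, best_n, ranking.top(best_n)


def nested_cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    candidate_ns: Sequence[int] | None = None,
    grid: Sequence[Mapping] | None = None,
    outer_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    rank_cv_folds: int = 1,
    rank_step_fraction: float = 0.0,
    inner_cv: int = 3,
) -> np.ndarray:
    """Leak-free accuracy: rank and sweep inside each training partition.

    For each outer fold the RFE ranking and the top-N choice (over
    ``candidate_ns``, by inner CV accuracy on the training fold only) are
    redone from scratch; the selected model is then scored on the held-out
    fold.  Returns the per-repeat mean held-out accuracies.  This is the
    estimate to use when checking that a null cohort classifies at chance.
    """
    if grid is None:
        grid = [{"kernel": "linear", "C": 1}]
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    p = X.shape[1]
    if candidate_ns is None:
        candidate_ns = sorted({1, 2, 5, 10, min(20, p), p})
    candidate_ns = [n for n in candidate_ns if 1 <= n <= p]

    out = np.empty(n_repeats)
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=rep_seed)
        correct = 0
        for fold_i, (tr, te) in enumerate(outer.split(X, y)):
            rank = rfe_rank(
                X[tr],
                y[tr],
                cv_folds=rank_cv_folds,
                seed=rep_seed + fold_i,
                step_fraction=rank_step_fraction,
            )
            best_acc, best_cols = -1.0, rank.top(candidate_ns[0])
            for n in candidate_ns:
                cols = rank.top(n)
                inner_rep = svm_classify(
                    X[np.ix_(tr, cols)],
                    y[tr],
                    grid=grid,
                    cv_folds=min(inner_cv, outer_folds),
                    n_repeats=1,
                    seed=rep_seed + fold_i,
                    inner_cv=2,
                )
                if inner_rep.accuracy > best_acc:
                    best_acc, best_cols = inner_rep.accuracy, cols
            model = _grid_search_fit(
                X[np.ix_(tr, best_cols)], y[tr], grid, inner_cv, rep_seed + fold_i
            )
            correct += int(np.sum(model.predict(X[np.ix_(te, best_cols)]) == y[te]))
        out[rep] = correct / y.size
    return out
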