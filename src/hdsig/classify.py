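"""Group-aware cross-validated shallow classification.

The central object is :class:`GroupCVClassifier`, built from a
:class:`~hdsig.features.FeatureMatrix` and a :class:`ModelSpec`; ``fit()``
runs patient-grouped k-fold cross-validation — every epoch of a patient is
assigned to exactly one fold, so no patient's data ever straddles a
train/test boundary — and returns a :class:`CVResults` with pooled
out-of-fold metrics, confusion counts, curves and a ``summary()`` table.

Six shallow model families are supported: Extremely Randomized Trees,
Random Forest, polynomial-kernel SVM, logistic regression, and linear and
quadratic discriminant analysis. The tuned tree-ensemble specs use
n_estimators = 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapz_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "ModelSpec",
    "CVResults",
    "GroupCVClassifier",
    "MODEL_NAMES",
    "group_kfold_split",
    "evaluate",
    "confusion",
    "curves",
    "tuned_spec",
    "random_search",
]

MODEL_NAMES = ("ERT", "RandomForest", "SVM_poly", "LogisticRegression", "LDA", "QDA")


@dataclass(frozen=True)
class ModelSpec:
    """A named shallow model plus hyperparameter overrides.

    Defaults mirror the common library defaults: 100 trees with Gini
    impurity, SVM polynomial kernel of degree 3 with C=1, L2 logistic
    regression, unshrunk LDA/QDA.
    """

    name: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    def build(self):
        hp = dict(self.hyperparams)
        if self.name == "ERT":
            return ExtraTreesClassifier(random_state=self.seed, **hp)
        if self.name == "RandomForest":
            return RandomForestClassifier(random_state=self.seed, **hp)
        if self.name == "SVM_poly":
            hp.setdefault("kernel", "poly")
            if hp["kernel"] != "poly":
                raise ValueError("SVM kernel is fixed to polynomial")
            return SVC(random_state=self.seed, **hp)
        if self.name == "LogisticRegression":
            hp.setdefault("max_iter", 2000)
            return LogisticRegression(random_state=self.seed, **hp)
        if self.name == "LDA":
            return LinearDiscriminantAnalysis(**hp)
        return QuadraticDiscriminantAnalysis(**hp)


def tuned_spec(name: str = "ERT", seed: int = 0) -> ModelSpec:
    """The scaled-out tree-ensemble spec (n_estimators = 1000)."""
    if name not in ("ERT", "RandomForest"):
        raise ValueError("tuned specs exist for the tree ensembles only")
    return ModelSpec(name=name, hyperparams={"n_estimators": 1000}, seed=seed)


def group_kfold_split(
    groups: Sequence,
    k: int = 10,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> dict[str, int]:
    """Assign each patient to one of k folds, balanced in patient count.

    Patients are shuffled with the seed and dealt round-robin, so fold sizes
    differ by at most one. When per-epoch ``labels`` are supplied the deal is
    class-stratified (each class shuffled and dealt in turn), keeping the
    class mix nearly constant across folds — without this, the training-set
    prior shifts against each test fold's class mix and pooled out-of-fold
    probabilities acquire a pessimistic bias. Returns a patient_id -> fold
    map.
    """
    unique = list(dict.fromkeys(map(str, groups)))  # first-appearance order
    if len(unique) < k:
        raise ValueError(f"{len(unique)} patients < k={k} folds")
    rng = np.random.default_rng(seed)
    if labels is None:
        order = [unique[int(i)] for i in rng.permutation(len(unique))]
    else:
        label_of = dict(zip(map(str, groups), labels))
        order = []
        for cls in sorted({label_of[p] for p in unique}, reverse=True):
            members = [p for p in unique if label_of[p] == cls]
            order.extend(members[int(i)] for i in rng.permutation(len(members)))
    return {pid: pos % k for pos, pid in enumerate(order)}


def confusion(predictions: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts of binary predictions against labels."""
    predictions = np.asarray(predictions, int)
    labels = np.asarray(labels, int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(((predictions == 1) & (labels == 1)).sum())
    fp = int(((predictions == 1) & (labels == 0)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    fn = int(((predictions == 0) & (labels == 1)).sum())
    return tp, fp, tn, fn


def curves(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC and precision-recall curves with their areas.

    ROC is a threshold sweep with trapezoidal area; the PR area uses step
    interpolation (average precision).
    """
    labels = np.asarray(labels, int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both classes to compute curves")
    fpr, tpr, roc_thresh = roc_curve(labels, scores)
    precision, recall, pr_thresh = precision_recall_curve(labels, scores)
    # step-interpolated PR area: sum of precision * recall increments
    pr_auc = float(-np.sum(np.diff(recall) * np.array(precision)[:-1]))
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thresh,
        "roc_auc": float(_trapz_auc(fpr, tpr)),
        "precision": precision,
        "recall": recall,
        "pr_thresholds": pr_thresh,
        "pr_auc": pr_auc,
    }


@dataclass
class CVResults:
    """Pooled out-of-fold evaluation of one model.

    Percent-scale accuracy/precision/recall follow the usual reporting
    convention; ROC-AUC and F1 are on [0, 1].
    """

    model_name: str
    accuracy: float
    precision: float
    recall: float
    roc_auc: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    predictions: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    fold_map: dict[str, int]
    per_fold: list[dict] | None = None
    k: int = 10

    @property
    def confusion_matrix(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def curves(self) -> dict:
        return curves(self.scores, self.labels)

    def summary(self) -> str:
        lines = [
            f"Group {self.k}-fold CV results — {self.model_name}",
            "-" * 46,
            f"{'Accuracy (%)':<18}{self.accuracy:>10.3f}",
            f"{'Precision (%)':<18}{self.precision:>10.3f}",
            f"{'Recall (%)':<18}{self.recall:>10.3f}",
            f"{'ROC AUC':<18}{self.roc_auc:>10.3f}",
            f"{'F1 score':<18}{self.f1:>10.3f}",
            f"{'TP/FP/TN/FN':<18}"
            f"{self.tp:>5d}{self.fp:>5d}{self.tn:>5d}{self.fn:>5d}",
            f"{'n epochs':<18}{len(self.labels):>10d}",
            f"{'n patients':<18}{len(self.fold_map):>10d}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "accuracy_pct": self.accuracy,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
            "roc_auc": self.roc_auc,
            "f1": self.f1,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "fold_map": self.fold_map,
        }


def _metrics(labels, predictions, scores) -> dict:
    tp, fp, tn, fn = confusion(predictions, labels)
    n = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    # trapezoidal threshold-sweep area; identical to the rank statistic
    fpr, tpr, _ = roc_curve(labels, scores)
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "roc_auc": float(_trapz_auc(fpr, tpr)),
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


class GroupCVClassifier:
    """Patient-grouped k-fold cross-validated classifier evaluation.

    Parameters
    ----------
    fm : FeatureMatrix
        Epoch features with binary labels and patient groups.
    spec : ModelSpec, optional
        Model to evaluate (default: ERT with library defaults).
    k : int
        Number of folds.
    seed : int
        Drives the patient-to-fold shuffle (the model's own seed lives on
        the spec).
    per_fold : bool
        Additionally record per-fold metric blocks (metrics reported on the
        results object are always computed on the pooled out-of-fold
        predictions).
    """

    def __init__(
        self,
        fm: FeatureMatrix,
        spec: ModelSpec | None = None,
        k: int = 10,
        seed: int = 0,
        per_fold: bool = False,
    ) -> None:
        if len(set(fm.labels.tolist())) < 2:
            raise ValueError("feature matrix must contain both classes")
        self.fm = fm
        self.spec = spec if spec is not None else ModelSpec("ERT")
        self.k = k
        self.seed = seed
        self.per_fold = per_fold

    def fit(self) -> CVResults:
        fm, spec = self.fm, self.spec
        fold_map = group_kfold_split(
            fm.groups, k=self.k, seed=self.seed, labels=fm.labels
        )
        folds = np.array([fold_map[str(g)] for g in fm.groups])
        predictions = np.empty(fm.n_epochs, int)
        scores = np.empty(fm.n_epochs, float)
        fold_blocks = []
        for f in range(self.k):
            test = folds == f
            train = ~test
            if len(set(fm.labels[train].tolist())) < 2:
                raise ValueError(
                    f"fold {f} training set is single-class; use a larger or "
                    "better-balanced cohort"
                )
            est = spec.build()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # QDA collinearity etc.
                est.fit(fm.X[train], fm.labels[train])
                predictions[test] = est.predict(fm.X[test])
                if hasattr(est, "predict_proba"):
                    scores[test] = est.predict_proba(fm.X[test])[:, 1]
                else:
                    scores[test] = est.decision_function(fm.X[test])
            if self.per_fold:
                fold_blocks.append(
                    _metrics(fm.labels[test], predictions[test], scores[test])
                )
        m = _metrics(fm.labels, predictions, scores)
        return CVResults(
            model_name=spec.name,
            accuracy=m["accuracy"],
            precision=m["precision"],
            recall=m["recall"],
            roc_auc=m["roc_auc"],
            f1=m["f1"],
            tp=m["tp"],
            fp=m["fp"],
            tn=m["tn"],
            fn=m["fn"],
            predictions=predictions,
            scores=scores,
            labels=fm.labels.copy(),
            fold_map=fold_map,
            per_fold=fold_blocks if self.per_fold else None,
            k=self.k,
        )


def evaluate(
    fm: FeatureMatrix, spec: ModelSpec, k: int = 10, seed: int = 0
) -> CVResults:
    """Functional wrapper around :class:`GroupCVClassifier`."""
    return GroupCVClassifier(fm, spec, k=k, seed=seed).fit()


def random_search(
    fm: FeatureMatrix,
    name: str,
    grid: Mapping[str, Sequence],
    n_iter: int = 10,
    k: int = 10,
    seed: int = 0,
) -> tuple[ModelSpec, CVResults]:
    """Seeded random search over a hyperparameter grid.

    Samples ``n_iter`` configurations uniformly from the grid's cartesian
    product and returns the spec with the best pooled out-of-fold ROC-AUC.
    """
    rng = np.random.default_rng(seed)
    keys = list(grid)
    best: tuple[ModelSpec, CVResults] | None = None
    for _ in range(n_iter):
        hp = {key: grid[key][int(rng.integers(len(grid[key])))] for key in keys}
        spec = ModelSpec(name=name, hyperparams=hp, seed=seed)
        res = evaluate(fm, spec, k=k, seed=seed)
        if best is None or res.roc_auc > best[1].roc_auc:
            best = (spec, res)
    assert best is not None
    return best
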