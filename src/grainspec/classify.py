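"""Kennard-Stone partitioning, the four classifiers, and evaluation.

The modelling protocol: spectra are split 7:3 into calibration and test
sets by the deterministic maximin Kennard-Stone algorithm; SVM (RBF,
cost tuned around 2.5 by grid search), decision tree (Gini, at most 20
splits), KNN (Minkowski distance, K tuned over {3,5,7,9,11,15,20}) and
random forest (200 trees, minimum leaf size 5) are trained with 5-fold
cross-validated tuning on the calibration set; evaluation reports the
2x2 confusion matrix (infested = positive class) with accuracy,
precision, recall, F1 and Cohen's kappa.

The classifiers themselves come from scikit-learn; this module's
contract is the hyperparameters, the tuning rule and determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import ParameterError, SpectraMatrix, as_array
from .pls import CVPlan

log = logging.getLogger(__name__)

KINDS = ("svm_rbf", "dt", "knn", "rf")

#: K grid for KNN tuning
KNN_GRID = (3, 5, 7, 9, 11, 15, 20)
#: SVM cost grid, centered on 2.5
SVM_COST_GRID = (0.625, 1.25, 2.5, 5.0, 10.0)


@dataclass
class SplitPlan:
    """Deterministic train/test membership by row position."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    ratio: float

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        n = self.train_idx.size + self.test_idx.size
        union = np.union1d(self.train_idx, self.test_idx)
        if union.size != n or not np.array_equal(union, np.arange(n)):
            raise ParameterError("train/test indices must partition 0..N-1")


def kennard_stone_split(X, ratio: float = 0.7) -> SplitPlan:
    """Kennard-Stone maximin sample partitioning.

    Starts from the globally most distant pair (Euclidean distance on
    the rows) and repeatedly adds the sample whose minimum distance to
    the already selected set is largest, until round(ratio*N) samples
    are selected for training; the remainder is the test set.  Distance
    ties break to the lowest row index.
    """
    arr = as_array(X)
    n = arr.shape[0]
    if n < 3:
        raise ParameterError("Kennard-Stone needs at least 3 samples")
    if not 0 < ratio < 1:
        raise ParameterError("ratio must be in (0, 1)")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 2), n - 1)
    sq = np.sum(arr ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (arr @ arr.T)
    np.maximum(d2, 0, out=d2)
    # initial pair: globally most distant; lowest indices on ties
    flat = int(np.argmax(d2))
    i0, j0 = divmod(flat, n)
    selected = [min(i0, j0), max(i0, j0)]
    min_d = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d[selected] = -1.0
    while len(selected) < n_train:
        nxt = int(np.argmax(min_d))  # argmax -> lowest index on ties
        selected.append(nxt)
        np.minimum(min_d, d2[nxt], out=min_d)
        min_d[nxt] = -1.0
    train = np.sort(np.asarray(selected))
    test = np.setdiff1d(np.arange(n), train)
    return SplitPlan(train_idx=train, test_idx=test, ratio=ratio)


@dataclass
class ClassifierSpec:
    """One of the four classifier configurations.

    Fixed parameters follow the assay protocol: SVM has an RBF kernel
    with cost 2.5 (tunable by grid search) and 'scale' kernel width; the
    decision tree uses the Gini criterion with at most 20 splits; KNN
    uses Minkowski distance with uniform weights and K tuned over
    {3,5,7,9,11,15,20}; the random forest has 200 trees with minimum
    leaf size 5.
    """

    kind: str = "svm_rbf"
    tune: bool = True
    svm_cost: float = 2.5
    svm_cost_grid: tuple = SVM_COST_GRID
    knn_grid: tuple = KNN_GRID
    dt_max_splits: int = 20
    rf_n_trees: int = 200
    rf_min_leaf: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError(f"unknown classifier kind {self.kind!r}")
        if self.tune and self.kind == "svm_rbf" and not self.svm_cost_grid:
            raise ParameterError("empty SVM tuning grid")
        if self.tune and self.kind == "knn" and not self.knn_grid:
            raise ParameterError("empty KNN tuning grid")


@dataclass
class EvalReport:
    """2x2 confusion counts and the derived metrics.

    Positive class = infested (label 1).  ``acc`` is on the 0-1 scale;
    ``acc_pct`` gives the percentage.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def acc_pct(self) -> float:
        return 100.0 * self.acc

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def kappa(self) -> float:
        """Cohen's kappa, (p_o - p_e)/(1 - p_e), p_e from the marginals."""
        n = self.n
        po = (self.tp + self.tn) / n
        pe = ((self.tp + self.fp) * (self.tp + self.fn)
              + (self.tn + self.fn) * (self.tn + self.fp)) / n ** 2
        if pe == 1.0:
            return 0.0
        return (po - pe) / (1 - pe)

    @property
    def confusion(self) -> np.ndarray:
        """Counts as [[TN, FP], [FN, TP]] (rows = true 0/1, cols = pred)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
                "acc_pct": self.acc_pct, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "kappa": self.kappa}


def _make_estimator(spec: ClassifierSpec, **overrides):
    if spec.kind == "svm_rbf":
        return SVC(C=overrides.get("C", spec.svm_cost), kernel="rbf",
                   gamma="scale")
    if spec.kind == "dt":
        # "maximum of 20 splits" = at most 20 internal nodes = 21 leaves
        return DecisionTreeClassifier(criterion="gini",
                                      max_leaf_nodes=spec.dt_max_splits + 1,
                                      random_state=spec.seed)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=overrides.get("k", 5),
                                    metric="minkowski", weights="uniform")
    if spec.kind == "rf":
        return RandomForestClassifier(n_estimators=spec.rf_n_trees,
                                      min_samples_leaf=spec.rf_min_leaf,
                                      random_state=spec.seed)
    raise ParameterError(spec.kind)


def _report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return EvalReport(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))))


def _cv_score(spec: ClassifierSpec, Xtr, ytr, plan: CVPlan, **overrides):
    """Pooled out-of-fold accuracy and kappa for one candidate setting."""
    folds = plan.folds(len(ytr), ytr)
    pred = np.empty(len(ytr), dtype=int)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(ytr)), test_idx)
        est = _make_estimator(spec, **overrides)
        est.fit(Xtr[train], ytr[train])
        pred[test_idx] = est.predict(Xtr[test_idx])
    rep = _report_from_predictions(ytr, pred)
    return rep.acc, rep.kappa


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    estimator: object
    tuning_trace: list = field(default_factory=list)
    chosen: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(as_array(X)), dtype=int)


def tune_and_train(Xtr, ytr, spec: ClassifierSpec,
                   plan: Optional[CVPlan] = None) -> TrainedClassifier:
    """Grid-search tuning with 5-fold CV, then a final fit on all of Xtr.

    SVM tunes the cost over a grid centered on 2.5 by CV accuracy (kappa
    breaks ties, then the smaller cost).  KNN chooses K from the printed
    grid by maximum accuracy, kappa tie-break, then smaller K.  DT and
    RF train at their fixed parameters.
    """
    Xtr = as_array(Xtr)
    ytr = np.asarray(ytr, dtype=int)
    if np.unique(ytr).size < 2:
        raise ParameterError("training labels contain a single class")
    if plan is None:
        plan = CVPlan(n_folds=5, seed=spec.seed)
    trace = []
    chosen = {}
    if spec.tune and spec.kind == "svm_rbf":
        scored = []
        for c in spec.svm_cost_grid:
            acc, kappa = _cv_score(spec, Xtr, ytr, plan, C=c)
            scored.append((acc, kappa, -c))
            trace.append({"C": c, "cv_acc": acc, "cv_kappa": kappa})
        best = max(range(len(scored)), key=lambda i: scored[i])
        chosen = {"C": spec.svm_cost_grid[best]}
    elif spec.tune and spec.kind == "knn":
        scored = []
        for k in spec.knn_grid:
            acc, kappa = _cv_score(spec, Xtr, ytr, plan, k=k)
            scored.append((acc, kappa, -k))
            trace.append({"K": k, "cv_acc": acc, "cv_kappa": kappa})
        best = max(range(len(scored)), key=lambda i: scored[i])
        chosen = {"k": spec.knn_grid[best]}
    est = _make_estimator(spec, **chosen)
    est.fit(Xtr, ytr)
    return TrainedClassifier(spec=spec, estimator=est, tuning_trace=trace,
                             chosen=chosen)


def evaluate(model: TrainedClassifier, Xte, yte) -> EvalReport:
    """Confusion counts and metrics on a held-out set (infested = positive)."""
    Xte = as_array(Xte)
    yte = np.asarray(yte, dtype=int)
    if len(yte) == 0:
        raise ParameterError("empty test set")
    return _report_from_predictions(yte, model.predict(Xte))


def confusion_table(report: EvalReport) -> dict:
    """Raw counts plus row-normalised percentages of the confusion matrix."""
    counts = report.confusion.astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return {"counts": report.confusion.tolist(),
            "row_pct": norm.tolist(),
            "labels": ["healthy", "infested"]}
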