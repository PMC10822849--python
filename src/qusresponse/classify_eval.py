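"""Train/test splitting, cross-validation, linear SVM and metric reporting.

The evaluation protocol mirrors a response-prediction study on an
imbalanced two-class cohort: a stratified 20% holdout is set aside as
unseen data; the remaining 80% supports fivefold cross-validation (SMOTE
applied inside each fold's training part only); the final model is a linear
support-vector machine (C = 1).  Nonresponder (NR) is the positive class.
Reported metrics are per-class precision, recall and F1 plus balanced
accuracy (the mean of the two per-class recalls, computed before rounding);
percentages are rounded half-up to integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DegenerateFitError, ValidationError
from .selection_balancing import (
    CohortTable,
    SelectionRecord,
    k_rule,
    nonzero_filter,
    select_k_best,
    smote_balance,
)

__all__ = [
    "CLASSES",
    "SplitPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "PipelineResult",
    "split_cohort",
    "train_svm",
    "metrics_from_confusion",
    "crossvalidate",
    "evaluate_pipeline",
]

CLASSES = ("NR", "RR")  # NR is the positive class


def _round_pct(x: float) -> int:
    """Percentage rounded half-up to the nearest integer."""
    return int(np.floor(100.0 * x + 0.5))


@dataclass
class SplitPlan:
    test_fraction: float
    train_ids: np.ndarray
    test_ids: np.ndarray
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids.tolist()) & set(self.test_ids.tolist()):
            raise ValidationError("train and test ids overlap")


@dataclass
class ConfusionMatrix:
    """counts[true][predicted] over (NR, RR)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValidationError("confusion matrix must be 2x2")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        counts = np.zeros((2, 2), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[CLASSES.index(t), CLASSES.index(p)] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 (integer %) and balanced accuracy."""

    per_class: dict  # class -> {"precision": int|None, "recall": ..., "f1": ...}
    balanced_accuracy: int
    parameter: str | None = None
    fold_summaries: list = field(default_factory=list)


def split_cohort(
    labels: np.ndarray,
    test_fraction: float = 0.2,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Hold out ``round(test_fraction * N)`` patients for testing.

    The stratified default allocates per-class test counts by largest
    remainder, so a 174-patient 37/137 cohort yields a 35-patient test set
    with 7 NR and 28 RR.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError("test fraction must lie in (0, 1)")
    if n < 4 or len(np.unique(labels)) < 2:
        raise ValidationError("need >= 4 patients and both classes present")
    rng = np.random.default_rng(seed)
    n_test = int(np.floor(test_fraction * n + 0.5))
    if stratified:
        classes, counts = np.unique(labels, return_counts=True)
        exact = test_fraction * counts
        base = np.floor(exact + 0.5).astype(int)
        # largest-remainder adjustment toward the global test count,
        # ties resolved toward the larger class
        while base.sum() != n_test:
            rema = exact - base
            order = np.lexsort((-counts, -rema if base.sum() < n_test else rema))
            base[order[0]] += 1 if base.sum() < n_test else -1
        test_idx = []
        for cls, n_c in zip(classes, base):
            members = np.nonzero(labels == cls)[0]
            test_idx.extend(rng.permutation(members)[:n_c].tolist())
        test_idx = np.sort(np.asarray(test_idx, dtype=int))
    else:
        test_idx = np.sort(rng.permutation(n)[:n_test])
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return SplitPlan(
        test_fraction=test_fraction,
        train_ids=train_idx,
        test_ids=test_idx,
        stratified=stratified,
        seed=seed,
    )


def train_svm(X: np.ndarray, y: np.ndarray) -> SVC:
    """Linear-kernel SVM, C = 1; prediction is the sign of the decision
    function (no probability calibration)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("SVM training needs both classes")
    if np.unique(y, return_counts=True)[1].min() < 2:
        raise ValidationError("SVM training needs >= 2 rows per class")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    if np.all(X.std(axis=0) == 0):
        raise DegenerateFitError("all features constant: no separating direction exists")
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(X, y)
    return clf


def metrics_from_confusion(cm: ConfusionMatrix, parameter: str | None = None) -> MetricsReport:
    """Per-class precision/recall/F1 and balanced accuracy from a 2x2 matrix.

    Zero-denominator metrics are reported as ``None`` (undefined), never 0.
    Balanced accuracy is the mean of the two per-class recalls computed
    before any rounding.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    per_class: dict[str, dict] = {}
    recalls = []
    for i, cls in enumerate(CLASSES):
        tp = cm.counts[i, i]
        actual = cm.counts[i, :].sum()
        predicted = cm.counts[:, i].sum()
        precision = tp / predicted if predicted > 0 else None
        recall = tp / actual if actual > 0 else None
        if precision is not None and recall is not None and (precision + recall) > 0:
            f1 = 2 * precision * recall / (precision + recall)
        elif precision == recall == 0:
            f1 = 0.0
        else:
            f1 = None
        recalls.append(recall)
        per_class[cls] = {
            "precision": None if precision is None else _round_pct(precision),
            "recall": None if recall is None else _round_pct(recall),
            "f1": None if f1 is None else _round_pct(f1),
        }
    if any(r is None for r in recalls):
        raise ValidationError("balanced accuracy undefined: a true class is absent")
    return MetricsReport(
        per_class=per_class,
        balanced_accuracy=_round_pct(float(np.mean(recalls))),
        parameter=parameter,
    )


def crossvalidate(
    train: CohortTable,
    folds: int = 5,
    seed: int = 0,
    k: int | None = None,
    select_within_fold: bool = False,
    smote_k_neighbors: int = 5,
) -> tuple[list[MetricsReport], float]:
    """Stratified k-fold CV on the non-test subset.

    Per fold: (optionally re-fit the prevalence filter and k-best on the
    fold's training part,) SMOTE the training part, fit the linear SVM and
    score the held-out fold.  Returns the per-fold reports and the mean
    unrounded balanced accuracy (percent).
    """
    if folds < 2:
        raise ValidationError("need >= 2 folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    bas: list[float] = []
    for f, (tr, va) in enumerate(skf.split(train.X, train.y)):
        y_tr = train.y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValidationError(f"fold {f}: training part lacks a class")
        cols = np.arange(train.X.shape[1])
        if select_within_fold:
            sub = CohortTable(train.X[tr], y_tr, role="train")
            rec = select_k_best(sub, k or k_rule(len(tr)), nonzero_filter(sub))
            cols = rec.kbest_indices
        fold_train = CohortTable(train.X[np.ix_(tr, cols)], y_tr, role="train")
        balanced = smote_balance(fold_train, seed=seed * 1000 + f, k_neighbors=smote_k_neighbors)
        clf = train_svm(balanced.X, balanced.y)
        pred = clf.predict(train.X[np.ix_(va, cols)])
        rep = metrics_from_confusion(ConfusionMatrix.from_labels(train.y[va], pred))
        reports.append(rep)
        cm = ConfusionMatrix.from_labels(train.y[va], pred)
        rec_nr = cm.counts[0, 0] / cm.counts[0, :].sum()
        rec_rr = cm.counts[1, 1] / cm.counts[1, :].sum()
        bas.append(50.0 * (rec_nr + rec_rr))
    return reports, float(np.mean(bas))


@dataclass
class PipelineResult:
    report: MetricsReport
    confusion: ConfusionMatrix
    selection: SelectionRecord
    split: SplitPlan
    test_predictions: np.ndarray | None = None
    cv_reports: list = field(default_factory=list)
    cv_mean_balanced_accuracy: float | None = None


def evaluate_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    parameter: str | None = None,
    seed: int = 0,
    nonzero_threshold: float = 0.90,
    k: int | None = None,
    smote_k_neighbors: int = 5,
    run_cv: bool = False,
    folds: int = 5,
) -> PipelineResult:
    """Full evaluation: split -> filter/select (train only) -> SMOTE (train
    only) -> linear SVM -> unseen-test confusion matrix and metrics.

    ``k`` defaults to ``round(sqrt(n_patients))``.  All randomness derives
    from ``seed``; reruns are bit-identical.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    split = split_cohort(y, seed=seed)
    train = CohortTable(X[split.train_ids], y[split.train_ids], role="train",
                        patient_ids=split.train_ids.astype(str))
    record = nonzero_filter(train, threshold=nonzero_threshold)
    k_eff = k if k is not None else k_rule(len(y))
    record = select_k_best(train, k_eff, record)
    record.seed = seed
    cols = record.kbest_indices

    reduced = CohortTable(train.X[:, cols], train.y, role="train")
    balanced = smote_balance(reduced, seed=seed + 1, k_neighbors=smote_k_neighbors)
    clf = train_svm(balanced.X, balanced.y)
    pred = clf.predict(X[np.ix_(split.test_ids, cols)])
    cm = ConfusionMatrix.from_labels(y[split.test_ids], pred)
    report = metrics_from_confusion(cm, parameter=parameter)

    cv_reports: list = []
    cv_ba = None
    if run_cv:
        cv_reports, cv_ba = crossvalidate(
            reduced, folds=folds, seed=seed + 2, smote_k_neighbors=smote_k_neighbors
        )
        report.fold_summaries = cv_reports
    return PipelineResult(
        report=report,
        confusion=cm,
        selection=record,
        split=split,
        test_predictions=pred,
        cv_reports=cv_reports,
        cv_mean_balanced_accuracy=cv_ba,
    )
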