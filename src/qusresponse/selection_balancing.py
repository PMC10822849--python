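"""Feature selection and class rebalancing, fitted on training rows only.

The 100,352-dimension feature tables are reduced in two steps: a prevalence
filter keeping features that are nonzero in at least 90% of training
patients (rectified activations make exact zeros common), then ANOVA
F-statistic k-best selection with k = round(sqrt(n_patients)).  The
imbalanced training set (37 nonresponders vs 137 responders in the target
cohort) is then rebalanced with SMOTE: synthetic minority rows interpolated
between minority nearest neighbours.  Every fitted quantity here consumes
``role="train"`` rows exclusively; the test set never influences the
selected indices or the synthetic samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

__all__ = [
    "CohortTable",
    "SelectionRecord",
    "nonzero_filter",
    "k_rule",
    "select_k_best",
    "smote_balance",
]


@dataclass
class CohortTable:
    """Patients x features matrix with labels and a train/test role tag."""

    X: np.ndarray
    y: np.ndarray  # array of "NR" / "RR" labels
    role: str = "train"
    patient_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X))
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X rows and y labels must align 1:1")
        if self.role not in ("train", "test"):
            raise ValidationError("role must be 'train' or 'test'")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class SelectionRecord:
    """Reproducibility record of the selection pipeline."""

    nonzero_kept: np.ndarray
    threshold: float
    k: int | None = None
    kbest_indices: np.ndarray | None = None
    f_scores: np.ndarray | None = None
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "nonzero_kept": np.asarray(self.nonzero_kept).tolist(),
                "k": self.k,
                "kbest_indices": None
                if self.kbest_indices is None
                else np.asarray(self.kbest_indices).tolist(),
                "f_scores": None if self.f_scores is None else np.asarray(self.f_scores).tolist(),
                "seed": self.seed,
            }
        )


def nonzero_filter(train: CohortTable, threshold: float = 0.90) -> SelectionRecord:
    """Keep feature j iff the fraction of nonzero training entries >= threshold.

    "Nonzero" means exactly ``!= 0``; rectified activations produce genuine
    zeros, so no epsilon is applied.
    """
    if train.role != "train":
        raise ValidationError("prevalence filter must be fitted on training rows")
    if train.n == 0 or train.X.shape[1] == 0:
        raise ValidationError("empty training table")
    frac = np.count_nonzero(train.X, axis=0) / train.n
    kept = np.nonzero(frac >= threshold)[0]
    return SelectionRecord(nonzero_kept=kept, threshold=threshold)


def k_rule(n_patients: int) -> int:
    """k = round(sqrt(n)) to the nearest integer (never below 1)."""
    if n_patients < 1:
        raise ValidationError("need at least one patient")
    return max(1, int(np.floor(np.sqrt(n_patients) + 0.5)))


def select_k_best(train: CohortTable, k: int, record: SelectionRecord | None = None) -> SelectionRecord:
    """ANOVA F-test selection of the k most class-discriminative features.

    F statistics are computed between the two response classes on training
    rows (restricted to ``record.nonzero_kept`` when a filter record is
    given).  Constant features get F = 0 so they can never displace a varying
    feature; ties break toward the lower feature index.  Returned indices
    refer to the original feature space.
    """
    if train.role != "train":
        raise ValidationError("k-best selection must be fitted on training rows")
    if len(np.unique(train.y)) < 2:
        raise ValidationError("single-class training data: F statistic undefined")
    pool = np.arange(train.X.shape[1]) if record is None else np.asarray(record.nonzero_kept)
    if k > pool.size:
        raise ValidationError(f"k={k} exceeds the {pool.size} surviving features")
    X = np.asarray(train.X, dtype=np.float64)[:, pool]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(X, train.y)
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    order = np.lexsort((pool, -f_stat))  # descending F, then ascending index
    chosen = np.sort(pool[order[:k]])
    return SelectionRecord(
        nonzero_kept=pool,
        threshold=record.threshold if record is not None else 0.0,
        k=k,
        kbest_indices=chosen,
        f_scores=f_stat,
    )


def smote_balance(train: CohortTable, seed: int, k_neighbors: int = 5) -> CohortTable:
    """SMOTE oversampling of the minority class, training rows only.

    Each synthetic row is ``x + u (x_nn - x)`` with ``u ~ Uniform(0, 1)`` and
    ``x_nn`` one of the ``k_neighbors`` nearest minority neighbours of a
    randomly drawn minority row ``x`` (k shrinks to minority_size - 1 when
    necessary).  Original rows are preserved verbatim and class counts come
    out equal; fully deterministic under ``seed``.
    """
    if train.role != "train":
        raise ValidationError("SMOTE must only see training rows")
    counts = train.class_counts()
    if len(counts) != 2:
        raise ValidationError("SMOTE requires exactly two classes")
    minority = min(counts, key=counts.get)
    n_min, n_maj = counts[minority], max(counts.values())
    if n_min < 2:
        raise ValidationError("minority class of size 1: cannot interpolate")
    n_new = n_maj - n_min
    if n_new == 0:
        return CohortTable(train.X.copy(), train.y.copy(), role="train",
                           patient_ids=None if train.patient_ids is None else train.patient_ids.copy())

    Xmin = np.asarray(train.X)[train.y == minority]
    k_eff = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # column 0 is the point itself

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    neighbours = Xmin[idx[base, pick + 1]]
    synthetic = Xmin[base] + u[:, None] * (neighbours - Xmin[base])

    X_out = np.vstack([train.X, synthetic])
    y_out = np.concatenate([train.y, np.full(n_new, minority, dtype=train.y.dtype)])
    ids = None
    if train.patient_ids is not None:
        ids = np.concatenate(
            [train.patient_ids, np.array([f"SYN{i:04d}" for i in range(n_new)])]
        )
    return CohortTable(X_out, y_out, role="train", patient_ids=ids)
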