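"""Confusion matrices, per-class recall/precision/F1, class merging, and
the stillness-as-negative specificity framing.

Orientation convention: ``counts[t, p]`` counts windows of true class
``t`` predicted as class ``p``.  (Published tables of this layout are
often printed transposed — predicted classes as rows, true classes as
columns — see :mod:`triact.reference` for the conversion.)

Undefined ratios (0/0) are carried as ``nan`` markers, logged, and
excluded from any averaging; they never raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from triact.codes import ActivityCode, CANONICAL_CODES

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Square count matrix indexed (true class, predicted class)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.labels)
        if len(set(self.labels)) != c:
            raise ValueError("class labels must be unique")
        if self.counts.shape != (c, c):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({c}, {c})"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    # -- basic accessors ---------------------------------------------------
    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def true_totals(self) -> np.ndarray:
        """Per-class number of true (input) windows."""
        return self.counts.sum(axis=1)

    @property
    def predicted_totals(self) -> np.ndarray:
        """Per-class number of predicted (output) windows."""
        return self.counts.sum(axis=0)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot add matrices with different labels")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    def to_csv(self, path) -> None:
        """Write with a labeled header row and label column; rows are true
        classes, columns predicted classes."""
        lines = ["true\\pred," + ",".join(self.labels)]
        for lab, row in zip(self.labels, self.counts):
            lines.append(lab + "," + ",".join(str(int(v)) for v in row))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        header = lines[0].split(",")[1:]
        counts = [
            [int(v) for v in ln.split(",")[1:]] for ln in lines[1:]
        ]
        return cls(labels=tuple(header), counts=np.array(counts, dtype=int))


@dataclass
class ClassMetrics:
    """Per-class recall/precision/F1 (nan where undefined) plus overall
    accuracy."""

    labels: tuple[str, ...]
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    overall_accuracy: float

    def as_dict(self) -> dict:
        def clean(arr):
            return [None if np.isnan(v) else float(v) for v in arr]

        return {
            "labels": list(self.labels),
            "recall": clean(self.recall),
            "precision": clean(self.precision),
            "f1": clean(self.f1),
            "overall_accuracy": self.overall_accuracy,
        }


def _labels_of(truths: list) -> tuple[str, ...]:
    return tuple(c.value for c in CANONICAL_CODES)


def confusion_matrix(
    truths: list[ActivityCode],
    preds: list[ActivityCode],
    labels: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Count (true, predicted) pairs over the canonical ten-class order
    (or an explicit label tuple)."""
    if len(truths) != len(preds):
        raise ValueError(
            f"length mismatch: {len(truths)} truths vs {len(preds)} preds"
        )
    labels = labels or _labels_of(truths)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truths, preds):
        t_lab = t.value if isinstance(t, ActivityCode) else str(t)
        p_lab = p.value if isinstance(p, ActivityCode) else str(p)
        counts[index[t_lab], index[p_lab]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def per_class_metrics(matrix: ConfusionMatrix) -> ClassMetrics:
    """Recall, precision and F1 per class plus overall accuracy.

    recall_c = diag_c / true-class total; precision_c = diag_c /
    predicted-class total; f1_c = 2 r p / (r + p).  A zero denominator
    yields ``nan`` (logged), never an exception; recall/precision of 0/0
    pairs give f1 = 0 when both are defined and zero.
    """
    diag = np.diag(matrix.counts).astype(float)
    true_tot = matrix.true_totals.astype(float)
    pred_tot = matrix.predicted_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(true_tot > 0, diag / np.maximum(true_tot, 1), np.nan)
        precision = np.where(
            pred_tot > 0, diag / np.maximum(pred_tot, 1), np.nan
        )
    f1 = np.full_like(recall, np.nan)
    for i, (r, p) in enumerate(zip(recall, precision)):
        if np.isnan(r) or np.isnan(p):
            continue
        f1[i] = 2 * r * p / (r + p) if (r + p) > 0 else 0.0
    for i, lab in enumerate(matrix.labels):
        if np.isnan(recall[i]) or np.isnan(precision[i]):
            logger.info("metrics undefined for class %s (0/0)", lab)
    return ClassMetrics(
        labels=matrix.labels,
        recall=recall,
        precision=precision,
        f1=f1,
        overall_accuracy=overall_accuracy(matrix),
    )


def overall_accuracy(matrix: ConfusionMatrix) -> float:
    """Trace over grand total."""
    total = matrix.grand_total
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(matrix.counts) / total)


def merge_classes(
    matrix: ConfusionMatrix, mapping: dict[str, str]
) -> ConfusionMatrix:
    """Collapse classes through a total surjective label map.

    Merged counts are sums over preimage rows and columns; the grand
    total is conserved.  Merged labels keep the order of first appearance
    in the original label order.  Raises ``KeyError`` if the mapping
    misses a class.
    """
    merged_labels: list[str] = []
    for lab in matrix.labels:
        if lab not in mapping:
            raise KeyError(f"mapping is missing class {lab!r}")
        target = mapping[lab]
        if target not in merged_labels:
            merged_labels.append(target)
    idx = {lab: i for i, lab in enumerate(merged_labels)}
    m = len(merged_labels)
    counts = np.zeros((m, m), dtype=int)
    for i, ti in enumerate(matrix.labels):
        for j, tj in enumerate(matrix.labels):
            counts[idx[mapping[ti]], idx[mapping[tj]]] += matrix.counts[i, j]
    return ConfusionMatrix(labels=tuple(merged_labels), counts=counts)


def specificity_vs_negative(
    matrix: ConfusionMatrix, negative: str = "NA"
) -> float:
    """Fraction of true negative-class windows predicted as the negative
    class (the negative class's recall), with all other classes pooled as
    positive."""
    if negative not in matrix.labels:
        raise KeyError(f"negative class {negative!r} not in matrix")
    i = matrix.index_of(negative)
    total = matrix.true_totals[i]
    if total == 0:
        raise ValueError(f"no true {negative!r} windows in matrix")
    return float(matrix.counts[i, i] / total)


def column_percent_matrix(matrix: ConfusionMatrix) -> np.ndarray:
    """Percent distribution of predictions within each true class.

    Returned in (true, predicted) orientation: every row sums to 100.
    (In the transposed published layout these are the columns that "make
    100% in total".)  Raises ``ValueError`` on an empty true class.
    """
    totals = matrix.true_totals.astype(float)
    if (totals == 0).any():
        empty = [l for l, t in zip(matrix.labels, totals) if t == 0]
        raise ValueError(f"empty true class(es): {empty}")
    return 100.0 * matrix.counts / totals[:, None]


def summarize_folds(matrices: list[ConfusionMatrix]) -> dict:
    """Pooled matrix plus mean/std of per-fold accuracy.

    The pooled (element-wise summed) matrix is what published tables
    report; the per-fold mean is provided alongside to disambiguate.
    """
    if not matrices:
        raise ValueError("no fold matrices")
    pooled = matrices[0]
    for m in matrices[1:]:
        pooled = pooled + m
    fold_acc = [overall_accuracy(m) for m in matrices]
    return {
        "pooled": pooled,
        "pooled_accuracy": overall_accuracy(pooled),
        "fold_accuracy_mean": float(np.mean(fold_acc)),
        "fold_accuracy_std": float(np.std(fold_acc)),
        "fold_accuracies": fold_acc,
    }
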