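"""Train/test splitting, confusion matrices and per-class metrics.

For a confusion matrix C with rows = true classes and columns = predicted
classes, the per-class metrics are

    precision_j = C[j][j] / sum_i C[i][j]        (PPV)
    recall_j    = C[j][j] / sum_i C[j][i]        (sensitivity)
    F_j         = 2 * precision_j * recall_j / (precision_j + recall_j)

and the summary row averages them weighted by class support (row sums), so
the support-weighted recall equals the overall accuracy.  Unweighted macro
averages are reported alongside.  Display rounding is 3 decimals, half-up.

The package ships five reference confusion matrices (CSV, one per sensor
configuration) from a published wrist/chest/ankle activity-recognition
benchmark; they serve as regression fixtures for the metric arithmetic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .errors import DomainError
from .features import FeatureMatrix

#: Names of the packaged reference confusion matrices (rotation-forest per
#: sensor, rotation-forest on fused sensors, KNN on the reduced subset).
REFERENCE_MATRICES = (
    "wrist_rotation_forest",
    "chest_rotation_forest",
    "ankle_rotation_forest",
    "all_rotation_forest",
    "selected_knn",
)


def split(
    fm: FeatureMatrix,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Disjoint, exhaustive train/test partition of the instances.

    The training set has exactly ``round(train_fraction * n)`` instances and
    the test set the remainder; the partition is reproducible for a fixed
    seed.  Stratification preserves class proportions and falls back (with a
    warning) to a plain split when some class has fewer than 2 instances.
    """
    if not 0 < train_fraction < 1:
        raise DomainError("train_fraction must be strictly between 0 and 1")
    n = len(fm)
    n_train = int(round(train_fraction * n))
    idx = np.arange(n)
    strat = fm.labels if stratified else None
    if stratified:
        _, counts = np.unique(fm.labels, return_counts=True)
        if counts.min() < 2:
            warnings.warn(
                "a class has fewer than 2 instances; falling back to a plain split",
                stacklevel=2,
            )
            strat = None
    tr, te = train_test_split(idx, train_size=n_train, random_state=seed, stratify=strat)
    return fm.take(np.sort(tr)), fm.take(np.sort(te))


@dataclass
class ConfusionMatrix:
    """Counts C[i][j]: instances of true class i predicted as class j."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise DomainError("confusion matrix must be square over the class vocabulary")
        if (self.counts < 0).any():
            raise DomainError("confusion counts must be non-negative")

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(true_labels, predicted_labels, classes=None) -> ConfusionMatrix:
    """Tally a confusion matrix; vocabulary defaults to the union of labels seen."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise DomainError("true and predicted label streams differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([true_labels, predicted_labels]))
    counts = _sk_confusion(true_labels, predicted_labels, labels=classes)
    return ConfusionMatrix(list(classes), counts)


@dataclass
class EvaluationReport:
    """Per-class and averaged precision/recall/F plus overall accuracy."""

    classes: list
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    supports: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f: float
    macro_precision: float
    macro_recall: float
    macro_f: float
    accuracy: float
    zero_division_classes: list = field(default_factory=list)
    classifier: str | None = None
    split_seed: int | None = None

    def to_dict(self, digits: int | None = 3) -> dict:
        rnd = (lambda v: round_half_up(v, digits)) if digits is not None else float
        return {
            "classifier": self.classifier,
            "split_seed": self.split_seed,
            "accuracy": rnd(self.accuracy),
            "weighted": {
                "precision": rnd(self.weighted_precision),
                "recall": rnd(self.weighted_recall),
                "f_measure": rnd(self.weighted_f),
            },
            "macro": {
                "precision": rnd(self.macro_precision),
                "recall": rnd(self.macro_recall),
                "f_measure": rnd(self.macro_f),
            },
            "per_class": {
                str(c): {
                    "precision": rnd(self.precision[i]),
                    "recall": rnd(self.recall[i]),
                    "f_measure": rnd(self.f_measure[i]),
                    "support": int(self.supports[i]),
                }
                for i, c in enumerate(self.classes)
            },
            "zero_division_classes": [str(c) for c in self.zero_division_classes],
        }

    def to_json(self, digits: int | None = 3) -> str:
        return json.dumps(self.to_dict(digits), indent=2, sort_keys=True)

    def format_table(self, class_names: dict | None = None) -> str:
        """Plain-text table: one row per class, then weighted/macro summary rows."""
        lines = [f"{'Activity':<20}{'Precision':>10}{'Recall':>10}{'F-measure':>11}{'Support':>9}"]
        for i, c in enumerate(self.classes):
            name = class_names.get(c, str(c)) if class_names else str(c)
            lines.append(
                f"{name:<20}{round_half_up(self.precision[i]):>10.3f}"
                f"{round_half_up(self.recall[i]):>10.3f}"
                f"{round_half_up(self.f_measure[i]):>11.3f}{int(self.supports[i]):>9d}"
            )
        lines.append(
            f"{'Average (weighted)':<20}{round_half_up(self.weighted_precision):>10.3f}"
            f"{round_half_up(self.weighted_recall):>10.3f}"
            f"{round_half_up(self.weighted_f):>11.3f}{int(self.supports.sum()):>9d}"
        )
        lines.append(
            f"{'Average (macro)':<20}{round_half_up(self.macro_precision):>10.3f}"
            f"{round_half_up(self.macro_recall):>10.3f}"
            f"{round_half_up(self.macro_f):>11.3f}{int(self.supports.sum()):>9d}"
        )
        return "\n".join(lines)


def round_half_up(value: float, digits: int = 3) -> float:
    """Round-half-up to ``digits`` decimals (display convention for tables)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def metrics(
    cm: ConfusionMatrix, classifier: str | None = None, split_seed: int | None = None
) -> EvaluationReport:
    """Per-class precision/recall/F and their weighted and macro averages.

    Classes with a zero denominator (no predictions, or no instances) report
    0 for the affected metric and are listed in ``zero_division_classes``.
    The support-weighted averages are the headline convention; the weighted
    recall equals the overall accuracy by construction.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise DomainError("metrics of an all-zero confusion matrix are undefined")
    diag = np.diag(counts).astype(float)
    col_sums = counts.sum(axis=0).astype(float)
    row_sums = counts.sum(axis=1).astype(float)
    zero_div = [
        c
        for c, cs, rs in zip(cm.classes, col_sums, row_sums)
        if cs == 0 or rs == 0
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col_sums > 0, diag / col_sums, 0.0)
        recall = np.where(row_sums > 0, diag / row_sums, 0.0)
        denom = precision + recall
        f_measure = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    w = row_sums / total
    return EvaluationReport(
        classes=list(cm.classes),
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        supports=row_sums.astype(np.int64),
        weighted_precision=float(precision @ w),
        weighted_recall=float(recall @ w),
        weighted_f=float(f_measure @ w),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f=float(f_measure.mean()),
        accuracy=float(diag.sum() / total),
        zero_division_classes=zero_div,
        classifier=classifier,
        split_seed=split_seed,
    )


def evaluate(model, test_fm: FeatureMatrix, split_seed: int | None = None) -> EvaluationReport:
    """Predict on a held-out matrix and compute the full report."""
    from .classifiers import predict  # local import to avoid a cycle

    predicted = predict(model, test_fm)
    cm = confusion(test_fm.labels, predicted, classes=np.unique(test_fm.labels))
    return metrics(cm, classifier=model.spec.kind, split_seed=split_seed)


def load_reference_confusion(name: str) -> ConfusionMatrix:
    """Load one of the packaged reference confusion matrices by short name."""
    if name not in REFERENCE_MATRICES:
        raise DomainError(f"unknown reference matrix {name!r}; options: {REFERENCE_MATRICES}")
    path = resources.files("actiwin.data").joinpath(f"confusion_{name}.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, index_col=0)
    return ConfusionMatrix(list(df.index), df.to_numpy())
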