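"""Classification evaluation: confusion matrix, per-class metrics, exact CI.

The confusion matrix follows the clinical-report convention with predicted
classes as rows and true classes as columns, so precision is a row statistic
and recall a column statistic.  Overall accuracy carries an exact
(Clopper-Pearson) binomial confidence interval, computed from Beta quantiles
— the same interval R's ``binom.test`` reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .io import CLASS_LABELS, ValidationError

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "per_class_metrics",
    "accuracy_with_ci",
    "EvaluationReport",
    "evaluate_predictions",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report-rendering convention)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass
class ConfusionMatrix:
    """Square count matrix: rows = predicted class, columns = true class."""

    class_order: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be square over class_order")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str] = CLASS_LABELS,
) -> ConfusionMatrix:
    """counts[i, j] = number of samples predicted as class i with true class j."""
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label lists must have equal length")
    if len(true_labels) == 0:
        raise ValidationError("empty label lists")
    class_order = list(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValidationError(f"unknown true label {t!r}")
        if p not in index:
            raise ValidationError(f"unknown predicted label {p!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(class_order, counts)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Precision (row-wise), recall (column-wise) and F1 per class.

    Degenerate classes (never predicted / never true / both metrics zero)
    score 0 by convention.  Values are full precision; round at render time.
    """
    diag = np.diag(cm.counts).astype(float)
    row_sums = cm.counts.sum(axis=1).astype(float)
    col_sums = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(row_sums > 0, diag / row_sums, 0.0)
        recall = np.where(col_sums > 0, diag / col_sums, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1}, index=cm.class_order
    )


def accuracy_with_ci(
    correct: int, total: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Accuracy with the exact (Clopper-Pearson) binomial confidence interval.

    lower = BetaQuantile(alpha/2; correct, total - correct + 1), 0 when
    correct = 0; upper = BetaQuantile(1 - alpha/2; correct + 1, total -
    correct), 1 when correct = total.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    if total < 1 or not 0 <= correct <= total:
        raise ValidationError("need 0 <= correct <= total with total >= 1")
    alpha = 1.0 - level
    accuracy = correct / total
    lower = 0.0 if correct == 0 else float(beta_dist.ppf(alpha / 2, correct, total - correct + 1))
    upper = (
        1.0 if correct == total else float(beta_dist.ppf(1 - alpha / 2, correct + 1, total - correct))
    )
    return accuracy, lower, upper


@dataclass
class EvaluationReport:
    """Confusion matrix plus the derived headline metrics."""

    confusion: ConfusionMatrix
    metrics: pd.DataFrame
    accuracy: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95

    def render(self) -> str:
        """Text table mirroring the clinical-report layout (2-decimal metrics)."""
        cm = self.confusion.to_frame()
        lines = []
        header = ["Predicted\\True"] + list(cm.columns) + ["Precision", "Recall", "F1"]
        lines.append("\t".join(header))
        for cls in cm.index:
            row = [cls] + [str(int(v)) for v in cm.loc[cls]]
            row += [
                f"{round_half_away(self.metrics.loc[cls, m], 2):.2f}"
                for m in ("precision", "recall", "f1")
            ]
            lines.append("\t".join(row))
        lines.append(
            f"Accuracy: {round_half_away(self.accuracy, 4):.4f} "
            f"(Binomial {self.level:.0%} CI {self.ci_lower:.3f}-{self.ci_upper:.3f})"
        )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_order": self.confusion.class_order,
                "confusion": self.confusion.counts.tolist(),
                "metrics": self.metrics.to_dict(orient="index"),
                "accuracy": self.accuracy,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "level": self.level,
            },
            indent=1,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def evaluate_predictions(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str] = CLASS_LABELS,
    level: float = 0.95,
) -> EvaluationReport:
    """Full evaluation from raw label lists."""
    cm = confusion_matrix(true_labels, predicted_labels, class_order)
    metrics = per_class_metrics(cm)
    accuracy, lower, upper = accuracy_with_ci(cm.correct, cm.total, level)
    return EvaluationReport(cm, metrics, accuracy, lower, upper, level)
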