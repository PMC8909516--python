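"""Confusion-matrix accuracy assessment.

The confusion matrix is stored with rows = predicted (classified) class and
columns = reference class, the layout conventional in land-cover accuracy
assessment: the diagonal holds agreements, a row sum is the number of pixels
assigned to a class, a column sum the number truly in it. From it derive

    accuracy_i  = (TP_i + TN_i) / n            per-class binary accuracy
    precision_i = TP_i / (TP_i + FP_i)         = user's accuracy (row-wise)
    recall_i    = TP_i / (TP_i + FN_i)         = producer's accuracy (column-wise)
    F1_i        = 2 * precision_i * recall_i / (precision_i + recall_i)

plus overall accuracy (trace / n) and Cohen's kappa, the chance-corrected
agreement (p_o - p_e) / (1 - p_e) with p_e computed from the marginals.

Undefined ratios (0/0 on an empty row or column) are reported as NaN, never
silently as 0, and are excluded from any macro average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    """k x k count table; counts[p][r] = #{samples predicted p, truly r}."""

    counts: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix must contain at least one sample")
        if not self.class_names:
            self.class_names = tuple(f"class_{i}" for i in range(len(self.counts)))

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    """All per-class and overall metrics of one confusion matrix.

    Fractions in [0, 1]; kappa in [-1, 1]; undefined entries are NaN.
    """

    class_names: tuple[str, ...]
    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    users_accuracy: np.ndarray
    producers_accuracy: np.ndarray
    overall_accuracy: float
    kappa: float


def confusion(y_true: np.ndarray, y_pred: np.ndarray, k: int,
              class_names: tuple[str, ...] = ()) -> ConfusionMatrix:
    """Count table from paired label vectors with values in 0..k-1."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if (y_true < 0).any() or (y_true >= k).any() or (y_pred < 0).any() or (y_pred >= k).any():
        raise ValueError(f"labels must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_pred, y_true), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(cm: ConfusionMatrix, i: int) -> tuple[float, float, float, float]:
    """(accuracy_i, precision_i, recall_i, f1_i) for class i."""
    if not 0 <= i < cm.k:
        raise IndexError(f"class {i} out of range 0..{cm.k - 1}")
    c = cm.counts
    tp = float(c[i, i])
    fp = float(c[i, :].sum() - tp)
    fn = float(c[:, i].sum() - tp)
    tn = float(cm.n - tp - fp - fn)
    accuracy = (tp + tn) / cm.n
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = f1_score(precision, recall)
    return accuracy, precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (NaN if either is undefined)."""
    if np.isnan(precision) or np.isnan(recall):
        return float("nan")
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of all samples on the diagonal."""
    return float(np.trace(cm.counts)) / cm.n


def users_producers(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-class (user's accuracy, producer's accuracy) = (row, column) identity rates."""
    c = cm.counts.astype(float)
    diag = np.diag(c)
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), np.nan)
        producers = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), np.nan)
    return users, producers


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from the matrix marginals.

    Returns 1.0 in the degenerate case p_e = 1 (all mass in one agreeing
    cell), where agreement is perfect but chance-corrected agreement is 0/0.
    """
    c = cm.counts.astype(float)
    n = cm.n
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    """Every metric of the report for one confusion matrix."""
    per_class = [class_metrics(cm, i) for i in range(cm.k)]
    users, producers = users_producers(cm)
    return MetricReport(
        class_names=cm.class_names,
        accuracy=np.array([m[0] for m in per_class]),
        precision=np.array([m[1] for m in per_class]),
        recall=np.array([m[2] for m in per_class]),
        f1=np.array([m[3] for m in per_class]),
        users_accuracy=users,
        producers_accuracy=producers,
        overall_accuracy=overall_accuracy(cm),
        kappa=kappa(cm),
    )


def format_report(cm: ConfusionMatrix, report: MetricReport | None = None) -> str:
    """Pretty table in the classified-rows / reference-columns layout."""
    report = report if report is not None else metric_report(cm)
    names = list(cm.class_names)
    width = max(14, max(len(n) for n in names) + 2)
    head = "Classified".ljust(width) + "".join(n.rjust(width) for n in names)
    head += "Total".rjust(width) + "User's Acc.".rjust(width)
    lines = [head]
    for i, name in enumerate(names):
        row = name.ljust(width)
        row += "".join(str(int(v)).rjust(width) for v in cm.counts[i])
        row += str(int(cm.counts[i].sum())).rjust(width)
        row += _pct(report.users_accuracy[i]).rjust(width)
        lines.append(row)
    totals = "Total".ljust(width)
    totals += "".join(str(int(v)).rjust(width) for v in cm.counts.sum(axis=0))
    totals += str(cm.n).rjust(width)
    lines.append(totals)
    prod = "Producer's Acc.".ljust(width)
    prod += "".join(_pct(v).rjust(width) for v in report.producers_accuracy)
    lines.append(prod)
    lines.append(
        f"Overall Accuracy {_pct(report.overall_accuracy)}    "
        f"Kappa {_pct(report.kappa)}"
    )
    return "\n".join(lines)


def report_to_csv(cm: ConfusionMatrix, report: MetricReport | None = None) -> str:
    """Delimited per-class metric table plus overall accuracy and kappa."""
    report = report if report is not None else metric_report(cm)
    lines = ["class,accuracy,precision,recall,f1,users_accuracy,producers_accuracy"]
    for i, name in enumerate(report.class_names):
        lines.append(
            f"{name},{report.accuracy[i]:.6f},{report.precision[i]:.6f},"
            f"{report.recall[i]:.6f},{report.f1[i]:.6f},"
            f"{report.users_accuracy[i]:.6f},{report.producers_accuracy[i]:.6f}"
        )
    lines.append(f"overall_accuracy,{report.overall_accuracy:.6f},,,,,")
    lines.append(f"kappa,{report.kappa:.6f},,,,,")
    return "\n".join(lines)


def _pct(x: float) -> str:
    return "nan" if np.isnan(x) else f"{100.0 * x:.2f}%"
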