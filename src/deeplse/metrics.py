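"""Confusion-matrix statistics for imbalanced binary classification.

Implements the metric suite conventionally used for skewed protein
classification benchmarks: sensitivity (recall), specificity, precision,
accuracy, Matthews correlation coefficient (MCC), balanced accuracy
(BACC), Youden's index (YI), F1, and Cohen's kappa via the observed /
expected agreement pair (Po, Pe).  Reconstruction quality is reported on
a decibel scale, ``-10*log10(MSE)``, which for unit-range features equals
PSNR with peak 1.

Zero-denominator cases (e.g. no predicted positives) are reported as NaN
("undefined") rather than coerced to 0, and aggregation over repeated
trials skips undefined values while counting how many were skipped —
silent zeros would distort means in small-trial ablations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "compute_confusion",
    "compute_metrics",
    "bacc_from_rates",
    "youden_from_rates",
    "mse_db",
    "roc_auc",
    "pr_auc",
    "aggregate_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies; positive class = antioxidant."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"{f.name} must be a nonnegative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    """Tally the confusion matrix of binary predictions against truth."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length, got {t.shape} vs {p.shape}")
    if t.size < 1:
        raise ValueError("need at least one sample")
    for name, v in (("true", t), ("predicted", p)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


@dataclass(frozen=True)
class MetricReport:
    """The derived statistics; NaN marks an undefined (0/0) metric."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    balanced_accuracy: float
    youdens_index: float
    f1: float
    po: float
    pe: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {k: (round(v, ndigits) if math.isfinite(v) else v) for k, v in self.as_dict().items()}


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Derive all eleven statistics from the confusion counts."""
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    n = tp + fp + tn + fn

    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    acc = (tp + tn) / n

    mcc_den = math.sqrt((tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)

    bacc = (sn + sp) / 2
    yi = sn + sp - 1
    f1 = _ratio(2 * prec * sn, prec + sn) if math.isfinite(prec) and math.isfinite(sn) else float("nan")

    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    kappa = _ratio(po - pe, 1 - pe)

    return MetricReport(
        sensitivity=sn,
        specificity=sp,
        precision=prec,
        accuracy=acc,
        mcc=mcc,
        balanced_accuracy=bacc,
        youdens_index=yi,
        f1=f1,
        po=po,
        pe=pe,
        kappa=kappa,
    )


def bacc_from_rates(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy from already-computed class recalls."""
    return (sensitivity + specificity) / 2


def youden_from_rates(sensitivity: float, specificity: float) -> float:
    """Youden's index from already-computed class recalls."""
    return sensitivity + specificity - 1


def mse_db(original: np.ndarray, decoded: np.ndarray) -> float:
    """Reconstruction error as ``-10*log10(MSE)`` decibels (larger is better).

    Identical inputs give ``inf`` (zero error), reported as such.
    """
    a = np.asarray(original, dtype=np.float64)
    b = np.asarray(decoded, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return -10.0 * math.log10(mse)


def roc_auc(true_labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve of the positive-class scores."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(np.asarray(true_labels), np.asarray(scores)))


def pr_auc(true_labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the precision-recall curve."""
    from sklearn.metrics import auc, precision_recall_curve

    prec, rec, _ = precision_recall_curve(np.asarray(true_labels), np.asarray(scores))
    return float(auc(rec, prec))


def aggregate_reports(
    reports: Iterable[Mapping[str, float] | MetricReport],
) -> dict[str, dict[str, float]]:
    """Mean/std per metric over trials, skipping undefined values.

    Returns ``{metric: {"mean":, "std":, "n":, "n_undefined":}}``; std is
    the population standard deviation over the defined trials.
    """
    dicts = [r.as_dict() if isinstance(r, MetricReport) else dict(r) for r in reports]
    if not dicts:
        raise ValueError("no reports to aggregate")
    out: dict[str, dict[str, float]] = {}
    for key in dicts[0]:
        vals = np.array([d[key] for d in dicts], dtype=np.float64)
        ok = np.isfinite(vals)
        defined = vals[ok]
        out[key] = {
            "mean": float(defined.mean()) if defined.size else float("nan"),
            "std": float(defined.std()) if defined.size else float("nan"),
            "n": int(defined.size),
            "n_undefined": int(vals.size - defined.size),
        }
    return out
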