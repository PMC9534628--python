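"""Confusion-count bookkeeping, the metric suite, and 10-fold CV.

Metrics follow the Chou-style error-rate formulation common in protein
predictor papers.  With H+ true positives-in-truth (DBPs), H- true
negatives-in-truth, fp non-DBPs mispredicted as DBPs and fn DBPs
mispredicted as non-DBPs:

    Acc = 1 - (fn + fp) / (H+ + H-)
    Sn  = 1 - fn / H+
    Sp  = 1 - fp / H-
    MCC = (1 - (fn/H+ + fp/H-))
          / sqrt((1 + (fp - fn)/H+) * (1 + (fn - fp)/H-))

which is algebraically identical to the standard
(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) form.  Metrics
whose denominator is empty are reported as NaN (undefined), never
silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from sklearn.model_selection import StratifiedKFold

from dbp_idwt.modeling import LabeledDataset, ModelConfig, TrainedModel, predict, train


@dataclass
class ConfusionCounts:
    """h_pos/h_neg are the true class sizes; fp and fn the two error
    counts (non-DBPs called DBP and DBPs called non-DBP)."""

    h_pos: int
    h_neg: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.h_pos, self.h_neg, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.fp > self.h_neg or self.fn > self.h_pos:
            raise ValueError("error counts cannot exceed their class sizes")

    @property
    def tp(self) -> int:
        return self.h_pos - self.fn

    @property
    def tn(self) -> int:
        return self.h_neg - self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            h_pos=int((y_true == 1).sum()),
            h_neg=int((y_true == 0).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricsReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the full metric suite from confusion counts.

    Sn/Sp/MCC require both classes to be present; precision requires at
    least one positive call and F1 a nonzero precision + recall — each
    is NaN otherwise.
    """
    total = c.h_pos + c.h_neg
    acc = 1.0 - (c.fn + c.fp) / total if total else math.nan
    sn = 1.0 - c.fn / c.h_pos if c.h_pos else math.nan
    sp = 1.0 - c.fp / c.h_neg if c.h_neg else math.nan
    if c.h_pos and c.h_neg:
        num = 1.0 - (c.fn / c.h_pos + c.fp / c.h_neg)
        den = (1.0 + (c.fp - c.fn) / c.h_pos) * (1.0 + (c.fn - c.fp) / c.h_neg)
        mcc = num / math.sqrt(den) if den > 0 else math.nan
    else:
        mcc = math.nan
    predicted_pos = c.tp + c.fp
    precision = c.tp / predicted_pos if predicted_pos else math.nan
    recall = sn
    if (
        not math.isnan(precision)
        and not math.isnan(recall)
        and precision + recall > 0
    ):
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = math.nan
    return MetricsReport(acc, sn, sp, mcc, precision, recall, f1)


def _mean_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Field-wise arithmetic mean of per-fold reports (NaN-aware)."""
    values = {
        f.name: float(np.nanmean([getattr(r, f.name) for r in reports]))
        for f in fields(MetricsReport)
    }
    return MetricsReport(**values)


@dataclass
class CvResult:
    mean_report: MetricsReport
    fold_reports: list[MetricsReport]
    fold_counts: list[ConfusionCounts]
    fold_indices: list[np.ndarray]

    @property
    def pooled_report(self) -> MetricsReport:
        pooled = ConfusionCounts(
            h_pos=sum(c.h_pos for c in self.fold_counts),
            h_neg=sum(c.h_neg for c in self.fold_counts),
            fp=sum(c.fp for c in self.fold_counts),
            fn=sum(c.fn for c in self.fold_counts),
        )
        return compute_metrics(pooled)


def ten_fold_cv(
    config: ModelConfig,
    dataset: LabeledDataset,
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[MetricsReport, CvResult]:
    """Stratified k-fold cross-validation (default 10 folds).

    Folds partition the dataset — each sample is tested exactly once —
    and are stratified by label with seed-controlled shuffling.  The
    headline report is the arithmetic mean of per-fold metrics; the
    pooled-confusion alternative is available on the returned
    :class:`CvResult`.
    """
    counts = np.bincount(dataset.y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"{n_folds}-fold CV needs at least {n_folds} samples per class, "
            f"got {counts.tolist()}"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_reports: list[MetricsReport] = []
    fold_counts: list[ConfusionCounts] = []
    fold_indices: list[np.ndarray] = []
    for train_idx, test_idx in splitter.split(dataset.X, dataset.y):
        model = train(config, dataset.subset(train_idx))
        labels, _ = predict(model, dataset.X[test_idx])
        c = ConfusionCounts.from_predictions(dataset.y[test_idx], labels)
        fold_counts.append(c)
        fold_reports.append(compute_metrics(c))
        fold_indices.append(test_idx)
    mean_report = _mean_reports(fold_reports)
    return mean_report, CvResult(mean_report, fold_reports, fold_counts, fold_indices)


def independent_test(model: TrainedModel, dataset: LabeledDataset) -> MetricsReport:
    """Apply a trained model to a held-out dataset and score it."""
    labels, _ = predict(model, dataset.X)
    return compute_metrics(ConfusionCounts.from_predictions(dataset.y, labels))
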