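"""Confusion-matrix metrics, ROC/AUC, and the repeated subject-wise split.

Metrics are reported as percentages: accuracy, recall (sensitivity),
precision, specificity, NPV and F1.  Undefined ratios (zero denominator) are
reported as NaN rather than 0, so fold averages are never silently inflated.
The evaluation protocol is a stratified subject-level 70/30 split repeated
five times; slices never cross the train/test boundary.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

METRIC_NAMES = ("accuracy", "recall", "precision", "specificity", "npv", "f1")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    recall: float
    precision: float
    specificity: float
    npv: float
    f1: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    repeat_index: int
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]


def confusion(pred, truth) -> ConfusionCounts:
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    return ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    """The six headline metrics (percent).  NPV is TN/(TN+FN)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion table")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        recall=recall,
        precision=precision,
        specificity=_ratio(c.tn, c.tn + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        f1=f1,
    )


def roc_auc(scores, truth) -> float:
    """AUC as the normalized rank statistic (ties count 1/2), equal to the
    trapezoidal area under the ROC curve."""
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC requires both classes in the truth vector")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def roc_points(scores, truth) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) for export/plotting."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(truth).astype(int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def make_folds(
    subject_ids,
    subject_labels,
    train_fraction: float = 0.7,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[FoldSplit]:
    """Repeated stratified subject-level splits (fresh random draw each repeat)."""
    ids = np.asarray(subject_ids)
    labels = np.asarray(subject_labels)
    if ids.shape != labels.shape:
        raise ValueError("subject_ids and subject_labels must align")
    for cls in np.unique(labels):
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 subjects")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed
    )
    folds = []
    for k, (tr, te) in enumerate(splitter.split(ids, labels), start=1):
        folds.append(
            FoldSplit(
                repeat_index=k,
                train_subjects=tuple(ids[tr]),
                test_subjects=tuple(ids[te]),
            )
        )
    return folds


def summarize_folds(reports: list[MetricsReport], ddof: int = 1) -> pd.DataFrame:
    """Per-metric mean and std across folds (sample std by default).

    A single report yields std 0 and ``single_fold=True``.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    single = len(reports) == 1
    for name in METRIC_NAMES + ("auc",):
        values = np.array([getattr(r, name) for r in reports], dtype=float)
        valid = values[~np.isnan(values)]
        if valid.size == 0:
            mean = std = float("nan")
        else:
            mean = float(valid.mean())
            std = 0.0 if valid.size == 1 else float(valid.std(ddof=ddof))
        rows.append({"metric": name, "mean": mean, "std": std, "single_fold": single})
    return pd.DataFrame(rows).set_index("metric")
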