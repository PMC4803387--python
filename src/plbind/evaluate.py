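"""ROC/AUC, MCC, sensitivity/specificity and stratified cross-validation."""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from . import learners
from .profiles import LabeledDataset

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "UndefinedMetricError",
    "StratificationError",
    "roc_auc",
    "confusion_from_scores",
    "confusion_metrics",
    "cross_validate",
    "holdout_split",
    "write_report_json",
    "write_report_tsv",
    "write_roc_tsv",
    "plot_roc",
]


class UndefinedMetricError(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclasses.dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclasses.dataclass
class EvalReport:
    folds: list[dict]  # per-fold sensitivity/specificity/mcc/auc
    pooled: dict  # same keys, over concatenated held-out scores
    roc: np.ndarray  # (n_points, 2) of (FPR, TPR)
    threshold: float
    n_examples: int


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve over all score thresholds and its trapezoidal area.

    The area equals the normalized Mann-Whitney statistic with ties counted
    as one half.  Curve points are (FPR, TPR), from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if np.unique(labels).size < 2:
        raise UndefinedMetricError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def confusion_from_scores(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (labels == 1))),
        FP=int(np.sum(pred & (labels == 0))),
        TN=int(np.sum(~pred & (labels == 0))),
        FN=int(np.sum(~pred & (labels == 1))),
    )


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, MCC); MCC is 0 when a factor is zero."""
    if counts.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("sensitivity/specificity need both classes")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sens, spec, mcc


def _fold_metrics(scores, labels, threshold) -> dict:
    _, auc = roc_auc(scores, labels)
    sens, spec, mcc = confusion_metrics(confusion_from_scores(scores, labels, threshold))
    return {"sensitivity_pct": sens, "specificity_pct": spec, "mcc": mcc, "auc": auc}


def cross_validate(
    data: LabeledDataset,
    params: learners.HyperParams,
    folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV; pooled ROC over concatenated held-out scores.

    The operating threshold for sensitivity/specificity/MCC is fixed by
    score type: 0 for SVM decision values, 0.5 for NN/RF probabilities.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(data.y, dtype=int)
    if folds == len(y):
        # leave-one-out: stratification is impossible; per-fold metrics are
        # undefined for single-example folds, only the pooled curve is reported
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        for cls in (0, 1):
            if int(np.sum(y == cls)) < folds:
                raise StratificationError(f"class {cls} has fewer examples than folds")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    threshold = learners.default_threshold(params.algorithm)

    pooled_scores = np.zeros(len(y))
    fold_reports = []
    for train_idx, test_idx in splitter.split(data.X, y):
        model = learners.train((data.X[train_idx], y[train_idx]), params, seed=seed)
        s = learners.score(model, data.X[test_idx])
        pooled_scores[test_idx] = s
        if np.unique(y[test_idx]).size == 2:
            fold_reports.append(_fold_metrics(s, y[test_idx], threshold))

    curve, auc = roc_auc(pooled_scores, y)
    sens, spec, mcc = confusion_metrics(confusion_from_scores(pooled_scores, y, threshold))
    pooled = {"sensitivity_pct": sens, "specificity_pct": spec, "mcc": mcc, "auc": auc}
    return EvalReport(
        folds=fold_reports, pooled=pooled, roc=curve, threshold=threshold, n_examples=len(y)
    )


def holdout_split(
    data: LabeledDataset, test_fraction: float = 0.15, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random train/test split, reproducible by seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(len(data.y))
    try:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, random_state=seed, stratify=data.y
        )
    except ValueError as exc:
        raise StratificationError(str(exc)) from None
    for part in (train_idx, test_idx):
        if np.unique(data.y[part]).size < 2:
            raise StratificationError("split leaves a class empty")

    def subset(sel):
        sel = np.sort(sel)
        return LabeledDataset(
            X=data.X[sel], y=data.y[sel], meta=[data.meta[i] for i in sel], w=data.w
        )

    return subset(train_idx), subset(test_idx)


def _round_report(report: EvalReport, digits: int = 6) -> dict:
    def rd(d):
        return {k: round(float(v), digits) for k, v in d.items()}

    return {
        "threshold": report.threshold,
        "n_examples": report.n_examples,
        "pooled": rd(report.pooled),
        "folds": [rd(f) for f in report.folds],
    }


def write_report_json(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_report(report), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_report_tsv(report: EvalReport, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["fold", "sensitivity_pct", "specificity_pct", "mcc", "auc"])
        for i, f in enumerate(report.folds, start=1):
            w.writerow([i] + [f"{f[k]:.6f}" for k in ("sensitivity_pct", "specificity_pct", "mcc", "auc")])
        w.writerow(
            ["pooled"]
            + [f"{report.pooled[k]:.6f}" for k in ("sensitivity_pct", "specificity_pct", "mcc", "auc")]
        )


def write_roc_tsv(report: EvalReport, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["fpr", "tpr"])
        for fpr, tpr in report.roc:
            w.writerow([f"{fpr:.6f}", f"{tpr:.6f}"])


def plot_roc(reports: dict[str, EvalReport], path) -> None:
    """ROC figure (FPR on x, TPR on y), one labelled curve per report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        ax.plot(rep.roc[:, 0], rep.roc[:, 1], label=f"{name} (AUC={rep.pooled['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate (FPR)")
    ax.set_ylabel("True positive rate (TPR)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
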