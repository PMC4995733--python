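"""Cross-validated evaluation: SN / SP / ACC / MCC, ROC and AUC.

Metric definitions, with TP/TN/FP/FN counted against the redox-sensitive
(+1) class as positive:

    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 when any factor of its denominator vanishes (the
standard convention for the otherwise-undefined case).  ROC curves come
from a full threshold sweep over the distinct decision scores, with tied
scores grouped into one step, and AUC is the trapezoidal integral.

Cross-validation is stratified with a seeded shuffle.  Two ROC summaries
are produced: the pooled-scores curve over all folds, and a fold-averaged
curve obtained by interpolating each fold's TPR on a common 101-point FPR
grid and averaging pointwise.  Both AUCs are reported and labelled, along
with the mean of per-fold AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import model as _model
from .seqio import NEGATIVE, POSITIVE, CysteineSite, SiteTable

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ROCCurve",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_and_auc",
    "cross_validate",
    "evaluate_by_group",
    "sample_balanced_negatives",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclass(frozen=True)
class MetricSet:
    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {"SN": self.SN, "SP": self.SP, "ACC": self.ACC, "MCC": self.MCC, "AUC": self.AUC}


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """2x2 confusion counts with +1 as the positive class."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        bad = set(np.unique(arr)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"{name} contains labels outside {{+1,-1}}: {sorted(bad)}")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == -1) & (yp == -1))),
        FP=int(np.sum((yt == -1) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == -1))),
    )


def metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """Sensitivity, specificity, accuracy and Matthews correlation."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricSet(SN=float(sn), SP=float(sp), ACC=float(acc), MCC=float(mcc), AUC=auc)


@dataclass
class ROCCurve:
    """(FPR, TPR) points from a threshold sweep, plus trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_and_auc(scores: Sequence[float], y_true: Sequence[int]) -> ROCCurve:
    """ROC by sweeping a threshold over the distinct scores (ties grouped).

    The curve starts at (0,0) and ends at (1,1); AUC is its trapezoidal
    integral, which equals the Mann-Whitney two-sample rank statistic
    normalised by n+ * n-.
    """
    s = np.asarray(scores, dtype=float)
    yt = np.asarray(y_true, dtype=int)
    if s.shape != yt.shape or s.ndim != 1:
        raise ValueError("scores and y_true must be 1-D of equal length")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], yt[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == -1)
    # keep only the last index of each tied-score run
    last_of_run = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp[last_of_run] / n_pos]
    fpr = np.r_[0.0, fp[last_of_run] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation results.

    ``aggregate`` metrics come from pooled confusion counts over all test
    folds; its AUC is that of the fold-averaged ROC curve.  ``pooled_roc``
    uses all held-out scores at once; ``mean_fold_auc`` averages per-fold
    AUCs.  ``fold_assignment[i]`` is the fold whose test split held
    sample i.
    """

    fold_metrics: list[MetricSet]
    aggregate: MetricSet
    roc: ROCCurve
    pooled_roc: ROCCurve
    mean_fold_auc: float
    fold_assignment: np.ndarray
    seed: int
    k: int
    y_true: np.ndarray = field(repr=False, default=None)
    y_pred: np.ndarray = field(repr=False, default=None)
    scores: np.ndarray = field(repr=False, default=None)
    per_group: pd.DataFrame | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i, **m.as_dict()) for i, m in enumerate(self.fold_metrics)]
        rows.append(dict(fold="aggregate", **self.aggregate.as_dict()))
        return pd.DataFrame(rows)


def _average_roc(fold_curves: list[ROCCurve], n_grid: int = 101) -> ROCCurve:
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, c.fpr, c.tpr) for c in fold_curves])
    mean_tpr = tprs.mean(axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ROCCurve(fpr=grid, tpr=mean_tpr, auc=float(np.trapezoid(mean_tpr, grid)))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    trainer: Callable[[np.ndarray, np.ndarray, int], _model.TrainedModel],
    k: int = 10,
    seed: int = 0,
    groups: Sequence[str | None] | None = None,
    min_group_positives: int = 10,
) -> EvalReport:
    """Seeded stratified k-fold evaluation of an arbitrary trainer.

    ``trainer(X_train, y_train, seed)`` must return a model applicable
    through :func:`redoxcys.model.predict` to full-width feature rows
    (internal feature selection travels inside the model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k > len(y):
        raise ValueError(f"k={k} exceeds sample count {len(y)}")
    class_counts = [int(np.sum(y == c)) for c in (-1, 1)]
    if min(class_counts) < k:
        raise ValueError(
            f"cannot stratify {k} folds with class counts {class_counts}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.full(len(y), -1, dtype=int)
    y_pred = np.zeros(len(y), dtype=int)
    scores = np.zeros(len(y), dtype=float)
    fold_metrics: list[MetricSet] = []
    fold_curves: list[ROCCurve] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fitted = trainer(X[tr], y[tr], seed)
        labels, sc = _model.predict(fitted, X[te])
        fold_assignment[te] = fold
        y_pred[te], scores[te] = labels, sc
        counts = confusion(y[te], labels)
        pooled = pooled + counts
        curve = roc_and_auc(sc, y[te])
        fold_curves.append(curve)
        fold_metrics.append(metrics(counts, auc=curve.auc))
    avg_roc = _average_roc(fold_curves)
    pooled_roc = roc_and_auc(scores, y)
    aggregate = metrics(pooled, auc=avg_roc.auc)
    per_group = None
    if groups is not None:
        per_group = evaluate_by_group(y, y_pred, groups, min_positives=min_group_positives)
    return EvalReport(
        fold_metrics=fold_metrics,
        aggregate=aggregate,
        roc=avg_roc,
        pooled_roc=pooled_roc,
        mean_fold_auc=float(np.mean([c.auc for c in fold_curves])),
        fold_assignment=fold_assignment,
        seed=seed,
        k=k,
        y_true=y,
        y_pred=y_pred,
        scores=scores,
        per_group=per_group,
    )


def evaluate_by_group(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    groups: Sequence[str | None],
    min_positives: int = 10,
) -> pd.DataFrame:
    """Per-group confusion and metrics (gene-family style breakdown).

    Groups with fewer than ``min_positives`` positive sites are suppressed
    from the table; a "Total" row over all samples is always included.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    tags = np.asarray([g if g is not None else "ungrouped" for g in groups], dtype=object)
    rows = []
    for g in sorted(set(tags.tolist())):
        mask = tags == g
        n_pos = int(np.sum(yt[mask] == 1))
        if n_pos < min_positives:
            continue
        m = metrics(confusion(yt[mask], yp[mask]))
        rows.append(dict(group=g, n_cys=int(mask.sum()), **m.as_dict()))
    total = metrics(confusion(yt, yp))
    rows.append(dict(group="Total", n_cys=len(yt), **total.as_dict()))
    return pd.DataFrame(rows).drop(columns=["AUC"])


def sample_balanced_negatives(site_table: SiteTable, seed: int = 0) -> SiteTable:
    """Balanced dataset: all positives plus an equal-size seeded uniform
    sample of the negatives, preserving the input ordering."""
    positives = site_table.positives()
    negatives = site_table.negatives()
    if len(negatives) < len(positives):
        raise ValueError(
            f"need >= {len(positives)} negatives to balance, have {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(negatives), size=len(positives), replace=False)
    chosen = {(negatives[i].protein_id, negatives[i].position) for i in chosen_idx}
    keep = [
        s
        for s in site_table
        if s.label == POSITIVE
        or (s.label == NEGATIVE and (s.protein_id, s.position) in chosen)
    ]
    return SiteTable(keep)
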