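"""SVM-based recursive feature elimination (SVM-RFE).

Backward elimination for the RBF-kernel SVM: at each iteration an SVM is
trained on the surviving features, every surviving feature f is scored by
the change in the trained dual objective

    W2(alpha) = sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j)

when the kernel is recomputed without f while the dual coefficients are
held fixed (the standard nonlinear generalisation of the linear-SVM
weight criterion), and the lowest-scoring features are removed.  Ties are
broken by eliminating the lower feature index first.  The final ranking
is the reverse of the elimination order.

A held-out split (default 20 %, seeded, stratified) tracks the validation
error rate along the elimination path; it is logged per iteration and
never drives which feature is removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .evaluate import EvalReport, cross_validate
from .model import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    SVMParams,
    grid_search,
    scale_apply,
    scale_fit,
    train_svm,
)

__all__ = [
    "RankedFeatures",
    "CountCurve",
    "svm_rfe",
    "select_top",
    "performance_vs_count",
]

_FEATURE_CHUNK = 64  # bounds the n_sv^2 x p scratch arrays


@dataclass
class RankedFeatures:
    """Feature ranking, best first, with the full elimination trace.

    ``elimination_log`` holds one ``(feature_index, criterion)`` entry per
    feature in elimination order (worst first); ``validation_errors`` has
    one held-out error rate per elimination iteration (empty when no
    validation split was requested).
    """

    order: np.ndarray
    elimination_log: list[tuple[int, float]]
    validation_errors: list[float]

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        p = self.order.size
        if sorted(self.order.tolist()) != list(range(p)):
            raise ValueError("order must be a permutation of 0..p-1")
        if len(self.elimination_log) != p:
            raise ValueError("elimination_log must have one entry per feature")

    def to_rows(self, names: Sequence[str] | None = None) -> list[tuple]:
        crit = {i: c for i, c in self.elimination_log}
        return [
            (rank + 1, int(i), names[i] if names is not None else str(i), crit[int(i)])
            for rank, i in enumerate(self.order)
        ]


@dataclass
class CountCurve:
    """Cross-validated ACC / MCC / AUC as a function of the feature count."""

    counts: np.ndarray
    acc: np.ndarray
    mcc: np.ndarray
    auc: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if not (len(self.counts) == len(self.acc) == len(self.mcc) == len(self.auc)):
            raise ValueError("count-curve arrays must be aligned")
        if np.any(np.diff(self.counts) <= 0):
            raise ValueError("counts must be strictly increasing")

    def best_count(self, by: str = "auc") -> int:
        arr = getattr(self, by)
        return int(self.counts[int(np.argmax(arr))])


def _dual_objective_drops(
    X_surv: np.ndarray,
    svc: SVC,
    gamma: float,
) -> np.ndarray:
    """|W2 - W2_without_f| for every column of ``X_surv``, alpha frozen.

    ``X_surv`` must be exactly the (scaled, surviving-column) matrix the
    SVC was fitted on.
    """
    sv = svc.support_
    dual = svc.dual_coef_[0].astype(np.float32)  # alpha_i * y_i, signed
    # float32 suffices: the drops only order features, and the ordering is
    # computed identically on every rerun
    Xsv = X_surv[sv].astype(np.float32)
    d2 = (Xsv[:, None, :] - Xsv[None, :, :]) ** 2  # n_sv x n_sv x p_surv
    D2 = d2.sum(axis=2)
    K = np.exp(-np.float32(gamma) * D2)
    base = dual @ K @ dual
    p_surv = X_surv.shape[1]
    drops = np.empty(p_surv)
    for start in range(0, p_surv, _FEATURE_CHUNK):
        stop = min(start + _FEATURE_CHUNK, p_surv)
        K_wo = np.exp(-np.float32(gamma) * (D2[:, :, None] - d2[:, :, start:stop]))
        w2_wo = np.einsum("i,ijf,j->f", dual, K_wo, dual)
        drops[start:stop] = 0.5 * np.abs(np.float64(w2_wo) - np.float64(base))
    return drops


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    svm_params: SVMParams | None = None,
    step: int = 1,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> RankedFeatures:
    """Rank features by recursive elimination under the RBF-SVM.

    Features are scaled to [-1, 1] internally (fit on the elimination
    training part).  ``step`` features are removed per iteration; the
    default of one is affordable up to a few hundred features.  When
    ``svm_params`` is omitted, C=1 and gamma=1/p are used — with scaled
    features this matches the usual kernel-width heuristic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 features")
    if len(set(np.unique(y))) < 2:
        raise ValueError("y has a single class; cannot rank features")
    if step < 1:
        raise ValueError("step must be a positive integer")
    p = X.shape[1]
    params = svm_params if svm_params is not None else SVMParams(C=1.0, gamma=1.0 / p)
    if not params.squared:
        raise ValueError("RFE criterion is defined for the squared-norm kernel")
    if validation_fraction > 0:
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=validation_fraction, stratify=y, random_state=seed
        )
    else:
        X_tr, y_tr = X, y
        X_val = y_val = None
    scaling = scale_fit(X_tr)
    Xs = scale_apply(scaling, X_tr)
    Xs_val = scale_apply(scaling, X_val) if X_val is not None else None

    surviving = np.arange(p)
    eliminated: list[tuple[int, float]] = []
    validation_errors: list[float] = []
    while surviving.size > 0:
        svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        svc.fit(Xs[:, surviving], y_tr)
        if Xs_val is not None:
            err = float(np.mean(svc.predict(Xs_val[:, surviving]) != y_val))
            validation_errors.append(err)
        if surviving.size == 1:
            # removing the only feature collapses the kernel to all-ones
            sv = svc.support_
            dual = svc.dual_coef_[0]
            d = Xs[sv][:, surviving]
            K = np.exp(-params.gamma * (d[:, None, 0] - d[None, :, 0]) ** 2)
            drop = 0.5 * abs(dual @ K @ dual - dual.sum() ** 2)
            eliminated.append((int(surviving[0]), float(drop)))
            break
        drops = _dual_objective_drops(Xs[:, surviving], svc, params.gamma)
        n_remove = min(step, surviving.size)
        # smallest criterion first; ties -> lower feature index eliminated first
        order_local = np.lexsort((surviving, drops))
        for j in order_local[:n_remove]:
            eliminated.append((int(surviving[j]), float(drops[j])))
        keep = np.ones(surviving.size, dtype=bool)
        keep[order_local[:n_remove]] = False
        surviving = surviving[keep]
    order = np.array([i for i, _ in reversed(eliminated)], dtype=int)
    return RankedFeatures(order, eliminated, validation_errors)


def select_top(ranking: RankedFeatures, k: int) -> np.ndarray:
    """The k best-ranked feature indices (in rank order)."""
    p = ranking.order.size
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    return ranking.order[:k].copy()


def performance_vs_count(
    X: np.ndarray,
    y: np.ndarray,
    ranking: RankedFeatures,
    counts: Sequence[int],
    k: int = 10,
    seed: int = 0,
    tune: bool = False,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    svm_params: SVMParams | None = None,
    tune_k: int = 5,
) -> CountCurve:
    """Cross-validated performance for each candidate feature count.

    For each count the top-ranked features are kept and an RBF-SVM is
    k-fold cross-validated (optionally re-tuned per count by an inner
    grid search on the training split of each fold).
    """
    X = np.asarray(X, dtype=float)
    counts_arr = np.asarray(sorted(set(int(c) for c in counts)), dtype=int)
    if counts_arr.size == 0:
        raise ValueError("counts must be non-empty")
    if counts_arr[0] < 1 or counts_arr[-1] > X.shape[1]:
        raise ValueError(f"counts must lie in [1, {X.shape[1]}]")
    acc, mcc, auc = [], [], []
    for count in counts_arr:
        cols = select_top(ranking, int(count))
        X_sub = X[:, cols]

        if tune:

            def trainer(Xt, yt, s):
                gs = grid_search(Xt, yt, C_grid, gamma_grid, k=tune_k, seed=s)
                return train_svm(Xt, yt, gs.best, seed=s)

        else:
            fixed = svm_params if svm_params is not None else SVMParams(
                C=1.0, gamma=1.0 / X.shape[1]
            )

            def trainer(Xt, yt, s, fixed=fixed):
                return train_svm(Xt, yt, fixed, seed=s)

        report: EvalReport = cross_validate(X_sub, y, trainer, k=k, seed=seed)
        acc.append(report.aggregate.ACC)
        mcc.append(report.aggregate.MCC)
        auc.append(report.aggregate.AUC)
    return CountCurve(counts_arr, np.array(acc), np.array(mcc), np.array(auc))
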