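"""End-to-end workflows: encode, select, tune and cross-validate.

These functions glue the module layers together the way the predictor is
meant to be run: balanced sites are encoded into a design matrix, SVM-RFE
ranks the features, an RBF-SVM is tuned on the retained features by grid
search, and everything is scored by stratified 10-fold cross-validation.

Feature selection and tuning default to running *inside* each
cross-validation fold (ranking and hyper-parameters are re-derived from
the training split only), which keeps the reported performance free of
selection leakage.  A ``whole_dataset`` selection mode — ranking once on
all data before cross-validating, as simpler historical protocols did —
is available for comparison and is expected to read optimistic.

At the pipeline level RFE removes 4 features per iteration and tuning
uses coarser x8 power-of-two grids; both are configurable and the
single-feature-step, x4-grid defaults of the underlying modules are
untouched.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .evaluate import EvalReport, cross_validate, sample_balanced_negatives
from .features import FeatureSpec, build_design_matrix
from .model import SVMParams, grid_search, train_svm
from .seqio import SiteTable
from .selection import select_top, svm_rfe
from .synth import SynthConfig, SynthDataset, generate

__all__ = [
    "PIPELINE_C_GRID",
    "PIPELINE_GAMMA_GRID",
    "rfe_svm_trainer",
    "evaluate_pipeline",
    "encode_balanced",
    "synthetic_study",
    "sweep_neighbors",
    "sweep_windows",
]

PIPELINE_C_GRID: tuple[float, ...] = tuple(float(2.0**e) for e in range(-5, 16, 3))
PIPELINE_GAMMA_GRID: tuple[float, ...] = tuple(float(2.0**e) for e in range(-15, 4, 3))
DEFAULT_RFE_STEP = 4


def rfe_svm_trainer(
    n_features: int | None = 40,
    rfe_step: int = DEFAULT_RFE_STEP,
    tune: bool = True,
    C_grid: Sequence[float] = PIPELINE_C_GRID,
    gamma_grid: Sequence[float] = PIPELINE_GAMMA_GRID,
    tune_k: int = 5,
    fixed_params: SVMParams | None = None,
    preselected: np.ndarray | None = None,
):
    """A trainer closure for :func:`redoxcys.evaluate.cross_validate`.

    Ranks features by SVM-RFE on the training split, keeps the top
    ``n_features``, tunes (C, gamma) by inner grid search, and fits the
    final SVM.  The returned model carries its selected column indices,
    so it applies directly to full-width test rows.  ``n_features=None``
    skips selection; ``preselected`` skips ranking and uses fixed column
    indices (whole-dataset selection mode).
    """

    def trainer(X_tr: np.ndarray, y_tr: np.ndarray, seed: int):
        if preselected is not None:
            cols = np.asarray(preselected, dtype=int)
        elif n_features is not None and n_features < X_tr.shape[1]:
            ranking = svm_rfe(
                X_tr, y_tr, step=rfe_step, validation_fraction=0.0, seed=seed
            )
            cols = select_top(ranking, n_features)
        else:
            cols = np.arange(X_tr.shape[1])
        X_sel = X_tr[:, cols]
        if tune:
            gs = grid_search(X_sel, y_tr, C_grid, gamma_grid, k=tune_k, seed=seed)
            params = gs.best
        else:
            params = fixed_params if fixed_params is not None else SVMParams(
                C=1.0, gamma=1.0 / X_tr.shape[1]
            )
        fitted = train_svm(X_sel, y_tr, params, seed=seed)
        fitted.selected = cols
        return fitted

    return trainer


def evaluate_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    n_features: int | None = 40,
    rfe_step: int = DEFAULT_RFE_STEP,
    k: int = 10,
    seed: int = 0,
    tune: bool = True,
    C_grid: Sequence[float] = PIPELINE_C_GRID,
    gamma_grid: Sequence[float] = PIPELINE_GAMMA_GRID,
    selection_mode: str = "fold_internal",
    groups: Sequence[str | None] | None = None,
) -> EvalReport:
    """Cross-validate the full select-tune-train pipeline on a design matrix."""
    if selection_mode not in ("fold_internal", "whole_dataset"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    preselected = None
    if selection_mode == "whole_dataset" and n_features is not None:
        ranking = svm_rfe(X, y, step=rfe_step, validation_fraction=0.0, seed=seed)
        preselected = select_top(ranking, n_features)
    trainer = rfe_svm_trainer(
        n_features=n_features,
        rfe_step=rfe_step,
        tune=tune,
        C_grid=C_grid,
        gamma_grid=gamma_grid,
        preselected=preselected,
    )
    return cross_validate(X, y, trainer, k=k, seed=seed, groups=groups)


def encode_balanced(
    table: SiteTable,
    spec: FeatureSpec,
    records: Mapping,
    pssms: Mapping | None = None,
    annotations: Mapping | None = None,
    seed: int = 0,
    balance: bool = True,
):
    """Balanced-negative sampling followed by design-matrix construction."""
    if balance:
        table = sample_balanced_negatives(table, seed=seed)
    return build_design_matrix(table, spec, records, pssms, annotations)


def synthetic_study(
    config: SynthConfig,
    spec: FeatureSpec | None = None,
    n_features: int | None = 40,
    k: int = 10,
    seed: int | None = None,
    tune: bool = True,
    **pipeline_kwargs,
) -> tuple[SynthDataset, EvalReport]:
    """Generate a dataset and run the full pipeline on it.

    ``seed`` (defaulting to the generator's) drives negative sampling,
    fold assignment and all model fitting.
    """
    if seed is None:
        seed = config.seed
    dataset = generate(config)
    spec = spec if spec is not None else FeatureSpec()
    records, pssms, annotations = dataset.registries()
    design = encode_balanced(
        dataset.site_table, spec, records, pssms, annotations, seed=seed
    )
    report = evaluate_pipeline(
        design.X,
        design.y,
        n_features=n_features,
        k=k,
        seed=seed,
        tune=tune,
        groups=design.groups,
        **pipeline_kwargs,
    )
    return dataset, report


def _cv_fixed(X, y, k, seed, params: SVMParams | None):
    fixed = params if params is not None else SVMParams(C=1.0, gamma=1.0 / max(X.shape[1], 1))

    def trainer(Xt, yt, s):
        return train_svm(Xt, yt, fixed, seed=s)

    return cross_validate(X, y, trainer, k=k, seed=seed)


def sweep_neighbors(
    table: SiteTable,
    records: Mapping,
    neighbor_grid: Sequence[int] = tuple(range(1, 11)),
    k: int = 10,
    seed: int = 0,
    params: SVMParams | None = None,
) -> list[dict]:
    """Distance-feature-only CV performance for each neighbour count."""
    rows = []
    for n in neighbor_grid:
        spec = FeatureSpec(n_neighbors=n, window=3, blocks=("D",))
        design = encode_balanced(table, spec, records, seed=seed)
        report = _cv_fixed(design.X, design.y, k, seed, params)
        rows.append(
            dict(parameter="n_neighbors", value=int(n), ACC=report.aggregate.ACC,
                 MCC=report.aggregate.MCC, AUC=report.aggregate.AUC)
        )
    return rows


def sweep_windows(
    table: SiteTable,
    records: Mapping,
    pssms: Mapping,
    annotations: Mapping,
    window_grid: Sequence[int] = tuple(range(3, 26, 2)),
    blocks: tuple[str, ...] = ("PSSM", "SS", "SA", "PCP"),
    k: int = 10,
    seed: int = 0,
    params: SVMParams | None = None,
) -> list[dict]:
    """Windowed-block CV performance for each window size."""
    rows = []
    for w in window_grid:
        spec = FeatureSpec(n_neighbors=0, window=w, blocks=blocks)
        design = encode_balanced(table, spec, records, pssms, annotations, seed=seed)
        report = _cv_fixed(design.X, design.y, k, seed, params)
        rows.append(
            dict(parameter="window", value=int(w), ACC=report.aggregate.ACC,
                 MCC=report.aggregate.MCC, AUC=report.aggregate.AUC)
        )
    return rows
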