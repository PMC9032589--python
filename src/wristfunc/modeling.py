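"""Model training and evaluation under subject-wise nested cross-validation.

All 51 task configurations (binary type, binary intensity, multiclass
activity, energy-expenditure regression; boosted trees and L1-penalized
linear models; LPP/HPP/ALL cohorts) share one harness: five outer folds
estimate generalization, five inner folds select hyperparameters, and
subjects are never shared between training and evaluation sets at any level.
Group-transfer experiments (leave-one-group-out, leave-partial-group-out)
reuse the same tuning loop.

Boosted trees are scikit-learn gradient-boosted ensembles exposing
impurity-based feature importances; L1 models standardize features with
training-fold statistics only and drop constant columns.
Class imbalance is handled with sample weights inversely proportional to
class frequency: w_c = N / (K * N_c).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.feature_selection import VarianceThreshold
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    mean_squared_error,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES
from .taxonomy import TaskSpec, enumerate_model_configs

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "EvalResult",
    "TransferResult",
    "DEFAULT_TREE_GRID",
    "DEFAULT_L1_GRID",
    "REDUCED_TREE_GRID",
    "REDUCED_L1_GRID",
    "build_design",
    "fit_boosted_trees",
    "fit_l1_linear",
    "compute_metrics",
    "nested_cv",
    "run_loo",
    "run_lpo",
    "run_all",
    "rank_importance",
]

DEFAULT_TREE_GRID: list[dict] = [
    {"max_depth": d, "n_estimators": n, "learning_rate": lr}
    for d, n, lr in itertools.product((3, 6), (100, 300), (0.05, 0.1))
]
#: 20 log-spaced L1 penalties (lambda); logistic models use C = 1/lambda.
DEFAULT_L1_GRID: list[dict] = [
    {"penalty_lambda": lam} for lam in np.logspace(-4, 1, 20)
]

# single-candidate / short grids for budgeted test runs
REDUCED_TREE_GRID: list[dict] = [
    {"max_depth": 3, "n_estimators": 50, "learning_rate": 0.1}
]
REDUCED_L1_GRID: list[dict] = [
    {"penalty_lambda": lam} for lam in np.logspace(-3, 0, 4)
]


@dataclass
class DesignMatrix:
    """Windows x features plus target, subject ids, and sample weights."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    sample_weights: np.ndarray
    feature_names: tuple[str, ...]
    task: TaskSpec
    subject_strata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.subject_ids) == len(self.sample_weights) == n):
            raise ValueError("design matrix components misaligned")
        if n == 0:
            raise ValueError("empty design matrix")
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains non-finite features")
        if np.any(self.sample_weights < 0):
            raise ValueError("sample weights must be non-negative")

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject_ids))


@dataclass
class EvalResult:
    """Cross-validated metrics for one task configuration."""

    task: TaskSpec
    per_fold_metrics: list[dict[str, float]]
    metric_means: dict[str, float]
    metric_sds: dict[str, float]
    confusion: pd.DataFrame | None
    importance: list[tuple[str, float]] | None
    fold_subjects: list[tuple[frozenset, frozenset]]


@dataclass
class TransferResult:
    """Group-transfer scores (LOO: one shot; LPO: one score per repeat)."""

    mode: str
    train_group: str
    test_group: str
    repeats: int
    metric_name: str
    scores: list[float]
    mean: float

    def __post_init__(self) -> None:
        if self.mode not in ("LOO", "LPO"):
            raise ValueError("mode must be LOO or LPO")
        if len(self.scores) != self.repeats:
            raise ValueError("one score required per repeat")


def _class_weights(y: np.ndarray) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    n, k = len(y), len(classes)
    per_class = {c: n / (k * cnt) for c, cnt in zip(classes, counts)}
    return np.array([per_class[v] for v in y])


def build_design(feature_table: pd.DataFrame, task: TaskSpec) -> DesignMatrix:
    """Turn a labeled feature table into the design matrix for one task.

    Applies the cohort filter, derives the binary/multiclass/regression
    target, and attaches inverse-frequency class weights (unit weights for
    regression).
    """
    table = feature_table
    if task.cohort != "ALL":
        if "group" not in table.columns:
            raise ValueError("feature table lacks a 'group' column")
        table = table[table["group"] == task.cohort]
    if table.empty:
        raise ValueError(f"no rows left for cohort {task.cohort}")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    subjects = table["subject_id"].to_numpy()
    if task.task_kind == "binary_type":
        y = (table["type_category"] == task.positive_class).to_numpy().astype(int)
    elif task.task_kind == "binary_intensity":
        y = (
            (table["intensity_category"] == task.positive_class)
            .to_numpy()
            .astype(int)
        )
    elif task.task_kind == "multiclass_activity":
        y = table["activity_name"].to_numpy()
    else:
        if "mets" not in table.columns:
            raise ValueError("regression_ee requires a 'mets' column")
        y = table["mets"].to_numpy(dtype=float)
    if task.is_classification:
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"cohort {task.cohort} has a single class for "
                f"{task.label()}; cannot train"
            )
        weights = _class_weights(y)
    else:
        weights = np.ones(len(y))
    strata = {}
    if "group" in table.columns:
        strata = dict(
            table.drop_duplicates("subject_id")[["subject_id", "group"]]
            .to_numpy()
            .tolist()
        )
    return DesignMatrix(
        X=X,
        y=y,
        subject_ids=subjects,
        sample_weights=weights,
        feature_names=tuple(FEATURE_NAMES),
        task=task,
        subject_strata=strata,
    )


def _make_model(task: TaskSpec, params: dict, seed: int):
    if task.algorithm == "boosted_trees":
        cls = (
            GradientBoostingClassifier
            if task.is_classification
            else GradientBoostingRegressor
        )
        return cls(random_state=seed, **params)
    lam = params.get("penalty_lambda", 1.0)
    if task.is_classification:
        model = LogisticRegression(
            l1_ratio=1.0, C=1.0 / max(lam, 1e-12), solver="liblinear",
            max_iter=2000, random_state=seed,
        )
    else:
        model = Lasso(alpha=lam, max_iter=20000)
    return Pipeline(
        [
            ("drop_constant", VarianceThreshold(0.0)),
            ("scale", StandardScaler()),
            ("model", model),
        ]
    )


def fit_boosted_trees(design: DesignMatrix, hyperparams: dict, seed: int = 0):
    """Fit a gradient-boosted tree ensemble with the design's sample weights."""
    task = design.task
    if task.algorithm != "boosted_trees":
        task = TaskSpec(task.task_kind, task.positive_class, "boosted_trees", task.cohort)
    model = _make_model(task, hyperparams, seed)
    model.fit(design.X, design.y, sample_weight=design.sample_weights)
    return model


def fit_l1_linear(design: DesignMatrix, hyperparams: dict, seed: int = 0):
    """Fit an L1-penalized linear model (logistic or least squares)."""
    task = design.task
    if task.algorithm != "l1_linear":
        task = TaskSpec(task.task_kind, task.positive_class, "l1_linear", task.cohort)
    model = _make_model(task, hyperparams, seed)
    n_constant = int((np.ptp(design.X, axis=0) == 0).sum())
    if n_constant:
        logger.warning("dropping %d constant feature columns", n_constant)
    _fit_with_weights(model, design.X, design.y, design.sample_weights)
    return model


def _fit_with_weights(model, X, y, w):
    if isinstance(model, Pipeline):
        model.fit(X, y, model__sample_weight=w)
    else:
        model.fit(X, y, sample_weight=w)
    return model


def _scores_for_auc(model, X, classification: bool):
    if not classification:
        return None
    proba = model.predict_proba(X)
    return proba[:, 1] if proba.shape[1] == 2 else proba


def compute_metrics(
    y_true,
    y_pred,
    y_score=None,
    kind: str = "binary",
    labels: list | None = None,
) -> dict[str, float]:
    """Evaluation metrics for one prediction set.

    ``kind``: 'binary' -> F1 of the positive class, ROC AUC, balanced
    accuracy, accuracy; 'multiclass' -> per-class one-vs-rest F1
    (``f1__<label>``), macro F1, macro one-vs-rest AUC (flagged approximate),
    balanced accuracy, accuracy; 'regression' -> RMSE.
    Zero-denominator F1 is 0 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if kind == "regression":
        return {"rmse": float(np.sqrt(mean_squared_error(y_true, y_pred)))}
    out: dict[str, float] = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
    }
    if kind == "binary":
        out["f1"] = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0))
        if y_score is not None and len(np.unique(y_true)) == 2:
            out["auc"] = float(roc_auc_score(y_true, y_score))
        else:
            out["auc"] = float("nan")
        return out
    if kind != "multiclass":
        raise ValueError(f"unknown metric kind {kind!r}")
    if labels is None:
        labels = sorted(np.unique(y_true).tolist())
    per_class = f1_score(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )
    for lab, val in zip(labels, per_class):
        out[f"f1__{lab}"] = float(val)
    out["f1"] = float(np.mean(per_class))  # macro
    if y_score is not None and len(np.unique(y_true)) == len(labels):
        try:
            out["auc"] = float(
                roc_auc_score(
                    y_true, y_score, multi_class="ovr",
                    average="macro", labels=labels,
                )
            )
        except ValueError:
            out["auc"] = float("nan")
    else:
        out["auc"] = float("nan")
    return out


def _metric_kind(task: TaskSpec) -> str:
    if task.task_kind == "regression_ee":
        return "regression"
    if task.task_kind == "multiclass_activity":
        return "multiclass"
    return "binary"


def _selection_score(metrics: dict[str, float], task: TaskSpec) -> float:
    if task.task_kind == "regression_ee":
        return -metrics["rmse"]
    return metrics["f1"]


def _subject_folds(
    subjects: np.ndarray,
    strata: dict[str, str],
    k: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition unique subjects into k folds, stratified by group label."""
    unique = np.unique(subjects)
    if len(unique) < k:
        raise ValueError(
            f"need at least {k} distinct subjects, got {len(unique)}"
        )
    y_strat = np.array([strata.get(s, "all") for s in unique])
    if len(np.unique(y_strat)) > 1 and np.min(np.bincount(
        pd.factorize(y_strat)[0]
    )) >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(unique, y_strat)
    else:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(unique))
        chunks = np.array_split(order, k)
        split_iter = (
            (np.setdiff1d(np.arange(len(unique)), test), test)
            for test in chunks
        )
    folds = []
    for train_idx, test_idx in split_iter:
        folds.append((unique[train_idx], unique[test_idx]))
    return folds


def _assert_disjoint(train_subjects, test_subjects, context: str) -> None:
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise AssertionError(
            f"subject leakage in {context}: {sorted(overlap)[:5]}"
        )


def _subset(design: DesignMatrix, subjects) -> DesignMatrix:
    mask = np.isin(design.subject_ids, subjects)
    return DesignMatrix(
        X=design.X[mask],
        y=design.y[mask],
        subject_ids=design.subject_ids[mask],
        sample_weights=design.sample_weights[mask],
        feature_names=design.feature_names,
        task=design.task,
        subject_strata=design.subject_strata,
    )


def _grid_for(task: TaskSpec, grids: dict | None) -> list[dict]:
    if grids and task.algorithm in grids:
        return grids[task.algorithm]
    return (
        DEFAULT_TREE_GRID
        if task.algorithm == "boosted_trees"
        else DEFAULT_L1_GRID
    )


def _tune(
    design: DesignMatrix,
    task: TaskSpec,
    grid: list[dict],
    inner_k: int,
    seed: int,
    leakage_log: list | None = None,
) -> dict:
    """Pick the grid candidate with the best mean inner-validation score."""
    if len(grid) == 1:
        return grid[0]
    folds = _subject_folds(
        design.subject_ids, design.subject_strata, inner_k, seed
    )
    best_params, best_score = grid[0], -np.inf
    kind = _metric_kind(task)
    for params in grid:
        scores = []
        for train_subj, val_subj in folds:
            _assert_disjoint(train_subj, val_subj, "inner fold")
            if leakage_log is not None:
                leakage_log.append((frozenset(train_subj), frozenset(val_subj)))
            train = _subset(design, train_subj)
            val = _subset(design, val_subj)
            if task.is_classification and len(np.unique(train.y)) < 2:
                continue
            model = _make_model(task, params, seed)
            _fit_with_weights(model, train.X, train.y, train.sample_weights)
            pred = model.predict(val.X)
            metrics = compute_metrics(
                val.y, pred,
                _scores_for_auc(model, val.X, task.is_classification),
                kind,
            )
            scores.append(_selection_score(metrics, task))
        mean_score = float(np.mean(scores)) if scores else -np.inf
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    return best_params


def nested_cv(
    design: DesignMatrix,
    task: TaskSpec | None = None,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    grids: dict | None = None,
) -> EvalResult:
    """Nested subject-wise cross-validation for one task configuration.

    Outer folds partition subjects (stratified by performance group when
    available); the inner loop selects hyperparameters by mean validation F1
    (classification) or RMSE (regression); the selected model is refit on the
    full outer-training set and scored once on the outer-test subjects.
    """
    task = task or design.task
    grid = _grid_for(task, grids)
    kind = _metric_kind(task)
    labels = (
        sorted(np.unique(design.y).tolist()) if kind == "multiclass" else None
    )
    outer = _subject_folds(
        design.subject_ids, design.subject_strata, outer_k, seed
    )
    per_fold: list[dict[str, float]] = []
    fold_subjects: list[tuple[frozenset, frozenset]] = []
    confusion_total = None
    importances = []
    for fold_i, (train_subj, test_subj) in enumerate(outer):
        _assert_disjoint(train_subj, test_subj, f"outer fold {fold_i}")
        fold_subjects.append((frozenset(train_subj), frozenset(test_subj)))
        train = _subset(design, train_subj)
        test = _subset(design, test_subj)
        params = _tune(
            train, task, grid, inner_k, seed + fold_i,
            leakage_log=fold_subjects,
        )
        model = _make_model(task, params, seed)
        _fit_with_weights(model, train.X, train.y, train.sample_weights)
        pred = model.predict(test.X)
        metrics = compute_metrics(
            test.y, pred,
            _scores_for_auc(model, test.X, task.is_classification),
            kind, labels=labels,
        )
        per_fold.append(metrics)
        if task.is_classification:
            labs = labels if labels is not None else [0, 1]
            cm = confusion_matrix(test.y, pred, labels=labs)
            confusion_total = cm if confusion_total is None else confusion_total + cm
            importances.append(dict(rank_importance(model, design.feature_names, top_k=len(design.feature_names))))
    keys = sorted({k for m in per_fold for k in m})
    means = {
        k: float(np.nanmean([m.get(k, np.nan) for m in per_fold])) for k in keys
    }
    sds = {
        k: float(np.nanstd([m.get(k, np.nan) for m in per_fold], ddof=1))
        if len(per_fold) > 1
        else 0.0
        for k in keys
    }
    confusion = None
    importance = None
    if task.is_classification and confusion_total is not None:
        labs = labels if labels is not None else [0, 1]
        confusion = pd.DataFrame(confusion_total, index=labs, columns=labs)
        merged: dict[str, float] = {}
        for imp in importances:
            for name, value in imp.items():
                merged[name] = merged.get(name, 0.0) + value / len(importances)
        importance = sorted(merged.items(), key=lambda kv: -kv[1])
    return EvalResult(
        task=task,
        per_fold_metrics=per_fold,
        metric_means=means,
        metric_sds=sds,
        confusion=confusion,
        importance=importance,
        fold_subjects=fold_subjects,
    )


def run_loo(
    feature_table: pd.DataFrame,
    task: TaskSpec,
    train_group: str,
    test_group: str,
    seed: int = 0,
    inner_k: int = 5,
    grids: dict | None = None,
) -> TransferResult:
    """Leave-one-group-out: tune and train on one group, test on the other."""
    if train_group == test_group:
        raise ValueError(
            "train and test group must differ (use nested_cv within a group)"
        )
    train_task = TaskSpec(task.task_kind, task.positive_class, task.algorithm, train_group)
    test_task = TaskSpec(task.task_kind, task.positive_class, task.algorithm, test_group)
    train = build_design(feature_table, train_task)
    test = build_design(feature_table, test_task)
    _assert_disjoint(train.subject_ids, test.subject_ids, "LOO")
    grid = _grid_for(task, grids)
    params = _tune(train, task, grid, inner_k, seed)
    model = _make_model(task, params, seed)
    _fit_with_weights(model, train.X, train.y, train.sample_weights)
    pred = model.predict(test.X)
    kind = _metric_kind(task)
    metrics = compute_metrics(
        test.y, pred,
        _scores_for_auc(model, test.X, task.is_classification),
        kind,
    )
    score = metrics["rmse"] if kind == "regression" else metrics["f1"]
    return TransferResult(
        mode="LOO",
        train_group=train_group,
        test_group=test_group,
        repeats=1,
        metric_name="rmse" if kind == "regression" else "f1",
        scores=[score],
        mean=score,
    )


def run_lpo(
    feature_table: pd.DataFrame,
    task: TaskSpec,
    full_group: str,
    split_group: str,
    frac: float = 0.5,
    repeats: int = 10,
    seed: int = 0,
    inner_k: int = 5,
    grids: dict | None = None,
) -> TransferResult:
    """Leave-partial-group-out with subject-level random splits.

    Per repeat r the ``split_group`` subjects are split ``frac``/(1-frac) with
    rng(seed + r); training uses all of ``full_group`` plus the first part and
    testing uses the held-out part.  The per-repeat scores are retained and
    averaged.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    if full_group == split_group:
        raise ValueError("full_group and split_group must differ")
    all_task = TaskSpec(task.task_kind, task.positive_class, task.algorithm, "ALL")
    if "group" not in feature_table.columns:
        raise ValueError("feature table lacks a 'group' column")
    split_subjects = np.unique(
        feature_table.loc[
            feature_table["group"] == split_group, "subject_id"
        ].to_numpy()
    )
    if len(split_subjects) < 2:
        raise ValueError("split_group needs at least two subjects")
    full_subjects = np.unique(
        feature_table.loc[
            feature_table["group"] == full_group, "subject_id"
        ].to_numpy()
    )
    kind = _metric_kind(task)
    grid = _grid_for(task, grids)
    scores: list[float] = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(split_subjects)
        n_train = int(round(frac * len(perm)))
        n_train = min(max(n_train, 1), len(perm) - 1)
        train_half, test_half = perm[:n_train], perm[n_train:]
        train_subjects = np.concatenate([full_subjects, train_half])
        _assert_disjoint(train_subjects, test_half, f"LPO repeat {r}")
        base = build_design(feature_table, all_task)
        train = _subset(base, train_subjects)
        test = _subset(base, test_half)
        params = _tune(train, task, grid, inner_k, seed + r)
        model = _make_model(task, params, seed)
        _fit_with_weights(model, train.X, train.y, train.sample_weights)
        pred = model.predict(test.X)
        metrics = compute_metrics(
            test.y, pred,
            _scores_for_auc(model, test.X, task.is_classification),
            kind,
        )
        scores.append(
            metrics["rmse"] if kind == "regression" else metrics["f1"]
        )
    return TransferResult(
        mode="LPO",
        train_group=full_group,
        test_group=split_group,
        repeats=repeats,
        metric_name="rmse" if kind == "regression" else "f1",
        scores=scores,
        mean=float(np.mean(scores)),
    )


def run_all(
    feature_table: pd.DataFrame,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    grids: dict | None = None,
) -> list[EvalResult]:
    """Run every configuration in the 51-model experiment grid."""
    results = []
    for task in enumerate_model_configs():
        design = build_design(feature_table, task)
        results.append(
            nested_cv(design, task, outer_k=outer_k, inner_k=inner_k,
                      seed=seed, grids=grids)
        )
    return results


def rank_importance(
    model, feature_names, top_k: int = 15
) -> list[tuple[str, float]]:
    """Top-k features by impurity importance, scaled to sum to one.

    Linear models fall back to |coefficient| magnitudes (flagged via log).
    """
    names = list(feature_names)
    top_k = min(top_k, len(names))
    estimator = model
    kept = np.arange(len(names))
    if isinstance(model, Pipeline):
        estimator = model.named_steps["model"]
        kept = model.named_steps["drop_constant"].get_support(indices=True)
    if hasattr(estimator, "feature_importances_"):
        raw = np.asarray(estimator.feature_importances_, dtype=float)
    elif hasattr(estimator, "coef_"):
        logger.warning(
            "model exposes no impurity importances; using |coefficients|"
        )
        raw = np.abs(np.atleast_2d(estimator.coef_)).sum(axis=0)
    else:
        raise ValueError("model exposes neither importances nor coefficients")
    full = np.zeros(len(names))
    full[kept] = raw
    total = full.sum()
    if total > 0:
        full = full / total
    order = np.argsort(-full)
    return [(names[i], float(full[i])) for i in order[:top_k]]
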