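"""Stage classification from key-hub expression profiles.

A 70/30 stratified split reserves a holdout set; on the training part an
elastic-net logistic model is tuned and evaluated by stratified 5-fold
cross-validation (per-fold AUC), then refit on all training samples and
scored on the holdout.  AUC is the Mann-Whitney U statistic with midranks
for ties, which equals the trapezoidal area under the ROC curve.  Late stage
is the positive class (early = 0, late = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from ._glmnet import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_LAMBDA_GRID,
    ElasticNetLogit,
    tune_elasticnet,
)

__all__ = [
    "split_train_test",
    "cv_train",
    "roc_auc",
    "evaluate",
    "ClassifierReport",
    "train_and_evaluate",
]


def split_train_test(
    samples: list[str],
    y: pd.Series | np.ndarray,
    train_fraction: float = 0.7,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Stratified train/test split, deterministic under ``seed``.

    Per class, ``round(train_fraction * n_class)`` samples go to training;
    train and test are disjoint and exhaustive.
    """
    y = np.asarray(y)
    samples = list(samples)
    if len(samples) != len(y):
        raise ValueError("samples and y must have equal length")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        n_train = int(round(train_fraction * len(idx)))
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return [samples[i] for i in train_idx], [samples[i] for i in test_idx]


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Rank-based AUC (midranks for ties) and the swept ROC polyline.

    Returns ``(auc, points)`` where ``points`` is an array of (fpr, tpr)
    pairs starting at (0, 0) and ending at (1, 1); the trapezoidal area
    under the polyline equals the returned AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # midranks
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    if not (points[0] == [0.0, 0.0]).all():
        points = np.vstack([[0.0, 0.0], points])
    if not (points[-1] == [1.0, 1.0]).all():
        points = np.vstack([points, [1.0, 1.0]])
    return auc, points


@dataclass
class ClassifierReport:
    fold_aucs: list[float]
    mean_auc: float
    model: dict
    holdout_auc: float | None = None
    holdout_accuracy: float | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "holdout_auc": None if self.holdout_auc is None else float(self.holdout_auc),
            "holdout_accuracy": (
                None if self.holdout_accuracy is None else float(self.holdout_accuracy)
            ),
            "model": self.model,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _model_dict(fitted: ElasticNetLogit, genes: list[str], alpha, lam, seed) -> dict:
    return {
        "genes": list(genes),
        "coefficients": [float(c) for c in fitted.coef_],
        "intercept": float(fitted.intercept_),
        "standardize_mean": [float(m) for m in fitted.mean_],
        "standardize_sd": [float(s) for s in fitted.sd_],
        "alpha": float(alpha),
        "lambda": float(lam),
        "seed": seed,
    }


def cv_train(
    X_train: pd.DataFrame,
    y_train: pd.Series | np.ndarray,
    k: int = 5,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    inner_folds: int = 5,
    seed: int | None = None,
) -> tuple[dict, list[float]]:
    """Stratified k-fold CV with per-fold inner tuning, then a final refit.

    ``X_train`` is samples x genes.  Each outer fold tunes (alpha, lambda)
    by inner CV on its k-1 training folds, fits, and scores AUC on the held
    fold; the final model is tuned and refit on all training samples.
    Returns ``(model, fold_aucs)`` where the model dict carries gene ids,
    coefficients, intercept and the training standardization parameters.
    """
    X = X_train.to_numpy(dtype=float)
    y = np.asarray(y_train, dtype=float)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} samples per class")
    ss = np.random.SeedSequence(seed)
    outer_seed, tune_seed, final_seed = (
        int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(3)
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=outer_seed)
    fold_aucs = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        alpha, lam = tune_elasticnet(
            X[tr], y[tr], alpha_grid, lambda_grid,
            n_folds=inner_folds, seed=tune_seed + i,
        )
        model = ElasticNetLogit(alpha=alpha, lam=lam).fit(X[tr], y[tr])
        auc, _ = roc_auc(model.predict_proba(X[te]), y[te])
        fold_aucs.append(auc)
    alpha, lam = tune_elasticnet(
        X, y, alpha_grid, lambda_grid, n_folds=inner_folds, seed=final_seed
    )
    final = ElasticNetLogit(alpha=alpha, lam=lam).fit(X, y)
    model = _model_dict(final, list(X_train.columns), alpha, lam, seed)
    return model, fold_aucs


def _predict_from_dict(model: dict, X_new: pd.DataFrame) -> np.ndarray:
    genes = model["genes"]
    missing = [g for g in genes if g not in X_new.columns]
    if missing:
        raise ValueError(f"genes missing from evaluation data: {missing}")
    Z = (
        X_new[genes].to_numpy(dtype=float) - np.asarray(model["standardize_mean"])
    ) / np.asarray(model["standardize_sd"])
    eta = Z @ np.asarray(model["coefficients"]) + model["intercept"]
    return 1.0 / (1.0 + np.exp(-eta))


def evaluate(
    model: dict,
    X_new: pd.DataFrame,
    y_new: pd.Series | np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, float, np.ndarray]:
    """Holdout AUC, accuracy at the probability threshold, and ROC points.

    The training standardization parameters stored in the model are reused,
    so evaluation is leakage-free.  A constant score vector (e.g. an
    all-zero model) scores AUC 0.5 by the midrank convention.
    """
    y = np.asarray(y_new, dtype=float)
    probs = _predict_from_dict(model, X_new)
    auc, points = roc_auc(probs, y)
    accuracy = float(((probs >= threshold).astype(float) == y).mean())
    return auc, accuracy, points


def train_and_evaluate(
    X: pd.DataFrame,
    y: pd.Series,
    train_fraction: float = 0.7,
    k: int = 5,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    inner_folds: int = 5,
    threshold: float = 0.5,
    seed: int | None = None,
) -> ClassifierReport:
    """Full protocol: stratified split, CV training, holdout evaluation."""
    samples = list(X.index)
    yv = np.asarray(y.loc[samples] if isinstance(y, pd.Series) else y, dtype=float)
    ss = np.random.SeedSequence(seed)
    split_seed, cv_seed = (
        int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(2)
    )
    train_ids, test_ids = split_train_test(
        samples, yv, train_fraction=train_fraction, seed=split_seed
    )
    pos = {s: i for i, s in enumerate(samples)}
    y_train = yv[[pos[s] for s in train_ids]]
    y_test = yv[[pos[s] for s in test_ids]]
    model, fold_aucs = cv_train(
        X.loc[train_ids], y_train, k=k, alpha_grid=alpha_grid,
        lambda_grid=lambda_grid, inner_folds=inner_folds, seed=cv_seed,
    )
    holdout_auc, holdout_acc, points = evaluate(
        model, X.loc[test_ids], y_test, threshold=threshold
    )
    return ClassifierReport(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        model=model,
        holdout_auc=holdout_auc,
        holdout_accuracy=holdout_acc,
        roc_points=points,
        seed=seed,
    )
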