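"""Random-forest fitting with out-of-bag (OOB) estimation, importances and Q².

Tree induction is delegated to scikit-learn's forests; this module owns the
OOB contract: every sample's prediction aggregates only trees whose bootstrap
resample excluded it, which makes the OOB error an internal cross-validation
estimate.  Both Breiman importance measures are exposed: the mean decrease in
OOB accuracy under per-feature permutation, and the total decrease in node
impurity (Gini for classification, residual sum of squares for regression).

Predictive quality of a regression forest is summarised by

    Q² = 1 − MSE_OOB / Var(y),

with MSE taken over OOB predictions and the population variance (denominator
n) over all samples, so a mean-prediction baseline scores exactly 0 and Q²
can be negative when OOB predictions are worse than the mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.ensemble._forest import _generate_unsampled_indices

from .io_datasets import ClassLabels

__all__ = [
    "RFParams",
    "ClassifierFit",
    "RegressorFit",
    "default_mtry",
    "fit_classifier",
    "fit_regressor",
    "q_squared",
]


@dataclass
class RFParams:
    """Forest hyperparameters.

    ``mtry="auto"`` resolves to the conventional defaults: nearest integer to
    √p for classification and to p/3 for regression (floor 1, ties round half
    up).  ``ntree=500`` follows common practice for metabolomics-scale data.
    """

    ntree: int = 500
    mtry: int | str = "auto"
    seed: int = 0
    min_leaf_classification: int = 1
    min_leaf_regression: int = 5

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry != "auto" and (not isinstance(self.mtry, int) or self.mtry < 1):
            raise ValueError("mtry must be a positive integer or 'auto'")

    def resolve_mtry(self, p: int, task: str) -> int:
        if self.mtry == "auto":
            return default_mtry(p, task)
        if self.mtry > p:
            raise ValueError(f"mtry={self.mtry} exceeds feature count {p}")
        return self.mtry


@dataclass
class ClassifierFit:
    """Summary of a fitted classification forest (no tree dumps)."""

    classes: list
    feature_ids: list
    oob_votes: np.ndarray  # samples x classes, per-tree OOB vote counts
    oob_error: float
    per_class_error: np.ndarray
    importance_permutation: np.ndarray  # mean decrease in OOB accuracy
    importance_impurity: np.ndarray  # mean per-tree total Gini decrease
    params: RFParams = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "feature_ids": list(self.feature_ids),
            "oob_error": self.oob_error,
            "per_class_error": self.per_class_error.tolist(),
            "importance_permutation": self.importance_permutation.tolist(),
            "importance_impurity": self.importance_impurity.tolist(),
        }


@dataclass
class RegressorFit:
    """Summary of a fitted regression forest."""

    feature_ids: list
    oob_predictions: np.ndarray
    mse_oob: float
    q2: float
    importance_impurity: np.ndarray  # mean per-tree RSS decrease
    params: RFParams = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "mse_oob": self.mse_oob,
            "q2": self.q2,
            "importance_impurity": self.importance_impurity.tolist(),
        }


def default_mtry(p: int, task: str) -> int:
    """Features sampled per split: nearest integer to √p (classification) or p/3
    (regression), with ties rounded half up and a floor of 1."""
    if p < 1:
        raise ValueError("feature count must be >= 1")
    if task == "classification":
        raw = math.sqrt(p)
    elif task == "regression":
        raw = p / 3.0
    else:
        raise ValueError(f"unknown task {task!r}")
    return max(1, math.floor(raw + 0.5))


def _as_codes(y) -> tuple[np.ndarray, list]:
    if isinstance(y, ClassLabels):
        return y.codes(), y.levels
    y = np.asarray(y)
    levels = list(dict.fromkeys(y.tolist()))  # order of first appearance
    lookup = {v: i for i, v in enumerate(levels)}
    return np.array([lookup[v] for v in y.tolist()]), levels


def _oob_index_sets(forest, n: int) -> list[np.ndarray]:
    return [
        _generate_unsampled_indices(est.random_state, n, n, None)
        for est in forest.estimators_
    ]


def _as_f32(X: np.ndarray) -> np.ndarray:
    """Trees store float32 thresholds; pre-converting lets us call the cython
    predictor directly and skip per-call validation."""
    return np.ascontiguousarray(X, dtype=np.float32)


def _tree_predict_class(est, X32: np.ndarray) -> np.ndarray:
    """Hard class codes from one tree (codes 0..k-1, as trained)."""
    leaf = est.tree_.predict(X32)
    if leaf.ndim == 3:  # (n, n_outputs, k)
        leaf = leaf[:, 0, :]
    return leaf.argmax(axis=1)


def _tree_predict_reg(est, X32: np.ndarray) -> np.ndarray:
    return est.tree_.predict(X32).ravel()


def _permutation_importance_oob(forest, X, y_codes, oob_sets, seed: int) -> np.ndarray:
    """Breiman permutation importance: per tree, OOB accuracy minus OOB accuracy
    with one feature's values shuffled among the tree's OOB samples; averaged
    over trees.  All per-feature permutations of a tree are scored in a single
    batched predict."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    X32 = _as_f32(X)
    totals = np.zeros(p)
    counts = np.zeros(p)
    for est, oob in zip(forest.estimators_, oob_sets):
        m = len(oob)
        if m == 0:
            continue
        X_oob = X32[oob]
        y_oob = y_codes[oob]
        base_acc = np.mean(_tree_predict_class(est, X_oob) == y_oob)
        # one block of m rows per feature, feature j shuffled within block j
        block = np.tile(X_oob, (p, 1))
        for j in range(p):
            block[j * m : (j + 1) * m, j] = X_oob[rng.permutation(m), j]
        perm_pred = _tree_predict_class(est, block).reshape(p, m)
        perm_acc = (perm_pred == y_oob).mean(axis=1)
        totals += base_acc - perm_acc
        counts += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)


def _impurity_importance(forest, p: int) -> np.ndarray:
    """Mean over trees of the (unnormalised) total impurity decrease per feature."""
    acc = np.zeros(p)
    for est in forest.estimators_:
        acc += est.tree_.compute_feature_importances(normalize=False)
    return acc / len(forest.estimators_)


def fit_classifier(
    X,
    y,
    params: RFParams | None = None,
    feature_ids=None,
    compute_permutation_importance: bool = True,
) -> ClassifierFit:
    """Fit a multiclass random forest and summarise its OOB behaviour.

    Each of ``ntree`` trees is grown on a bootstrap resample of size n (with
    replacement) considering ``mtry`` candidate features per split.  A sample's
    OOB vote tallies the hard predictions of exactly the trees whose bootstrap
    excluded it; vote ties break towards the earlier class level.
    """
    params = params or RFParams()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    y_codes, levels = _as_codes(y)
    if len(levels) < 2:
        raise ValueError("classification needs >=2 classes")
    counts = np.bincount(y_codes)
    if counts.min() < 2:
        raise ValueError("every class needs >=2 samples")
    if feature_ids is None:
        feature_ids = list(range(p))

    mtry = params.resolve_mtry(p, "classification")
    forest = RandomForestClassifier(
        n_estimators=params.ntree,
        max_features=mtry,
        bootstrap=True,
        min_samples_leaf=params.min_leaf_classification,
        random_state=params.seed,
        n_jobs=1,
    ).fit(X, y_codes)

    k = len(levels)
    oob_sets = _oob_index_sets(forest, n)
    X32 = _as_f32(X)
    votes = np.zeros((n, k))
    for est, oob in zip(forest.estimators_, oob_sets):
        if len(oob) == 0:
            continue
        pred = _tree_predict_class(est, X32[oob])
        np.add.at(votes, (oob, pred), 1)

    never_oob = np.flatnonzero(votes.sum(axis=1) == 0)
    if len(never_oob):
        warnings.warn(
            f"{len(never_oob)} samples were in every bootstrap (ntree too small); "
            "their votes use all trees",
            stacklevel=2,
        )
        for est in forest.estimators_:
            pred = _tree_predict_class(est, X32[never_oob])
            np.add.at(votes, (never_oob, pred), 1)

    oob_pred = votes.argmax(axis=1)  # first max -> earlier level wins ties
    miss = oob_pred != y_codes
    oob_error = float(miss.mean())
    per_class_error = np.array(
        [miss[y_codes == c].mean() for c in range(k)]
    )

    imp_perm = (
        _permutation_importance_oob(forest, X, y_codes, oob_sets, params.seed)
        if compute_permutation_importance
        else np.full(p, np.nan)
    )
    imp_impurity = _impurity_importance(forest, p)

    return ClassifierFit(
        classes=levels,
        feature_ids=list(feature_ids),
        oob_votes=votes,
        oob_error=oob_error,
        per_class_error=per_class_error,
        importance_permutation=imp_perm,
        importance_impurity=imp_impurity,
        params=params,
    )


def fit_regressor(X, y, params: RFParams | None = None, feature_ids=None) -> RegressorFit:
    """Fit a regression forest; OOB predictions average the trees that left each
    sample out, MSE_OOB is the mean squared OOB residual and Q² follows from it."""
    params = params or RFParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("regression needs n >= 5")
    if np.var(y) == 0:
        raise ValueError("response has zero variance")
    if feature_ids is None:
        feature_ids = list(range(p))

    mtry = params.resolve_mtry(p, "regression")
    forest = RandomForestRegressor(
        n_estimators=params.ntree,
        max_features=mtry,
        bootstrap=True,
        min_samples_leaf=params.min_leaf_regression,
        random_state=params.seed,
        n_jobs=1,
    ).fit(X, y)

    oob_sets = _oob_index_sets(forest, n)
    X32 = _as_f32(X)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for est, oob in zip(forest.estimators_, oob_sets):
        if len(oob) == 0:
            continue
        pred_sum[oob] += _tree_predict_reg(est, X32[oob])
        pred_cnt[oob] += 1

    never_oob = np.flatnonzero(pred_cnt == 0)
    if len(never_oob):
        warnings.warn(
            f"{len(never_oob)} samples were in every bootstrap (ntree too small); "
            "their predictions use all trees",
            stacklevel=2,
        )
        pred_sum[never_oob] = forest.predict(X[never_oob]) * len(forest.estimators_)
        pred_cnt[never_oob] = len(forest.estimators_)

    oob_pred = pred_sum / pred_cnt
    mse_oob = float(np.mean((y - oob_pred) ** 2))
    return RegressorFit(
        feature_ids=list(feature_ids),
        oob_predictions=oob_pred,
        mse_oob=mse_oob,
        q2=q_squared(oob_pred, y),
        importance_impurity=_impurity_importance(forest, p),
        params=params,
    )


def q_squared(oob_predictions, y) -> float:
    """Predictive variance explained: 1 − mean((y−ŷ)²) / popvar(y).

    The variance denominator is n (population variance), so predicting the
    mean gives exactly 0; values are unbounded below and at most 1.
    """
    yhat = np.asarray(oob_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError(f"length mismatch: {yhat.shape} vs {y.shape}")
    var = np.var(y)  # ddof=0
    if var == 0:
        raise ValueError("response has zero variance")
    return float(1.0 - np.mean((y - yhat) ** 2) / var)
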