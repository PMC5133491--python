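"""RF-regression association of clinical phenotypes with omics features,
with permutation-derived significance for Q² and per-feature importance.

A random forest regressed on a phenotype reports Q² (OOB variance explained)
and per-feature node-impurity importances, but no significance level for
either.  The permutation test supplies one: the phenotype vector is shuffled
``n_perm`` times (the feature matrix untouched), the forest refit each time,
and the observed statistics are compared against the 95th percentile of the
resulting null distributions.  Importance nulls are pooled across features
into one distribution by default (a single cut-off for the whole model);
per-feature nulls are available via ``pooled_importance=False``.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_datasets import DatasetCollection
from .rf_core import RFParams, RegressorFit, fit_regressor

__all__ = [
    "PermutationParams",
    "PermutationNull",
    "AssociationResult",
    "nearest_rank_percentile",
    "permutation_null",
    "assess_significance",
    "regress_all",
]


def derive_seed(base_seed: int, *keys) -> int:
    """Stable sub-seed from a base seed and string/int keys (< 2^31).

    Hash-based so results for one dataset or phenotype never depend on how
    many others are present.
    """
    digest = hashlib.blake2s(
        "\x1f".join(str(k) for k in (base_seed, *keys)).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PermutationParams:
    n_perm: int = 1000
    percentile: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0,100)")


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ⌈q/100·n⌉-th smallest value (reproducible,
    no interpolation)."""
    values = np.sort(np.asarray(values, dtype=float))
    rank = max(1, math.ceil(percentile / 100.0 * len(values)))
    return float(values[rank - 1])


@dataclass
class PermutationNull:
    """Null distributions of Q² and impurity importance under phenotype shuffling."""

    q2_null: np.ndarray  # (n_perm,)
    impurity_null: np.ndarray  # (n_perm, p) per-permutation per-feature importances
    percentile: float
    pooled_importance: bool = True
    n_samples: int = 0
    n_features: int = 0

    @property
    def q2_threshold(self) -> float:
        return nearest_rank_percentile(self.q2_null, self.percentile)

    @property
    def importance_threshold(self) -> float | np.ndarray:
        if self.pooled_importance:
            return nearest_rank_percentile(self.impurity_null.ravel(), self.percentile)
        return np.array(
            [
                nearest_rank_percentile(self.impurity_null[:, j], self.percentile)
                for j in range(self.impurity_null.shape[1])
            ]
        )


@dataclass
class AssociationResult:
    phenotype_id: str
    dataset_name: str
    q2_observed: float
    q2_threshold: float
    q2_significant: bool
    significant_features: dict = field(default_factory=dict)  # id -> observed importance
    importance_threshold: float | np.ndarray = 0.0
    q2_pvalue: float = float("nan")  # empirical: (1 + #null >= obs) / (n_perm + 1)
    fit: RegressorFit | None = field(repr=False, default=None)
    n_perm: int = 0

    def to_dict(self) -> dict:
        thr = self.importance_threshold
        return {
            "phenotype_id": self.phenotype_id,
            "dataset_name": self.dataset_name,
            "q2_observed": self.q2_observed,
            "q2_threshold": self.q2_threshold,
            "q2_significant": bool(self.q2_significant),
            "q2_pvalue": self.q2_pvalue,
            "importance_threshold": thr.tolist() if isinstance(thr, np.ndarray) else thr,
            "significant_features": {k: float(v) for k, v in self.significant_features.items()},
            "n_perm": self.n_perm,
        }


def permutation_null(
    X,
    y,
    perm_params: PermutationParams | None = None,
    rf_params: RFParams | None = None,
    pooled_importance: bool = True,
) -> PermutationNull:
    """Build the Q²/importance null by refitting the forest on shuffled phenotypes.

    Permutations are independent uniform shuffles (no derangement constraint);
    each refit gets its own derived seed so the whole null is deterministic
    given ``perm_params.seed``.
    """
    perm_params = perm_params or PermutationParams()
    rf_params = rf_params or RFParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        raise ValueError("response has zero variance")
    n, p = X.shape
    rng = np.random.default_rng(perm_params.seed)
    q2_null = np.empty(perm_params.n_perm)
    imp_null = np.empty((perm_params.n_perm, p))
    for i in range(perm_params.n_perm):
        y_perm = y[rng.permutation(n)]
        fit = fit_regressor(
            X,
            y_perm,
            RFParams(
                ntree=rf_params.ntree,
                mtry=rf_params.mtry,
                seed=derive_seed(rf_params.seed, "perm", i),
                min_leaf_regression=rf_params.min_leaf_regression,
            ),
        )
        q2_null[i] = fit.q2
        imp_null[i] = fit.importance_impurity
    return PermutationNull(
        q2_null=q2_null,
        impurity_null=imp_null,
        percentile=perm_params.percentile,
        pooled_importance=pooled_importance,
        n_samples=n,
        n_features=p,
    )


def assess_significance(
    X,
    y,
    null: PermutationNull,
    rf_params: RFParams | None = None,
    feature_ids=None,
    phenotype_id: str = "",
    dataset_name: str = "",
) -> AssociationResult:
    """Fit the observed forest and flag Q² / features exceeding the null cut-offs."""
    rf_params = rf_params or RFParams()
    X = np.asarray(X, dtype=float)
    if X.shape[0] != null.n_samples or X.shape[1] != null.n_features:
        raise ValueError(
            f"shape {X.shape} does not match the null's ({null.n_samples}, {null.n_features})"
        )
    fit = fit_regressor(X, y, rf_params, feature_ids=feature_ids)
    q2_thr = null.q2_threshold
    imp_thr = null.importance_threshold
    q2_pvalue = float((1 + np.sum(null.q2_null >= fit.q2)) / (len(null.q2_null) + 1))
    flagged_mask = fit.importance_impurity > imp_thr
    flagged = {
        fid: float(imp)
        for fid, imp, keep in zip(fit.feature_ids, fit.importance_impurity, flagged_mask)
        if keep
    }
    return AssociationResult(
        phenotype_id=phenotype_id,
        dataset_name=dataset_name,
        q2_observed=fit.q2,
        q2_threshold=q2_thr,
        q2_significant=bool(fit.q2 > q2_thr),
        significant_features=flagged,
        importance_threshold=imp_thr,
        q2_pvalue=q2_pvalue,
        fit=fit,
        n_perm=len(null.q2_null),
    )


def regress_all(
    collection: DatasetCollection,
    perm_params: PermutationParams | None = None,
    rf_params: RFParams | None = None,
    phenotypes: list[str] | None = None,
    datasets: list[str] | None = None,
    multiple_testing: str = "none",
) -> tuple[pd.DataFrame, dict[tuple[str, str], AssociationResult]]:
    """One permutation-tested RF regression per (dataset, phenotype) pair.

    Returns the Q² matrix (datasets x phenotypes, exportable as TSV) and the
    full results keyed by ``(dataset, phenotype)``.  Seeds derive from the
    pair's names, so adding a dataset never perturbs the others.

    No correction across phenotypes is applied by default;
    ``multiple_testing="bh"`` additionally gates ``q2_significant`` on the
    Benjamini-Hochberg-adjusted empirical Q² p-values at the level implied
    by the percentile (5% FDR for the default 95th percentile).
    """
    if multiple_testing not in {"none", "bh"}:
        raise ValueError(f"unknown multiple_testing {multiple_testing!r}")
    if collection.clinical is None:
        raise ValueError("collection has no clinical table")
    perm_params = perm_params or PermutationParams()
    rf_params = rf_params or RFParams()
    phenotypes = phenotypes or collection.clinical.phenotype_ids
    datasets = datasets or collection.dataset_names

    results: dict[tuple[str, str], AssociationResult] = {}
    q2 = pd.DataFrame(index=datasets, columns=phenotypes, dtype=float)
    for dname in datasets:
        table = collection.table(dname)
        X = table.values
        for pheno in phenotypes:
            y = collection.clinical.phenotype(pheno)
            pair_perm = PermutationParams(
                n_perm=perm_params.n_perm,
                percentile=perm_params.percentile,
                seed=derive_seed(perm_params.seed, dname, pheno, "null"),
            )
            pair_rf = RFParams(
                ntree=rf_params.ntree,
                mtry=rf_params.mtry,
                seed=derive_seed(rf_params.seed, dname, pheno, "fit"),
                min_leaf_regression=rf_params.min_leaf_regression,
            )
            null = permutation_null(X, y, pair_perm, pair_rf)
            res = assess_significance(
                X,
                y,
                null,
                pair_rf,
                feature_ids=table.feature_ids,
                phenotype_id=pheno,
                dataset_name=dname,
            )
            results[(dname, pheno)] = res
            q2.loc[dname, pheno] = res.q2_observed
    if multiple_testing == "bh":
        keys = sorted(results)
        alpha = 1.0 - perm_params.percentile / 100.0
        reject, _, _, _ = multipletests(
            [results[k].q2_pvalue for k in keys], alpha=alpha, method="fdr_bh"
        )
        for k, keep in zip(keys, reject):
            results[k].q2_significant = bool(results[k].q2_significant and keep)
    return q2, results
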