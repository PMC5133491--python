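"""Backward-elimination feature selection minimising the OOB error.

Starting from the full feature set, each iteration discards the 20% of
features with the smallest variable importance, refits the forest, and
records the OOB misclassification error.  The final set is the iteration
minimising OOB error ("min", the default, with ties to the smaller set) or
the smallest set whose error is within one binomial standard error of that
minimum ("within_1se", a parsimony variant that trades a few genuinely
informative features for a smaller panel).

By default the importance ranking is frozen at the full-model fit rather
than recomputed after every drop — recomputing lets noise features that
look good by chance survive longer (selection bias).  Set
``recompute_importance=True`` for the greedier variant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rf_core import RFParams, fit_classifier

__all__ = [
    "SelectionParams",
    "SelectionIteration",
    "SelectionTrace",
    "elimination_sizes",
    "backward_eliminate",
    "choose_final_set",
    "cross_validated_error",
]


@dataclass
class SelectionParams:
    drop_fraction: float = 0.2
    min_features: int = 2
    recompute_importance: bool = False
    rule: str = "min"  # or "within_1se"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0,1)")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if self.rule not in {"min", "within_1se"}:
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass
class SelectionIteration:
    feature_ids: tuple
    oob_error: float
    oob_error_se: float
    importance: np.ndarray | None  # ranking snapshot (None if not recomputed)


@dataclass
class SelectionTrace:
    iterations: list[SelectionIteration]
    selected: tuple = field(default=())

    @property
    def sizes(self) -> list[int]:
        return [len(it.feature_ids) for it in self.iterations]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": range(len(self.iterations)),
                "n_features": self.sizes,
                "oob_error": [it.oob_error for it in self.iterations],
                "oob_error_se": [it.oob_error_se for it in self.iterations],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "selected": list(self.selected),
            "iterations": [
                {
                    "feature_ids": list(it.feature_ids),
                    "oob_error": it.oob_error,
                    "oob_error_se": it.oob_error_se,
                }
                for it in self.iterations
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def elimination_sizes(p: int, drop_fraction: float = 0.2, min_features: int = 2) -> list[int]:
    """Feature-set sizes visited: repeatedly remove max(1, round(f·p)) features
    until the next step would fall below ``min_features``."""
    sizes = [p]
    while True:
        nxt = sizes[-1] - max(1, _round_half_up(drop_fraction * sizes[-1]))
        if nxt < min_features:
            break
        sizes.append(nxt)
    return sizes


def _binomial_se(error: float, n: int) -> float:
    return math.sqrt(error * (1.0 - error) / n)


def backward_eliminate(
    X,
    y,
    sel_params: SelectionParams | None = None,
    rf_params: RFParams | None = None,
    feature_ids=None,
) -> SelectionTrace:
    """Iteratively refit the forest, dropping the lowest-importance 20% each round.

    Ranking uses the permutation importance (mean decrease in OOB accuracy)
    of the full model, or of the latest fit when
    ``sel_params.recompute_importance`` is set.  Each iteration records the
    OOB error and its binomial standard error √(e(1−e)/n).  The trace's
    ``selected`` attribute applies :func:`choose_final_set` with the
    configured rule.
    """
    sel_params = sel_params or SelectionParams()
    rf_params = rf_params or RFParams()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = list(range(p))
    feature_ids = list(feature_ids)
    if p < sel_params.min_features:
        raise ValueError(f"p={p} below min_features={sel_params.min_features}")

    col_of = {f: i for i, f in enumerate(feature_ids)}
    current = list(feature_ids)
    iterations: list[SelectionIteration] = []
    ranking: dict = {}

    for step, size in enumerate(elimination_sizes(p, sel_params.drop_fraction, sel_params.min_features)):
        if step > 0:
            # drop the bottom of the governing ranking
            current = sorted(current, key=lambda f: -ranking[f])[:size]
            current = [f for f in feature_ids if f in set(current)]  # keep original order
        cols = [col_of[f] for f in current]
        need_importance = step == 0 or sel_params.recompute_importance
        fit = fit_classifier(
            X[:, cols],
            y,
            RFParams(
                ntree=rf_params.ntree,
                mtry="auto" if rf_params.mtry == "auto" else min(rf_params.mtry, len(cols)),
                seed=(sel_params.seed + step) % (2**31),
                min_leaf_classification=rf_params.min_leaf_classification,
            ),
            feature_ids=current,
            compute_permutation_importance=need_importance,
        )
        if need_importance:
            ranking = dict(zip(current, fit.importance_permutation))
        iterations.append(
            SelectionIteration(
                feature_ids=tuple(current),
                oob_error=fit.oob_error,
                oob_error_se=_binomial_se(fit.oob_error, n),
                importance=fit.importance_permutation if need_importance else None,
            )
        )

    trace = SelectionTrace(iterations)
    trace.selected = choose_final_set(trace, sel_params.rule)
    return trace


def choose_final_set(trace: SelectionTrace, rule: str = "min") -> tuple:
    """Pick the final feature set from a trace.

    "min": the iteration with the smallest OOB error, ties going to the
    smaller (later) set.  "within_1se": the smallest set whose error is at
    most the minimum error plus one standard error of the minimum-error
    iteration.
    """
    if not trace.iterations:
        raise ValueError("empty selection trace")
    errors = np.array([it.oob_error for it in trace.iterations])
    best = len(errors) - 1 - int(np.argmin(errors[::-1]))  # last (smallest-set) minimum
    if rule == "min":
        return trace.iterations[best].feature_ids
    if rule == "within_1se":
        bound = errors[best] + trace.iterations[best].oob_error_se
        eligible = [i for i, e in enumerate(errors) if e <= bound]
        pick = min(eligible, key=lambda i: (len(trace.iterations[i].feature_ids), -i))
        return trace.iterations[pick].feature_ids
    raise ValueError(f"unknown rule {rule!r}")


def cross_validated_error(
    X,
    y,
    sel_params: SelectionParams | None = None,
    rf_params: RFParams | None = None,
    k: int = 5,
) -> float:
    """Unbiased error of the whole select-then-classify procedure.

    The OOB error of the reduced model is optimistic because the same data
    chose the features.  Here the entire backward elimination is repeated
    inside each of k stratified folds and the chosen set is evaluated on
    the held-out samples only.
    """
    from sklearn.model_selection import StratifiedKFold

    sel_params = sel_params or SelectionParams()
    rf_params = rf_params or RFParams()
    X = np.asarray(X, dtype=float)
    from .rf_core import _as_codes

    codes, _ = _as_codes(y)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=sel_params.seed)
    errors = []
    for fold, (train, test) in enumerate(splitter.split(X, codes)):
        trace = backward_eliminate(
            X[train],
            codes[train],
            SelectionParams(
                drop_fraction=sel_params.drop_fraction,
                min_features=sel_params.min_features,
                recompute_importance=sel_params.recompute_importance,
                rule=sel_params.rule,
                seed=(sel_params.seed + 1000 * (fold + 1)) % (2**31),
            ),
            rf_params,
        )
        cols = list(trace.selected)
        from sklearn.ensemble import RandomForestClassifier

        forest = RandomForestClassifier(
            n_estimators=rf_params.ntree,
            max_features=min(
                rf_params.resolve_mtry(len(cols), "classification"), len(cols)
            ),
            min_samples_leaf=rf_params.min_leaf_classification,
            random_state=(rf_params.seed + fold) % (2**31),
            n_jobs=1,
        ).fit(X[train][:, cols], codes[train])
        errors.append(np.mean(forest.predict(X[test][:, cols]) != codes[test]))
    return float(np.mean(errors))
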