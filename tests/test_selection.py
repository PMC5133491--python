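import numpy as np
import pytest

import omicforest as of
from omicforest.selection import SelectionIteration, SelectionTrace


def _noise_problem(rng, n=40, p=12, k=2):
    X = rng.normal(size=(n, p))
    y = np.repeat(np.arange(k), n // k)
    return X, y


class TestEliminationSizes:
    def test_p40_hand_iteration(self):
        # repeated p -> p - max(1, round(0.2 p)), stopping below 2 features
        assert of.elimination_sizes(40) == [40, 32, 26, 21, 17, 14, 11, 9, 7, 6, 5, 4, 3, 2]

    def test_small_p_single_iteration(self):
        assert of.elimination_sizes(2) == [2]

    @pytest.mark.parametrize("p", [3, 17, 100, 1000])
    def test_matches_independent_iteration(self, p):
        sizes, cur = [], p
        while cur >= 2:
            sizes.append(cur)
            cur -= max(1, int(np.floor(0.2 * cur + 0.5)))
        assert of.elimination_sizes(p) == sizes

    def test_strictly_shrinking(self):
        sizes = of.elimination_sizes(500)
        assert all(a > b for a, b in zip(sizes, sizes[1:]))


class TestBackwardEliminate:
    def test_trace_structure(self, rng):
        X, y = _noise_problem(rng, p=12)
        trace = of.backward_eliminate(
            X, y, of.SelectionParams(seed=0), of.RFParams(ntree=50, seed=0)
        )
        assert trace.sizes == of.elimination_sizes(12)
        full = set(trace.iterations[0].feature_ids)
        previous = full
        for it in trace.iterations[1:]:
            current = set(it.feature_ids)
            assert current < previous  # strictly shrinking, nested
            previous = current
        assert set(trace.selected) <= full

    def test_binomial_se_recorded(self, rng):
        X, y = _noise_problem(rng, n=40, p=6)
        trace = of.backward_eliminate(
            X, y, of.SelectionParams(seed=1), of.RFParams(ntree=50, seed=1)
        )
        it = trace.iterations[0]
        assert it.oob_error_se == pytest.approx(
            np.sqrt(it.oob_error * (1 - it.oob_error) / 40)
        )

    def test_p_below_min_features_rejected(self, rng):
        X, y = _noise_problem(rng, p=3)
        with pytest.raises(ValueError, match="min_features"):
            of.backward_eliminate(X, y, of.SelectionParams(min_features=5))

    def test_recompute_importance_variant_runs(self, rng):
        X, y = _noise_problem(rng, p=10)
        trace = of.backward_eliminate(
            X,
            y,
            of.SelectionParams(seed=2, recompute_importance=True),
            of.RFParams(ntree=50, seed=2),
        )
        # every iteration carries its own importance snapshot in this mode
        assert all(it.importance is not None for it in trace.iterations)

    def test_informative_features_survive(self, rng):
        # two strong features among noise; both should outlive elimination
        n = 60
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(n, 20))
        X[:, 3] += 2.5 * y
        X[:, 7] -= 2.5 * y
        trace = of.backward_eliminate(
            X, y, of.SelectionParams(seed=3), of.RFParams(ntree=200, seed=3)
        )
        assert {3, 7} <= set(trace.selected)

    def test_export_tsv_and_json(self, rng, tmp_path):
        X, y = _noise_problem(rng, p=8)
        trace = of.backward_eliminate(
            X, y, of.SelectionParams(seed=0), of.RFParams(ntree=30, seed=0)
        )
        trace.to_tsv(tmp_path / "trace.tsv")
        trace.to_json(tmp_path / "trace.json")
        lines = (tmp_path / "trace.tsv").read_text().strip().splitlines()
        assert len(lines) == len(trace.iterations) + 1


def _trace(errors, se, sizes=None):
    sizes = sizes or list(range(len(errors), 0, -1))
    return SelectionTrace(
        iterations=[
            SelectionIteration(tuple(range(s)), e, se, None)
            for e, s in zip(errors, sizes)
        ]
    )


class TestChooseFinalSet:
    def test_unique_minimum(self):
        trace = _trace([0.4, 0.35, 0.2, 0.3], se=0.01)
        assert len(of.choose_final_set(trace, "min")) == 2

    def test_tie_goes_to_smaller_set(self):
        trace = _trace([0.3, 0.2, 0.2, 0.4], se=0.01)
        assert len(of.choose_final_set(trace, "min")) == 2

    def test_within_1se_brute_force(self):
        errors, se = [0.30, 0.28, 0.29, 0.33], 0.05
        trace = _trace(errors, se)
        # oracle: smallest set with error <= min + se, scanned by hand
        bound = min(errors) + se
        eligible_sizes = [len(it.feature_ids) for it in trace.iterations if it.oob_error <= bound]
        assert len(of.choose_final_set(trace, "within_1se")) == min(eligible_sizes) == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            of.choose_final_set(SelectionTrace(iterations=[]), "min")

    def test_selected_matches_rule(self, rng):
        X, y = _noise_problem(rng, p=10)
        trace = of.backward_eliminate(
            X, y, of.SelectionParams(seed=5, rule="min"), of.RFParams(ntree=40, seed=5)
        )
        assert trace.selected == of.choose_final_set(trace, "min")


class TestCrossValidatedError:
    def test_cv_error_less_optimistic_than_oob(self, rng):
        # pure noise: the reduced-model OOB error is biased low, while the
        # outer-CV estimate stays near the 50% null rate
        X = rng.normal(size=(60, 20))
        y = np.repeat([0, 1], 30)
        trace = of.backward_eliminate(
            X, y, of.SelectionParams(seed=0), of.RFParams(ntree=60, seed=0)
        )
        sel = next(it for it in trace.iterations if it.feature_ids == trace.selected)
        cv = of.cross_validated_error(
            X, y, of.SelectionParams(seed=0), of.RFParams(ntree=60, seed=0), k=3
        )
        assert 0.0 <= cv <= 1.0
        assert cv >= sel.oob_error - 0.05  # CV does not inherit the selection optimism

    def test_deterministic(self, rng):
        X = rng.normal(size=(40, 10))
        y = np.repeat([0, 1], 20)
        args = (of.SelectionParams(seed=2), of.RFParams(ntree=30, seed=2))
        assert of.cross_validated_error(X, y, *args, k=3) == of.cross_validated_error(
            X, y, *args, k=3
        )


class TestNullErrorRate:
    def test_pure_noise_selected_error_near_null(self):
        """With no signal, the selected model's OOB error stays within 2 se of
        the balanced-k-class null rate (k-1)/k."""
        k, n = 3, 60
        gaps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(n, 15))
            y = np.repeat(np.arange(k), n // k)
            trace = of.backward_eliminate(
                X, y, of.SelectionParams(seed=seed), of.RFParams(ntree=60, seed=seed)
            )
            sel = next(it for it in trace.iterations if it.feature_ids == trace.selected)
            gaps.append((sel.oob_error - (k - 1) / k) / max(sel.oob_error_se, 1e-9))
        # selection optimism pulls the error below the null; the median run
        # stays within two standard errors of it
        assert abs(np.median(gaps)) < 2.0
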