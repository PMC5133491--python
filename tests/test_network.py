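import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import omicforest as of


def _table(name, arr, prefix):
    cols = [f"{prefix}{i}" for i in range(arr.shape[1])]
    idx = [f"s{i:03d}" for i in range(arr.shape[0])]
    return of.FeatureTable(name, pd.DataFrame(arr, index=idx, columns=cols))


class TestPearsonEdges:
    def test_perfect_linear_dependence(self, rng):
        a = rng.normal(size=(20, 1))
        A = _table("A", a, "a")
        B = _table("B", 2 * a, "b")
        edges, involved = of.pearson_edges(A, B, 0.8)
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(1.0)
        assert involved == {"a0", "b0"}

    def test_threshold_is_inclusive(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        r = np.corrcoef(a, b)[0, 1]
        A = _table("A", a[:, None], "a")
        B = _table("B", b[:, None], "b")
        at_r, _ = of.pearson_edges(A, B, abs(r))  # threshold == |r| exactly
        assert len(at_r) == 1
        above, _ = of.pearson_edges(A, B, abs(r) + 1e-9)
        assert len(above) == 0

    def test_negative_correlation_counted_by_magnitude(self, rng):
        a = rng.normal(size=(30, 1))
        edges, _ = of.pearson_edges(_table("A", a, "a"), _table("B", -a, "b"), 0.8)
        assert len(edges) == 1 and edges[0][2] < 0

    def test_independent_noise_no_edges(self, rng):
        A = _table("A", rng.normal(size=(200, 5)), "a")
        B = _table("B", rng.normal(size=(200, 5)), "b")
        edges, involved = of.pearson_edges(A, B, 0.8)
        assert edges == [] and involved == set()

    def test_unaligned_samples_rejected(self, rng):
        A = _table("A", rng.normal(size=(10, 2)), "a")
        B = _table("B", rng.normal(size=(11, 2)), "b")
        with pytest.raises(ValueError, match="aligned"):
            of.pearson_edges(A, B, 0.8)


class TestPartialCorrelation:
    def test_orthogonal_columns_give_zero(self, rng):
        # exactly orthonormal columns -> correlation identity -> zero partials
        q, _ = np.linalg.qr(rng.normal(size=(40, 4)))
        q -= q.mean(axis=0)  # centre; re-orthogonalise
        q, _ = np.linalg.qr(q)
        pcor, _ = of.partial_correlation(q)
        off = pcor[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 1e-10)

    def test_p2_equals_pearson(self, rng):
        X = rng.normal(size=(30, 2))
        pcor, pvals = of.partial_correlation(X)
        r = np.corrcoef(X, rowvar=False)[0, 1]
        assert pcor[0, 1] == pytest.approx(r, abs=1e-12)
        # k=0 controlled variables -> classic n-2 df Pearson test
        from scipy import stats

        t = r * np.sqrt(28 / (1 - r**2))
        assert pvals[0, 1] == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-9)

    def test_chain_conditional_independence(self):
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(500)
        x2 = x1 + rng.normal(0, 0.5, 500)
        x3 = x2 + rng.normal(0, 0.5, 500)
        X = np.column_stack([x1, x2, x3])
        assert abs(np.corrcoef(x1, x3)[0, 1]) > 0.5  # strong marginal correlation
        pcor, _ = of.partial_correlation(X)
        assert abs(pcor[0, 2]) < 0.15  # vanishes given the middleman

    def test_residual_regression_oracle_agreement(self, rng):
        X = rng.normal(size=(50, 5))
        pcor, _ = of.partial_correlation(X)
        for i in range(5):
            for j in range(i + 1, 5):
                rest = [k for k in range(5) if k not in (i, j)]
                A = np.column_stack([X[:, rest], np.ones(50)])
                ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
                rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
                assert pcor[i, j] == pytest.approx(np.corrcoef(ri, rj)[0, 1], abs=1e-10)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="reduce the variable set"):
            of.partial_correlation(rng.normal(size=(7, 5)))

    def test_constant_column_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 4.0
        with pytest.raises(ValueError, match="constant"):
            of.partial_correlation(X)

    def test_collinear_columns_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(ValueError, match="singular|collinear"):
            of.partial_correlation(X)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1), st.integers(min_value=2, max_value=6))
    def test_symmetry_unit_diagonal_bounded(self, seed, p):
        X = np.random.default_rng(seed).normal(size=(50, p))
        pcor, _ = of.partial_correlation(X)
        np.testing.assert_allclose(pcor, pcor.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(pcor), 1.0)
        assert np.all(np.abs(pcor) <= 1.0 + 1e-12)


class TestBuildNetwork:
    def test_alpha_threshold_semantics(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        _, pvals = of.partial_correlation(X)
        target = pvals[0, 1]
        just_above = of.build_network(X, params=of.NetworkParams(alpha=min(0.999, target * 1.01)))
        assert just_above.graph.has_edge("a", "b")
        if target > 1e-6:
            just_below = of.build_network(X, params=of.NetworkParams(alpha=target * 0.99))
            assert not just_below.graph.has_edge("a", "b")

    def test_no_self_loops_and_types(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=["m1", "m2", "m3", "AST"])
        g = of.build_network(X, node_types={"AST": "clinical"})
        assert all(u != v for u, v in g.graph.edges)
        assert g.graph.nodes["AST"]["type"] == "clinical"
        assert g.graph.nodes["m1"]["type"] == "metabolite"

    def test_chain_ggm_edges_recovered(self):
        """5-node chain GGM at n=300: true chain edges essentially always found;
        the exact edge set appears at roughly the rate alpha=0.05 per null pair
        allows (0.95^6 ~ 0.74 chance of zero false positives)."""
        prec = of.chain_precision(5, -0.4)
        chain = {(f"v{i}", f"v{i + 1}") for i in range(4)}
        all_true, exact = 0, 0
        for seed in range(30):
            X = pd.DataFrame(
                of.simulate_ggm_block(prec, 300, seed=seed),
                columns=[f"v{i}" for i in range(5)],
            )
            got = {tuple(sorted(e)) for e in of.build_network(X).graph.edges}
            all_true += chain <= got
            exact += got == chain
        assert all_true >= 29  # power ~ 1 for partial r = 0.4 at n=300
        assert exact >= 15  # ~74% expected; allow simulation noise

    def test_edge_attributes(self, rng):
        x = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.4, 200), "c": rng.normal(size=200)})
        g = of.build_network(X)
        d = g.graph.edges["a", "b"]
        assert d["sign"] == "+" and d["partial_r"] > 0 and d["p"] <= 0.05
        assert d["weight"] == pytest.approx(abs(d["partial_r"]))


class TestExportGraph:
    def _graph(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.3, 100), "c": rng.normal(size=100)})
        return of.build_network(X, node_types={"c": "clinical"})

    def test_graphml_roundtrip(self, rng, tmp_path):
        g = self._graph(rng)
        of.export_graph(g, tmp_path / "g.graphml", "graphml")
        back = of.read_graph(tmp_path / "g.graphml")
        assert set(back.graph.nodes) == set(g.graph.nodes)
        assert back.graph.number_of_edges() == g.graph.number_of_edges()
        for u, v, d in g.graph.edges(data=True):
            assert back.graph.edges[u, v]["partial_r"] == pytest.approx(d["partial_r"], abs=1e-9)
            assert back.graph.edges[u, v]["sign"] == d["sign"]
        assert back.graph.nodes["c"]["type"] == "clinical"

    def test_edge_tsv(self, rng, tmp_path):
        g = self._graph(rng)
        of.export_graph(g, tmp_path / "edges.tsv", "edge_tsv")
        df = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert list(df.columns) == ["node_i", "node_j", "partial_r", "p", "sign", "weight"]
        assert len(df) == g.graph.number_of_edges()

    def test_empty_graph_valid_file(self, rng, tmp_path):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        g = of.build_network(X, params=of.NetworkParams(alpha=1e-12))
        of.export_graph(g, tmp_path / "empty.graphml", "graphml")
        back = of.read_graph(tmp_path / "empty.graphml")
        assert back.graph.number_of_edges() == 0
        assert set(back.graph.nodes) == {"a", "b", "c"}

    def test_unknown_format_rejected(self, rng, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            of.export_graph(self._graph(rng), tmp_path / "g.bin", "parquet")
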