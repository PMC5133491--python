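"""Pearson screening and partial-correlation (Gaussian graphical) networks.

Nodes are metabolites or clinical parameters; edges carry the full-order
partial correlation — the correlation between two variables after the linear
effect of *all* other selected variables is removed — which separates direct
from indirect association where marginal correlation cannot.  Partial
correlations come from the inverse correlation (precision) matrix,

    ρ_ij·rest = −P_ij / √(P_ii P_jj),

and each gets a two-sided p-value from the t transform
t = r·√((n−2−k)/(1−r²)) with k = p−2 controlled variables and n−2−k degrees
of freedom.  Edges are drawn at p ≤ α (0.05 by default, uncorrected, per
edge).  A Pearson |r| ≥ 0.8 screen selects variable subsets for cross-dataset
networks before partialling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_datasets import FeatureTable

__all__ = [
    "NetworkParams",
    "NetworkGraph",
    "pearson_edges",
    "partial_correlation",
    "build_network",
    "export_graph",
    "read_graph",
]


@dataclass
class NetworkParams:
    alpha: float = 0.05
    r_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [0,1]")


@dataclass
class NetworkGraph:
    """Undirected graph; nodes typed metabolite|clinical, edges signed partial r."""

    graph: nx.Graph
    alpha: float = 0.05

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [(u, v, dict(d)) for u, v, d in self.graph.edges(data=True)]

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_i": u, "node_j": v, **d}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        cols = ["node_i", "node_j", "partial_r", "p", "sign", "weight"]
        return pd.DataFrame(rows, columns=cols)


def pearson_edges(
    A: FeatureTable, B: FeatureTable, r_threshold: float = 0.8
) -> tuple[list[tuple[str, str, float]], set[str]]:
    """All cross-platform pairs with |Pearson r| at or above the threshold.

    Returns the edge list and the union of involved variables, which is the
    input set for the subsequent partial-correlation step.
    """
    if A.sample_ids != B.sample_ids:
        raise ValueError("tables are not sample-aligned")
    n = len(A.sample_ids)
    if n < 3:
        raise ValueError("need n >= 3 samples for correlation")
    Xa, Xb = A.values, B.values
    za = (Xa - Xa.mean(0)) / Xa.std(0, ddof=0)
    zb = (Xb - Xb.mean(0)) / Xb.std(0, ddof=0)
    r = za.T @ zb / n
    edges = []
    involved: set[str] = set()
    for i, fa in enumerate(A.feature_ids):
        for j, fb in enumerate(B.feature_ids):
            if abs(r[i, j]) >= r_threshold:
                edges.append((fa, fb, float(r[i, j])))
                involved.add(fa)
                involved.add(fb)
    return edges, involved


def partial_correlation(X) -> tuple[np.ndarray, np.ndarray]:
    """Full-order partial correlations and two-sided p-values.

    ``X`` is an n x p matrix (or DataFrame) over the selected variables.
    Requires n > p + 2 so the t-test degrees of freedom n−2−(p−2) stay
    positive; for larger p reduce the variable set first (the pipeline's
    selection stages exist for exactly that reason).
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two variables")
    if n <= p + 2:
        raise ValueError(
            f"n={n} <= p+2={p + 2}: too few samples for full-order partial "
            "correlation; reduce the variable set"
        )
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"constant columns at positions {bad}")
    corr = np.corrcoef(X, rowvar=False)
    # inv() happily returns garbage for nearly singular input, so gate on the
    # reciprocal condition number instead of waiting for LinAlgError
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= eigvals.max() * 1e-10:
        raise ValueError("singular correlation matrix (collinear variables)")
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pcor, 1.0)

    k = p - 2  # controlled variables per pair
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = pcor * np.sqrt(df / (1.0 - pcor**2))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(np.abs(pcor) >= 1.0, 0.0, pvals)
    np.fill_diagonal(pvals, np.nan)
    return pcor, pvals


def build_network(
    X: pd.DataFrame,
    node_types: dict[str, str] | None = None,
    params: NetworkParams | None = None,
    node_datasets: dict[str, str] | None = None,
) -> NetworkGraph:
    """Partial-correlation graph over the columns of ``X`` at significance α.

    Edge attributes: ``partial_r`` (signed), ``p``, ``sign`` ("+"/"-") and
    ``weight`` = |partial_r| (line thickness in viewers).  ``node_types``
    maps variable -> "metabolite" | "clinical" (default metabolite).
    """
    params = params or NetworkParams()
    node_types = node_types or {}
    node_datasets = node_datasets or {}
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [str(c) for c in X.columns]
    names = list(X.columns)
    pcor, pvals = partial_correlation(X)

    g = nx.Graph()
    for name in names:
        g.add_node(
            name,
            type=node_types.get(name, "metabolite"),
            dataset=node_datasets.get(name, ""),
        )
    p = len(names)
    for i in range(p):
        for j in range(i + 1, p):
            if pvals[i, j] <= params.alpha:
                r = float(pcor[i, j])
                g.add_edge(
                    names[i],
                    names[j],
                    partial_r=r,
                    p=float(pvals[i, j]),
                    sign="+" if r >= 0 else "-",
                    weight=abs(r),
                )
    return NetworkGraph(graph=g, alpha=params.alpha)


def export_graph(g: NetworkGraph, path, format: str = "graphml") -> None:
    """Write the network as GraphML or a TSV edge list (attributes preserved)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g.graph, path)
    elif format == "edge_tsv":
        g.edge_frame().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r} (use 'graphml' or 'edge_tsv')")


def read_graph(path, alpha: float = 0.05) -> NetworkGraph:
    """Read back a GraphML export (round-trip counterpart of :func:`export_graph`)."""
    return NetworkGraph(graph=nx.read_graphml(Path(path)), alpha=alpha)
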