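"""Node and edge centrality of the familial network.

Five node measures — alpha, betweenness, harmonic (Latora) closeness,
eccentricity and degree — plus edge betweenness, their Pearson correlation
matrix, and PCA-based selection of non-redundant measures.

Conventions (stated because tools differ):

* alpha centrality and in/out-degree respect edge direction; betweenness,
  closeness and eccentricity are computed on the undirected view, since in
  a pedigree DAG most ordered pairs are mutually unreachable and the
  peripheral-vs-central reading of eccentricity only coheres undirected;
* betweenness counts unordered pairs, endpoints excluded, with fractional
  split over tied shortest paths (Brandes accumulation), unnormalised;
* harmonic closeness is the raw sum of reciprocal distances to reachable
  nodes (well defined on disconnected graphs); a normalised variant
  (divided by n - 1) is available behind a flag;
* eccentricity is the maximum finite shortest-path distance (larger = more
  peripheral), 0 for an isolated node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "alpha_centrality",
    "path_centralities",
    "edge_betweenness",
    "degree_centrality",
    "centrality_table",
    "centrality_correlations",
    "pca_contributions",
    "PCAContributions",
    "MEASURES",
]

MEASURES = ("alpha", "betweenness", "closeness", "eccentricity", "degree")


# ---------------------------------------------------------------------------
# alpha centrality
# ---------------------------------------------------------------------------

def alpha_centrality(g: nx.DiGraph, alpha: float = 1.0,
                     e: float | dict = 1.0) -> dict[str, float]:
    """Bonacich alpha centrality: the exact solution of
    ``x = alpha * A^T x + e``, i.e. ``x_v = e_v + alpha * sum_{u->v} x_u``.

    Every node receives exogenous status ``e`` plus attenuated status from
    its parents; on an acyclic pedigree the adjacency is nilpotent, so the
    system is solvable for any ``alpha`` (default 1).  For cyclic inputs
    ``alpha`` must stay below the reciprocal spectral radius or the solve
    fails with an explicit error.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    evec = np.full(n, float(e)) if np.isscalar(e) else np.array(
        [float(e[v]) for v in nodes])
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csc", dtype=float)
    system = scipy.sparse.identity(n, format="csc") - alpha * a.T
    try:
        x = scipy.sparse.linalg.spsolve(system, evec)
    except Exception as exc:  # singular matrix
        raise ValueError(
            f"alpha centrality system is singular at alpha={alpha}; "
            "reduce alpha below the reciprocal spectral radius") from exc
    if np.any(~np.isfinite(x)):
        raise ValueError(
            f"alpha centrality system is singular at alpha={alpha}")
    return {v: float(x[i]) for i, v in enumerate(nodes)}


# ---------------------------------------------------------------------------
# shortest-path measures (undirected view)
# ---------------------------------------------------------------------------

def path_centralities(g: nx.Graph, normalized_closeness: bool = False
                      ) -> pd.DataFrame:
    """Betweenness, harmonic closeness and eccentricity per node, computed
    on the undirected view.  Returns a DataFrame indexed by node."""
    u = g.to_undirected() if g.is_directed() else g
    bet = nx.betweenness_centrality(u, normalized=False)
    harm = nx.harmonic_centrality(u)
    if normalized_closeness and u.number_of_nodes() > 1:
        harm = {v: h / (u.number_of_nodes() - 1) for v, h in harm.items()}
    ecc: dict = {}
    for comp in nx.connected_components(u):
        sub = u.subgraph(comp)
        if len(comp) == 1:
            ecc[next(iter(comp))] = 0
        else:
            ecc.update(nx.eccentricity(sub))
    nodes = sorted(u.nodes)
    return pd.DataFrame({
        "betweenness": [bet[v] for v in nodes],
        "closeness": [float(harm[v]) for v in nodes],
        "eccentricity": [int(ecc[v]) for v in nodes],
    }, index=pd.Index(nodes, name="node"))


def edge_betweenness(g: nx.Graph) -> dict[tuple, float]:
    """Unnormalised edge betweenness on the undirected view: each unordered
    node pair spreads one unit over its tied shortest paths, credited to
    every edge crossed.  Keys are sorted endpoint tuples."""
    u = g.to_undirected() if g.is_directed() else g
    raw = nx.edge_betweenness_centrality(u, normalized=False)
    return {tuple(sorted((a, b))): float(s) for (a, b), s in raw.items()}


def degree_centrality(g: nx.DiGraph) -> pd.DataFrame:
    """In-, out- and total degree per node (direction-aware)."""
    nodes = sorted(g.nodes)
    if g.is_directed():
        ind = dict(g.in_degree())
        outd = dict(g.out_degree())
    else:
        ind = outd = dict(g.degree())
    return pd.DataFrame({
        "in_degree": [ind[v] for v in nodes],
        "out_degree": [outd[v] for v in nodes],
        "degree": [g.degree(v) for v in nodes],
    }, index=pd.Index(nodes, name="node"))


def centrality_table(g: nx.DiGraph, alpha: float = 1.0, e: float = 1.0,
                     normalized_closeness: bool = False) -> pd.DataFrame:
    """The full per-node centrality profile: alpha, betweenness, harmonic
    closeness, eccentricity, in/out/total degree."""
    ac = alpha_centrality(g, alpha=alpha, e=e)
    paths = path_centralities(g, normalized_closeness=normalized_closeness)
    deg = degree_centrality(g)
    table = paths.join(deg)
    table.insert(0, "alpha", [ac[v] for v in table.index])
    return table


# ---------------------------------------------------------------------------
# correlation and PCA selection
# ---------------------------------------------------------------------------

def centrality_correlations(table: pd.DataFrame,
                            columns: tuple[str, ...] | None = None
                            ) -> pd.DataFrame:
    """Pearson correlation matrix between centrality measures; symmetric
    with unit diagonal.  Zero-variance measures yield NaN entries and a
    warning rather than a silent 0."""
    cols = list(columns) if columns else [c for c in table.columns
                                          if c not in ("in_degree", "out_degree")]
    if len(table) < 3:
        raise ValueError("need at least 3 nodes for correlations")
    sub = table[cols].astype(float)
    flat = sub.std(ddof=0) == 0
    if flat.any():
        warnings.warn(f"zero-variance measures, correlations undefined: "
                      f"{list(sub.columns[flat])}", stacklevel=2)
    corr = sub.corr(method="pearson")
    for c in sub.columns[flat]:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr


@dataclass
class PCAContributions:
    """Per-measure contribution (%) to the leading principal components of
    the standardised centrality table, with the expected-average-
    contribution reference line (100/p for p measures) and the measures
    exceeding it on any reported component."""

    contributions: pd.DataFrame      # measures x PC1..PCk, percentages
    explained_variance_pct: list[float]
    reference_pct: float
    selected: list[str]


def pca_contributions(table: pd.DataFrame,
                      columns: tuple[str, ...] | None = None,
                      n_components: int = 3) -> PCAContributions:
    """PCA-based measure selection.

    Measures are standardised to zero mean and unit variance; the
    contribution of measure j to component k is its squared loading as a
    share of that component's total squared loadings, in percent.  A
    measure is "selected" when its contribution exceeds the expected
    average (100/p) on any of the first ``n_components`` components.
    """
    from sklearn.decomposition import PCA

    cols = list(columns) if columns else [c for c in table.columns
                                          if c not in ("in_degree", "out_degree")]
    x = table[cols].astype(float).to_numpy()
    n, p = x.shape
    keep = x.std(axis=0) > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 measures with positive variance")
    if not keep.all():
        warnings.warn(f"dropping zero-variance measures from PCA: "
                      f"{[c for c, k in zip(cols, keep) if not k]}", stacklevel=2)
        cols = [c for c, k in zip(cols, keep) if k]
        x = x[:, keep]
        p = x.shape[1]
    if n < p:
        warnings.warn(f"fewer nodes ({n}) than measures ({p}); "
                      "components truncated", stacklevel=2)
    k = min(n_components, p, n)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    pca = PCA(n_components=k)
    pca.fit(z)
    loadings = pca.components_                     # (k, p), rows unit norm
    contrib = (loadings**2 / (loadings**2).sum(axis=1, keepdims=True)).T * 100.0
    frame = pd.DataFrame(contrib, index=pd.Index(cols, name="measure"),
                         columns=[f"PC{i + 1}" for i in range(k)])
    reference = 100.0 / p
    selected = sorted(frame.index[(frame > reference).any(axis=1)])
    return PCAContributions(
        contributions=frame,
        explained_variance_pct=[float(v) * 100.0
                                for v in pca.explained_variance_ratio_],
        reference_pct=reference,
        selected=selected,
    )
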