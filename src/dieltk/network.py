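"""Thresholded co-expression networks and their topology diagnostics.

Nodes are rhythmic genes; an undirected edge joins two genes whose 24 h
hourly expression profiles have Pearson correlation strictly above a
threshold (0.95 by default).  Diagnostics mirror standard practice for
such networks: an ordinary least-squares fit of log10 degree frequency
on log10 degree (scale-free check), the mean local clustering
coefficient, and an empirical small-world test comparing the observed
clustering against preferential-attachment random graphs matched in node
and edge count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, hourly_profile_matrix

__all__ = [
    "CoexpressionNetwork",
    "TopologyReport",
    "build_network",
    "fit_powerlaw",
    "degree_fit",
    "mean_clustering",
    "smallworld_test",
    "export_edgelist",
    "export_graphml",
    "matched_scalefree_graph",
]


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    degree_fit: tuple[float, float, float, float]  # slope, intercept, r2, p
    mean_clustering: float
    smallworld_p: float
    n_random: int


def build_network(
    m: ExpressionMatrix,
    genes: list[str],
    threshold: float = 0.95,
    period: float = 24.0,
) -> CoexpressionNetwork:
    """Edge (i, j) iff Pearson r between hourly folded-mean profiles is
    strictly greater than ``threshold``.  Constant profiles (undefined
    correlation) are dropped with a warning."""
    missing = [g for g in genes if g not in m]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    profiles = hourly_profile_matrix(m, list(genes), period)
    keep = np.ptp(profiles, axis=1) > 0 if len(genes) else np.array([], bool)
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} constant profile(s): {dropped[:5]}..."
            if len(dropped) > 5
            else f"excluding constant profile(s): {dropped}"
        )
    kept = [g for g, k in zip(genes, keep) if k]
    g = nx.Graph()
    g.add_nodes_from(kept)
    if len(kept) >= 2:
        r = np.corrcoef(profiles[keep])
        ii, jj = np.triu_indices(len(kept), k=1)
        mask = r[ii, jj] > threshold
        g.add_weighted_edges_from(
            (kept[i], kept[j], float(r[i, j]))
            for i, j in zip(ii[mask], jj[mask])
        )
    return CoexpressionNetwork(g, threshold)


def fit_powerlaw(degrees) -> tuple[float, float, float, float]:
    """OLS of log10(frequency of degree k) on log10(k) over k >= 1.

    Returns (slope, intercept, r_squared, p_value); a clearly negative
    slope with high r-squared is the scale-free diagnostic.  Requires at
    least three distinct positive degrees.
    """
    degrees = np.asarray(degrees, dtype=float)
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if len(ks) < 3:
        raise ValueError(
            f"degree distribution has {len(ks)} support point(s); >=3 required"
        )
    res = stats.linregress(np.log10(ks), np.log10(counts))
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def degree_fit(net: CoexpressionNetwork) -> tuple[float, float, float, float]:
    """Log-log degree-distribution regression of the network."""
    return fit_powerlaw([d for _, d in net.graph.degree])


def mean_clustering(net: CoexpressionNetwork) -> float:
    """Average local clustering coefficient (degree<2 nodes count 0)."""
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    return float(nx.average_clustering(net.graph))


def matched_scalefree_graph(
    n_nodes: int, n_edges: int, rng: np.random.Generator
) -> nx.Graph:
    """Preferential-attachment graph adjusted to an exact edge count.

    Barabasi-Albert generation with m = round(E/V) attachment edges per
    node cannot hit an arbitrary E, so edges are randomly removed or
    non-edges randomly added until the count matches.
    """
    m_attach = min(max(1, round(n_edges / max(n_nodes, 1))), max(n_nodes - 1, 1))
    seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=seed)
    edges = list(g.edges)
    while g.number_of_edges() > n_edges:
        i = int(rng.integers(len(edges)))
        g.remove_edge(*edges[i])
        edges[i] = edges[-1]
        edges.pop()
    nodes = list(g.nodes)
    while g.number_of_edges() < n_edges:
        u, v = rng.integers(len(nodes), size=2)
        if u != v and not g.has_edge(nodes[u], nodes[v]):
            g.add_edge(nodes[u], nodes[v])
    return g


def smallworld_test(
    net: CoexpressionNetwork,
    n_random: int = 10_000,
    seed: int | None = None,
) -> float:
    """Empirical p for the small-world (high clustering) property.

    p = (1 + #{random graphs with mean clustering >= observed})
        / (n_random + 1)
    over ``n_random`` matched preferential-attachment graphs.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    observed = mean_clustering(net)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_random):
        g = matched_scalefree_graph(net.n_nodes, net.n_edges, rng)
        if nx.average_clustering(g) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_random + 1)


def topology_report(
    net: CoexpressionNetwork, n_random: int = 10_000, seed: int | None = None
) -> TopologyReport:
    return TopologyReport(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        degree_fit=degree_fit(net),
        mean_clustering=mean_clustering(net),
        smallworld_p=smallworld_test(net, n_random=n_random, seed=seed),
        n_random=n_random,
    )


def export_edgelist(net: CoexpressionNetwork, path) -> None:
    """Write the edge list as TSV: gene_a, gene_b, weight."""
    rows = [
        (u, v, net.graph.edges[u, v].get("weight", 1.0))
        for u, v in sorted(net.edge_set())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def export_graphml(net: CoexpressionNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def read_edgelist(path, threshold: float = 0.95) -> CoexpressionNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    for r in df.itertuples():
        g.add_edge(r.gene_a, r.gene_b, weight=float(r.weight))
    return CoexpressionNetwork(g, threshold)
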