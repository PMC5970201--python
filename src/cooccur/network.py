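"""Positive co-occurrence graphs and their null-model statistics.

Nodes are OTUs; an unweighted edge joins two OTUs when their estimated
correlation passes the threshold (ρ ≥ r_min) and survives FDR control
(q ≤ fdr).  Clustering beyond chance is quantified as the ratio of the
observed transitivity to the median transitivity of G(n, m) random graphs
with the same number of nodes and edges.  Per-node keystone metrics are the
normalized degree and the unweighted shortest-path betweenness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .sparcc import CorrelationResult

__all__ = [
    "NullDistribution",
    "NetworkReport",
    "build_network",
    "transitivity",
    "random_graph",
    "clustering_ratio",
    "node_statistics",
    "rank_keystone",
    "export_network",
    "read_edge_list",
    "read_graphml",
    "network_report",
]


@dataclass
class NullDistribution:
    """Transitivity values of G(n, m) replicates matched to an observed graph."""

    n_replicates: int
    transitivity_values: np.ndarray
    median: float
    seed: int | None = None

    @classmethod
    def from_values(cls, values, seed=None) -> "NullDistribution":
        values = np.asarray(values, dtype=float)
        return cls(len(values), values, float(np.median(values)), seed)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.transitivity_values, q))


@dataclass
class NetworkReport:
    """Observed transitivity, null comparison and per-node keystone statistics."""

    transitivity_observed: float
    clustering_ratio: float | None  # None when the null median is 0 (undefined)
    null: NullDistribution
    node_stats: pd.DataFrame
    n_nodes: int
    n_nodes_with_edges: int
    n_edges: int
    has_connected_triples: bool = True

    def to_dict(self) -> dict:
        return {
            "transitivity_observed": self.transitivity_observed,
            "clustering_ratio": self.clustering_ratio,
            "clustering_ratio_defined": self.clustering_ratio is not None,
            "has_connected_triples": self.has_connected_triples,
            "null": {
                "n_replicates": self.null.n_replicates,
                "median": self.null.median,
                "q025": self.null.quantile(0.025),
                "q975": self.null.quantile(0.975),
            },
            "n_nodes": self.n_nodes,
            "n_nodes_with_edges": self.n_nodes_with_edges,
            "n_edges": self.n_edges,
            "node_stats": self.node_stats.reset_index()
            .rename(columns={"index": "otu_id"})
            .to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_network(
    result: CorrelationResult,
    abundance: dict[str, float] | None = None,
    taxonomy: dict[str, str] | None = None,
    r_min: float = 0.3,
    fdr: float = 0.05,
    positive_only: bool = True,
) -> nx.Graph:
    """Build the significant-correlation graph.

    Edge rule: ρ ≥ r_min (or |ρ| ≥ r_min when negative correlations are kept)
    AND q ≤ fdr; both thresholds inclusive.  Every OTU is retained as a node,
    including isolates.
    """
    graph = nx.Graph()
    abundance = abundance or {}
    taxonomy = taxonomy or {}
    for otu in result.otu_ids:
        attrs = {}
        if otu in abundance:
            attrs["abundance"] = float(abundance[otu])
        if otu in taxonomy:
            attrs["taxonomy"] = str(taxonomy[otu])
        graph.add_node(otu, **attrs)
    d = len(result.otu_ids)
    for i in range(d):
        for j in range(i + 1, d):
            rho = float(result.rho[i, j])
            q = float(result.qvals[i, j])
            passes_rho = rho >= r_min if positive_only else abs(rho) >= r_min
            if passes_rho and q <= fdr:
                graph.add_edge(result.otu_ids[i], result.otu_ids[j], rho=rho, q=q)
    return graph


def transitivity(graph: nx.Graph) -> float:
    """Global transitivity: 3 × triangles / connected triples (0 if no triples)."""
    return float(nx.transitivity(graph))


def has_connected_triples(graph: nx.Graph) -> bool:
    return any(d >= 2 for _, d in graph.degree())


def random_graph(n_nodes: int, n_edges: int, seed=None) -> nx.Graph:
    """Uniform draw from simple graphs with exactly n_nodes and n_edges (G(n, m))."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges is infeasible for {n_nodes} nodes (max {max_edges})")
    if seed is not None and not isinstance(seed, (int, np.integer)):
        seed = np.random.default_rng(seed)
    return nx.gnm_random_graph(n_nodes, n_edges, seed=seed)


def clustering_ratio(
    graph: nx.Graph, n_null: int = 1000, seed=None
) -> tuple[float | None, NullDistribution, float]:
    """Observed transitivity over the median null transitivity.

    Returns ``(ratio, null, observed)``; ratio is None (undefined) when the
    null median is 0.
    """
    if graph.number_of_edges() < 1:
        raise ValueError("clustering ratio needs a graph with at least one edge")
    rng = np.random.default_rng(seed)
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    values = np.empty(n_null)
    for k in range(n_null):
        values[k] = transitivity(random_graph(n, m, seed=rng))
    null = NullDistribution.from_values(
        values, seed=seed if isinstance(seed, (int, np.integer)) else None
    )
    observed = transitivity(graph)
    ratio = observed / null.median if null.median > 0 else None
    return ratio, null, observed


def node_statistics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree, normalized degree and unweighted betweenness.

    Betweenness gives fractional credit across equal-length shortest paths and
    is unnormalized.  Isolated nodes score 0/0 and are flagged unrankable.
    """
    n = graph.number_of_nodes()
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    rows = []
    for node in graph.nodes():
        deg = degree[node]
        rows.append(
            {
                "degree": deg,
                "normalized_degree": deg / (n - 1) if n > 1 else 0.0,
                "betweenness": betweenness[node],
                "rankable": deg > 0,
            }
        )
    return pd.DataFrame(
        rows,
        index=list(graph.nodes()),
        columns=["degree", "normalized_degree", "betweenness", "rankable"],
    )


def rank_keystone(stats: pd.DataFrame) -> pd.DataFrame:
    """Rank nodes by normalized degree and by betweenness (rank 1 = highest).

    Ties break lexicographically by OTU id.  Zero-degree nodes cannot be
    ranked and carry empty (NA) ranks.
    """
    out = stats.copy()
    out["degree_rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["betweenness_rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    rankable = out.index[out["rankable"]]
    for metric, col in (("normalized_degree", "degree_rank"), ("betweenness", "betweenness_rank")):
        order = sorted(rankable, key=lambda o: (-out.loc[o, metric], str(o)))
        for rank, otu in enumerate(order, start=1):
            out.loc[otu, col] = rank
    return out


def export_network(graph: nx.Graph, path, format: str = "edge_list_tsv") -> None:
    """Write the graph as an edge-list TSV or GraphML with node/edge attributes."""
    path = str(path)
    if format == "edge_list_tsv":
        rows = [
            {"source": u, "target": v, "rho": d.get("rho", ""), "q": d.get("q", "")}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "q"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_edge_list(path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for _, row in df.iterrows():
        attrs = {}
        if "rho" in df.columns and pd.notna(row.get("rho")) and row.get("rho") != "":
            attrs["rho"] = float(row["rho"])
        if "q" in df.columns and pd.notna(row.get("q")) and row.get("q") != "":
            attrs["q"] = float(row["q"])
        graph.add_edge(str(row["source"]), str(row["target"]), **attrs)
    return graph


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def network_report(graph: nx.Graph, n_null: int = 1000, seed=None) -> NetworkReport:
    """Full report: transitivity vs null, clustering ratio, keystone ranks.

    The null comparison is made on the subgraph of nodes that carry at least
    one edge (the "positive graph" actually analysed); node statistics and
    ranks cover all nodes, with isolates unranked.
    """
    stats = rank_keystone(node_statistics(graph))
    connected_nodes = [n for n, d in graph.degree() if d > 0]
    core = graph.subgraph(connected_nodes)
    if core.number_of_edges() >= 1:
        ratio, null, observed = clustering_ratio(core, n_null=n_null, seed=seed)
    else:
        ratio = None
        null = NullDistribution.from_values(np.zeros(1), seed=None)
        observed = 0.0
    return NetworkReport(
        transitivity_observed=observed,
        clustering_ratio=ratio,
        null=null,
        node_stats=stats,
        n_nodes=graph.number_of_nodes(),
        n_nodes_with_edges=len(connected_nodes),
        n_edges=graph.number_of_edges(),
        has_connected_triples=has_connected_triples(core),
    )
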