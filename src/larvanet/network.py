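"""Directed MPA graph and node-importance metrics.

Nodes are MPAs; a directed edge i -> j exists wherever larvae transfer
(c(i,j) above the edge threshold, strictly greater than 0 by default).
Self-loops are excluded — self-recruitment is reported separately by the
connectivity stage.  Node metrics follow the directed-graph conventions:

* degree: number of distinct neighbor MPAs (union of in- and out-neighbors;
  a reciprocal pair contributes 1);
* indegree / outdegree: distinct upstream / downstream neighbors;
* betweenness bc(i) = sum over ordered pairs x != y != i of
  sigma_xy(i) / sigma_xy, with sigma_xy the number of shortest directed
  x -> y paths (fewest hops) and sigma_xy(i) those through i; pairs with no
  path contribute 0.  A weighted variant (edge length -log c) is available
  but off by default.

Edges with c >= 0.001 carry a demographic-relevance flag: weaker
connections may matter genetically but not demographically.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from larvanet.connectivity import DEMOGRAPHIC_THRESHOLD


def build_graph(c_matrix: pd.DataFrame, threshold: float = 0.0) -> nx.DiGraph:
    """Directed graph with edge i -> j iff i != j and c(i,j) > threshold."""
    c = np.asarray(c_matrix, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"c_matrix must be square, got shape {c.shape}")
    labels = list(c_matrix.index)
    if list(c_matrix.columns) != labels:
        raise ValueError("c_matrix row and column labels must match")
    g = nx.DiGraph(edge_threshold=threshold)
    g.add_nodes_from(labels)
    for a, i in zip(labels, range(len(labels))):
        for b, j in zip(labels, range(len(labels))):
            if i != j and c[i, j] > threshold:
                g.add_edge(a, b, weight=float(c[i, j]),
                           demographic=bool(c[i, j] >= DEMOGRAPHIC_THRESHOLD))
    return g


def node_metrics(graph: nx.DiGraph, weighted_betweenness: bool = False
                 ) -> pd.DataFrame:
    """Degree, indegree, outdegree, and betweenness per node.

    ``weighted_betweenness`` switches shortest paths from fewest-hops to
    minimal -log(c) length (strong connections are short).
    """
    nodes = list(graph.nodes)
    indeg = {n: len(set(graph.predecessors(n))) for n in nodes}
    outdeg = {n: len(set(graph.successors(n))) for n in nodes}
    deg = {n: len(set(graph.predecessors(n)) | set(graph.successors(n)))
           for n in nodes}
    if weighted_betweenness:
        h = graph.copy()
        for _, _, d in h.edges(data=True):
            d["length"] = -np.log(max(d["weight"], 1e-300))
        bc = nx.betweenness_centrality(h, normalized=False, weight="length")
    else:
        bc = nx.betweenness_centrality(graph, normalized=False)
    out = pd.DataFrame({
        "degree": pd.Series(deg),
        "indegree": pd.Series(indeg),
        "outdegree": pd.Series(outdeg),
        "betweenness": pd.Series(bc),
    }).loc[nodes]
    out.index.name = "mpa_id"
    return out


def summarize_network(graph: nx.DiGraph, metrics: pd.DataFrame,
                      selfr: pd.Series | None = None,
                      subr: pd.Series | None = None,
                      latitudes: dict[str, float] | None = None,
                      top_k: int = 5) -> dict:
    """Human-readable network report.

    Lists isolated MPAs, weakly connected clusters, edge counts, the share
    of demographically relevant connections, north->south vs south->north
    edge percentages (when node latitudes are supplied), and the top-k nodes
    by each metric.
    """
    if set(graph.nodes) != set(metrics.index):
        raise ValueError("graph nodes and metrics index disagree")
    nodes = list(graph.nodes)
    isolated = [n for n in nodes if metrics.loc[n, "degree"] == 0]
    components = [sorted(c) for c in
                  nx.weakly_connected_components(graph) if len(c) > 1]
    components.sort(key=lambda c: (-len(c), c))
    n_edges = graph.number_of_edges()
    n_demo = sum(1 for _, _, d in graph.edges(data=True) if d.get("demographic"))
    report = {
        "n_nodes": len(nodes),
        "n_edges": n_edges,
        "n_connected": len(nodes) - len(isolated),
        "isolated": sorted(isolated),
        "isolation_pct": 100.0 * len(isolated) / len(nodes) if nodes else 0.0,
        "clusters": components,
        "n_clusters": len(components),
        "demographic_edges": n_demo,
        "demographic_pct": 100.0 * n_demo / n_edges if n_edges else 0.0,
        "top": {col: metrics[col].sort_values(ascending=False)
                .head(top_k).to_dict() for col in metrics.columns},
    }
    if latitudes is not None:
        missing = [n for n in nodes if n not in latitudes]
        if missing:
            report["direction_warning"] = (
                f"no latitude for {sorted(missing)}; direction section omitted")
        else:
            southward = sum(1 for a, b in graph.edges
                            if latitudes[a] > latitudes[b])
            northward = sum(1 for a, b in graph.edges
                            if latitudes[a] < latitudes[b])
            report["southward_edges"] = southward
            report["northward_edges"] = northward
            directed = southward + northward
            report["southward_pct"] = (100.0 * southward / directed
                                       if directed else 0.0)
    if selfr is not None:
        report["pure_self_recruitment"] = sorted(
            selfr.index[np.isclose(selfr, 1.0)].tolist())
        report["zero_self_recruitment"] = sorted(
            selfr.index[(selfr == 0.0)
                        & (subr > 0 if subr is not None else True)].tolist())
    return report


def export_edge_list(graph: nx.DiGraph, path) -> None:
    """Edge-list CSV: origin, destination, weight, demographic flag."""
    rows = [(a, b, d.get("weight", 1.0), bool(d.get("demographic", False)))
            for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["origin", "destination", "weight",
                                "demographic"]).to_csv(path, index=False)


def export_graph(graph: nx.DiGraph, path) -> None:
    """Graph exchange export (GML, a standard text format)."""
    nx.write_gml(graph, path)


def report_to_text(report: dict) -> str:
    """Render the summary report as readable text."""
    lines = [
        f"MPA network: {report['n_nodes']} nodes, {report['n_edges']} edges",
        f"Isolated MPAs ({report['isolation_pct']:.1f}%): "
        + (", ".join(report["isolated"]) or "none"),
        f"Clusters (weakly connected, >1 node): {report['n_clusters']}",
    ]
    for c in report["clusters"]:
        lines.append("  - " + ", ".join(c))
    lines.append(f"Demographically relevant edges (c >= "
                 f"{DEMOGRAPHIC_THRESHOLD}): {report['demographic_edges']} "
                 f"({report['demographic_pct']:.0f}%)")
    if "southward_pct" in report:
        lines.append(f"North-to-south edges: {report['southward_edges']} "
                     f"({report['southward_pct']:.0f}%), south-to-north: "
                     f"{report['northward_edges']}")
    for metric, top in report["top"].items():
        ranked = ", ".join(f"{k}={v:.3g}" for k, v in top.items())
        lines.append(f"Top {metric}: {ranked}")
    return "\n".join(lines)
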