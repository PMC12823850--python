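"""Thresholded coherence graphs and the graph-theory metric suite.

A brain graph is built from a band coherence matrix by keeping the edges whose
magnitude-squared coherence exceeds a threshold (default 0.30, chosen to
suppress spurious connections). On the resulting graph we compute segregation
and hub measures per node:

* clustering coefficient  CC_i = 2 t_i / (k_i (k_i - 1)), with t_i the number
  of triangles through node i and k_i its degree;
* local efficiency        LE_i = mean inverse shortest-path length between
  the neighbors of i, with paths restricted to i's neighborhood subgraph;
* in-/out-degree          number of incoming / outgoing edges;
* in-/out-closeness       1 / sum of shortest-path lengths to (or from) the
  reachable nodes; an isolated node scores 0;
* betweenness             sum over pairs s != t != i of the fraction of
  shortest s-t paths passing through i (unnormalized; unordered pairs on
  undirected graphs, ordered pairs on directed ones).

Coherence is symmetric, so coherence-derived graphs are undirected and the
in/out variants coincide; the directed forms are provided for adjacency
matrices supplied from elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .spectral import CoherenceMatrix

#: Default coherence cutoff for edge inclusion (strict >).
DEFAULT_THRESHOLD = 0.30

METRIC_NAMES = ("CC", "LE", "in_degree", "out_degree",
                "in_closeness", "out_closeness", "betweenness")


@dataclass
class BrainGraph:
    """Binary (possibly directed) graph over the montage channels."""

    nodes: tuple
    adjacency: np.ndarray          # (n, n) of {0, 1}; adjacency[i, j]: edge i -> j
    weights: np.ndarray | None = None  # retained coherence values on kept edges
    band: str | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.nodes):
            raise ValueError("adjacency size must match node count")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diagonal(a).any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def is_symmetric(self) -> bool:
        return bool((self.adjacency == self.adjacency.T).all())

    def undirected_adjacency(self) -> np.ndarray:
        """OR-symmetrized view of the adjacency."""
        return ((self.adjacency + self.adjacency.T) > 0).astype(int)

    def to_networkx(self, directed=None):
        if directed is None:
            directed = not self.is_symmetric
        if directed:
            g = nx.from_numpy_array(self.adjacency, create_using=nx.DiGraph)
        else:
            g = nx.from_numpy_array(self.undirected_adjacency())
        return nx.relabel_nodes(g, dict(enumerate(self.nodes)))

    def n_edges(self) -> int:
        """Undirected edge count for symmetric graphs, arc count otherwise."""
        total = int(self.adjacency.sum())
        return total // 2 if self.is_symmetric else total


@dataclass
class NodeMetricTable:
    """Per-node values of one graph metric plus the global mean."""

    metric_name: str
    nodes: tuple
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.nodes),):
            raise ValueError("one value per node required")

    @property
    def global_mean(self) -> float:
        return float(self.values.mean())

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.nodes),
                         name=self.metric_name)


def threshold_adjacency(C: CoherenceMatrix, tau=DEFAULT_THRESHOLD,
                        mode="absolute") -> BrainGraph:
    """Build a brain graph from a coherence matrix.

    ``mode="absolute"`` keeps edge (a, b) iff C[a, b] > tau (the default
    reading of a "30% coherence threshold"); ``mode="proportional"`` instead
    keeps the strongest ``tau`` fraction of possible edges (edge-density
    thresholding), for users who read the threshold as a network density.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must lie in [0, 1)")
    values = np.array(C.values, dtype=float)
    np.fill_diagonal(values, 0.0)
    if mode == "absolute":
        adj = (values > tau).astype(int)
    elif mode == "proportional":
        n = values.shape[0]
        iu = np.triu_indices(n, k=1)
        n_keep = int(round(tau * len(iu[0])))
        adj = np.zeros_like(values, dtype=int)
        if n_keep > 0:
            order = np.argsort(values[iu])[::-1][:n_keep]
            rows, cols = iu[0][order], iu[1][order]
            adj[rows, cols] = adj[cols, rows] = 1
    else:
        raise ValueError("mode must be 'absolute' or 'proportional'")
    np.fill_diagonal(adj, 0)
    weights = np.where(adj > 0, values, 0.0)
    return BrainGraph(tuple(C.channel_labels), adj, weights=weights,
                      band=C.band.name)


def from_adjacency(adjacency, nodes=None) -> BrainGraph:
    """Wrap a user-supplied (possibly directed) binary adjacency matrix."""
    adjacency = np.asarray(adjacency)
    if nodes is None:
        nodes = tuple(f"N{i}" for i in range(adjacency.shape[0]))
    return BrainGraph(tuple(nodes), adjacency)


def clustering_coefficient(G: BrainGraph) -> NodeMetricTable:
    """Per-node clustering coefficient on the undirected view.

    Nodes with degree < 2 have no neighbor pair and score 0.
    """
    g = nx.from_numpy_array(G.undirected_adjacency())
    cc = nx.clustering(g)
    return NodeMetricTable("CC", G.nodes,
                           [cc[i] for i in range(G.n_nodes)])


def local_efficiency(G: BrainGraph) -> NodeMetricTable:
    """Per-node local efficiency on the undirected view.

    LE_i averages 1/d(j, h) over ordered neighbor pairs (j, h) of node i,
    with shortest paths confined to the subgraph induced by i's neighbors;
    unreachable pairs contribute 0 and nodes with degree < 2 score 0.
    """
    adj = G.undirected_adjacency()
    g = nx.from_numpy_array(adj)
    values = []
    for i in range(G.n_nodes):
        neigh = list(g.neighbors(i))
        k = len(neigh)
        if k < 2:
            values.append(0.0)
            continue
        sub = g.subgraph(neigh)
        total = 0.0
        for j, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(1.0 / d for h, d in lengths.items() if h != j)
        values.append(total / (k * (k - 1)))
    return NodeMetricTable("LE", G.nodes, values)


def degree_centrality(G: BrainGraph, direction="out") -> NodeMetricTable:
    """In-degree (column sums) or out-degree (row sums) per node."""
    if direction == "in":
        values = G.adjacency.sum(axis=0)
    elif direction == "out":
        values = G.adjacency.sum(axis=1)
    else:
        raise ValueError("direction must be 'in' or 'out'")
    return NodeMetricTable(f"{direction}_degree", G.nodes, values)


def closeness_centrality(G: BrainGraph, direction="out") -> NodeMetricTable:
    """Reciprocal summed shortest-path length to the reachable set.

    ``direction="out"`` sums distances from i to every node it can reach;
    ``direction="in"`` sums distances from every node that can reach i.
    Nodes reaching nothing (or unreached, for "in") score 0.
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    g = nx.from_numpy_array(G.adjacency, create_using=nx.DiGraph)
    if direction == "in":
        g = g.reverse(copy=False)
    values = []
    for i in range(G.n_nodes):
        lengths = nx.single_source_shortest_path_length(g, i)
        total = sum(d for node, d in lengths.items() if node != i)
        values.append(1.0 / total if total > 0 else 0.0)
    return NodeMetricTable(f"{direction}_closeness", G.nodes, values)


def betweenness_centrality(G: BrainGraph) -> NodeMetricTable:
    """Unnormalized shortest-path betweenness (Brandes accumulation).

    Counts unordered source-target pairs on undirected graphs and ordered
    pairs on directed graphs.
    """
    directed = not G.is_symmetric
    if directed:
        g = nx.from_numpy_array(G.adjacency, create_using=nx.DiGraph)
    else:
        g = nx.from_numpy_array(G.undirected_adjacency())
    bw = nx.betweenness_centrality(g, normalized=False)
    return NodeMetricTable("betweenness", G.nodes,
                           [bw[i] for i in range(G.n_nodes)])


def metric_suite(C: CoherenceMatrix, tau=DEFAULT_THRESHOLD, mode="absolute",
                 subject=None, state=None) -> dict:
    """Threshold a coherence matrix and compute all seven node-metric tables."""
    G = threshold_adjacency(C, tau=tau, mode=mode)
    tables = {
        "CC": clustering_coefficient(G),
        "LE": local_efficiency(G),
        "in_degree": degree_centrality(G, "in"),
        "out_degree": degree_centrality(G, "out"),
        "in_closeness": closeness_centrality(G, "in"),
        "out_closeness": closeness_centrality(G, "out"),
        "betweenness": betweenness_centrality(G),
    }
    meta = {"band": C.band.name, "tau": tau, "mode": mode,
            "subject": subject, "state": state}
    return {"graph": G, "tables": tables, "meta": meta}


def metrics_long_frame(suite) -> pd.DataFrame:
    """Long-format table (subject, state, band, node, metric, value)."""
    meta = suite["meta"]
    rows = []
    for name, table in suite["tables"].items():
        for node, value in zip(table.nodes, table.values):
            rows.append({"subject": meta["subject"], "state": meta["state"],
                         "band": meta["band"], "node": node,
                         "metric": name, "value": value})
    return pd.DataFrame(rows)


def graph_to_edgelist_frame(G: BrainGraph) -> pd.DataFrame:
    """Edge list (chan_a, chan_b, weight) for TSV export."""
    rows = []
    sym = G.is_symmetric
    n = G.n_nodes
    for a in range(n):
        for b in range(a + 1 if sym else 0, n):
            if a != b and G.adjacency[a, b]:
                w = G.weights[a, b] if G.weights is not None else 1.0
                rows.append({"chan_a": G.nodes[a], "chan_b": G.nodes[b],
                             "weight": w})
    return pd.DataFrame(rows, columns=["chan_a", "chan_b", "weight"])
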