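"""Centrality indices on the weighted, nonnegative MGM network.

Edge weights are association strengths, so shortest-path measures use
the length transform d_ij = 1 / w_ij (stronger association = shorter
path). Three indices per node:

* strength  S_i = Σ_j w_ij — direct connectedness;
* closeness C_i = 1 / Σ_j d(i, j) over nodes reachable from i —
  indirect connectedness; isolated nodes get C = 0 and a disconnection
  warning is attached because closeness loses its interpretation on a
  disconnected graph;
* betweenness B_i — the number of shortest paths between other node
  pairs that pass strictly through i, with tied shortest paths each
  contributing their fractional share (Brandes' convention; each
  unordered pair counted once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["CentralityTable", "strength", "closeness", "betweenness",
           "centrality_table", "to_graph"]


@dataclass(frozen=True)
class CentralityTable:
    table: pd.DataFrame          # columns S, C, B indexed by node
    connected: bool

    def standardized(self) -> pd.DataFrame:
        """z-scored centralities, as plotted in centrality profile figures."""
        t = self.table
        return (t - t.mean()) / t.std(ddof=1)


def _check_weights(weight: np.ndarray) -> np.ndarray:
    W = np.asarray(weight, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    return W


def to_graph(weight: np.ndarray, names: list[str] | None = None) -> nx.Graph:
    W = _check_weights(weight)
    p = W.shape[0]
    names = list(names) if names is not None else [f"v{i}" for i in range(p)]
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] > 0:
                G.add_edge(names[i], names[j], weight=W[i, j], length=1.0 / W[i, j])
    return G


def strength(weight: np.ndarray, names: list[str] | None = None) -> pd.Series:
    W = _check_weights(weight)
    names = list(names) if names is not None else [f"v{i}" for i in range(W.shape[0])]
    return pd.Series(W.sum(axis=1), index=names, name="S")


def closeness(weight: np.ndarray, names: list[str] | None = None) -> pd.Series:
    G = to_graph(weight, names)
    vals = {}
    disconnected = False
    for node in G.nodes:
        dist = nx.single_source_dijkstra_path_length(G, node, weight="length")
        total = sum(d for other, d in dist.items() if other != node)
        reached = len(dist) - 1
        if reached < len(G) - 1:
            disconnected = True
        vals[node] = 1.0 / total if reached > 0 and total > 0 else 0.0
    if disconnected:
        warnings.warn("graph is disconnected; closeness sums over reachable nodes only",
                      stacklevel=2)
    return pd.Series(vals, name="C")


def betweenness(weight: np.ndarray, names: list[str] | None = None) -> pd.Series:
    G = to_graph(weight, names)
    b = nx.betweenness_centrality(G, weight="length", normalized=False)
    return pd.Series(b, name="B")


def centrality_table(weight: np.ndarray, names: list[str] | None = None) -> CentralityTable:
    S = strength(weight, names)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        C = closeness(weight, names)
    connected = not any("disconnected" in str(w.message) for w in caught)
    B = betweenness(weight, names)
    return CentralityTable(table=pd.DataFrame({"S": S, "C": C, "B": B}),
                           connected=connected)
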