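"""Condensate interaction network: valency and eigenvector centrality.

The connectivity map is an undirected, unweighted graph of condensate
components (proteins plus an RNA node); constitutive complexes such as
Lsm1-7 are collapsed to a single node before analysis.  A component's
valency is its number of distinct interaction partners (degree), and its
eigenvector centrality is its entry in the dominant eigenvector of the
adjacency matrix, where links to well-connected partners count for more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Default collapse map for the constitutive Lsm1-7 assembly.
LSM_COLLAPSE = {f"Lsm{i}": "Lsm1-7" for i in range(1, 8)}


@dataclass
class ConnectivityGraph:
    """An interaction graph with per-node centrality scores."""

    graph: nx.Graph
    centrality: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def load_edge_list(path, collapse: dict[str, str] | None = None) -> ConnectivityGraph:
    """Read a two-column TSV of node-name pairs into an undirected graph.

    A collapse map (member → complex name) is applied before deduplication,
    so a complex inherits the union of its members' edges; internal edges
    become self-loops and are dropped.  Self-loop *rows* in the input are
    rejected with their row number.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["a", "b"], dtype=str, skip_blank_lines=True)
    collapse = collapse or {}
    g = nx.Graph()
    for row, (a, b) in enumerate(zip(df["a"], df["b"]), start=1):
        if pd.isna(a) or pd.isna(b):
            continue
        a, b = a.strip(), b.strip()
        if a == b:
            raise ValueError(f"self-loop at row {row}: {a!r}")
        a = collapse.get(a, a)
        b = collapse.get(b, b)
        if a != b:                               # intra-complex edge collapses away
            g.add_edge(a, b)
    return ConnectivityGraph(g)


def valency(cg: ConnectivityGraph, node: str) -> int:
    """Number of distinct interaction partners (degree)."""
    if node not in cg.graph:
        raise KeyError(f"unknown node {node!r}")
    return int(cg.graph.degree[node])


def eigenvector_centrality(cg: ConnectivityGraph, component_of: str | None = None,
                           tol: float = 1e-12, max_iter: int = 100_000,
                           ) -> dict[str, float]:
    """Eigenvector centrality by power iteration, L2-normalized.

    Iterates on ``A + I`` — the spectral shift leaves eigenvectors unchanged
    but makes the dominant eigenvalue strictly largest in magnitude, so the
    iteration converges even on bipartite components where plain power
    iteration oscillates.  Restricted to the connected component containing
    ``component_of`` (e.g. the RNA node) when given.
    """
    g = cg.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if component_of is not None:
        if component_of not in g:
            raise KeyError(f"unknown node {component_of!r}")
        g = g.subgraph(nx.node_connected_component(g, component_of))
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    v = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        w = a @ v + v                            # (A + I) v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    v /= np.linalg.norm(v)
    scores = {n: float(s) for n, s in zip(nodes, v)}
    cg.centrality.update(scores)
    return scores


def centrality_table(cg: ConnectivityGraph,
                     component_of: str | None = None) -> pd.DataFrame:
    """Per-node valency and eigenvector centrality, sorted by centrality."""
    scores = eigenvector_centrality(cg, component_of=component_of)
    rows = [{"node": n, "valency": valency(cg, n), "centrality": c}
            for n, c in scores.items()]
    return (pd.DataFrame(rows)
            .sort_values("centrality", ascending=False)
            .reset_index(drop=True))
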