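"""Hub-target identification on a protein-protein interaction network.

Nodes of a simple undirected PPI graph are ranked by three topological
scores — Degree, Maximum Neighborhood Component (MNC, the size of the
largest connected component induced by a node's open neighborhood) and
Maximal Clique Centrality (MCC, the sum of (|C| - 1)! over the maximal
cliques of size >= 2 containing the node) — and densely connected modules
are extracted with the MCODE seed-and-grow procedure.  Maximal cliques are
enumerated exactly (Bron-Kerbosch with pivoting, via networkx); all
tie-breaks are by node symbol so rankings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class DenseModule:
    members: tuple[str, ...]
    seed: str
    score: float          # module density x module size


def read_edge_list(path: str | Path, min_score: float | None = 0.4) -> nx.Graph:
    """Read a TSV edge list (node_a, node_b[, score]) into a simple graph.

    When a third column is present, edges with score below ``min_score`` are
    skipped.  Self-loops and duplicate edges are discarded.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if len(row) > 2 and row[2] is not None and min_score is not None:
            if float(row[2]) < min_score:
                continue
        if a != b:
            g.add_edge(a, b)
    return g


def _check_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("a simple undirected graph is required")
    if any(graph.has_edge(v, v) for v in graph):
        raise ValueError("self-loops are not allowed")


def degree(graph: nx.Graph) -> dict[str, float]:
    """Edge count at each node."""
    _check_simple(graph)
    return {v: float(d) for v, d in graph.degree()}


def mnc(graph: nx.Graph) -> dict[str, float]:
    """Size of the largest connected component of each open neighborhood."""
    _check_simple(graph)
    out = {}
    for v in graph:
        nbrs = list(graph.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = graph.subgraph(nbrs)
        out[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return out


def mcc(graph: nx.Graph) -> dict[str, float]:
    """Maximal clique centrality: sum of (|C| - 1)! over maximal cliques at v."""
    _check_simple(graph)
    scores = {v: 0.0 for v in graph}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        contrib = float(factorial(len(clique) - 1))
        for v in clique:
            scores[v] += contrib
    return scores


def top_k(scores: dict[str, float], k: int = 10) -> list[str]:
    """Top-k nodes by descending score, ties by symbol; min(k, n) returned."""
    ranked = sorted(scores, key=lambda v: (-scores[v], v))
    return ranked[: max(k, 0)]


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_weights(graph: nx.Graph) -> dict[str, float]:
    """Core-clustering weight: density of the highest k-core of N[v], times k."""
    _check_simple(graph)
    weights = {}
    for v in graph:
        closed = graph.subgraph(list(graph.neighbors(v)) + [v])
        core_num = nx.core_number(closed)
        k_max = max(core_num.values())
        core_nodes = [u for u, c in core_num.items() if c >= k_max]
        weights[v] = k_max * _density(closed.subgraph(core_nodes))
    return weights


def mcode(graph: nx.Graph, k_core: int = 2, score_cutoff: float = 0.2,
          haircut: bool = True, fluff: bool = False,
          ) -> list[DenseModule]:
    """MCODE dense-module detection (seed, grow, haircut, k-core filter).

    Seeds are taken in descending core-clustering weight (ties by symbol);
    a module grows outward from its seed over still-unassigned nodes whose
    weight is at least ``(1 - score_cutoff) * seed weight``.  The haircut
    step iteratively removes members with fewer than two within-module
    neighbors; modules whose induced subgraph lacks a ``k_core``-core are
    discarded.  The fluff stage is not implemented (kept off).
    """
    if fluff:
        raise NotImplementedError("fluff stage is not implemented")
    _check_simple(graph)
    weights = mcode_weights(graph)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    modules: list[DenseModule] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = (1.0 - score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in sorted(graph.neighbors(v)):
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append(u)
        if haircut:
            sub = graph.subgraph(members).copy()
            while True:
                weak = [v for v, d in sub.degree() if d < 2]
                if not weak:
                    break
                sub.remove_nodes_from(weak)
            members = set(sub.nodes)
        assigned |= members | {seed}
        if members:
            sub = graph.subgraph(members)
            if max(nx.core_number(sub).values(), default=0) < k_core:
                continue
            modules.append(DenseModule(tuple(sorted(members)),
                                       seed, _density(sub) * len(members)))
    return modules
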