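"""Topology statistics of the inferred regulatory network.

Betweenness follows the shortest-path counting definition: for node v,

    Bet(v) = sum over ordered pairs s != t (both != v, with at least one
             shortest s->t path) of sigma_st(v) / sigma_st

where sigma_st counts shortest s->t paths and sigma_st(v) those passing
through v as an intermediate node (endpoints never count).  Values are
unnormalized.  Self-loops are ignored by every metric here; edges are
treated as unweighted (topology only).

"Important" modules are those ranking highest in in-degree (I),
out-degree (O) or betweenness (B) — either the top k per criterion or
the 95th percentile per criterion, both with ties at the cutoff included.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkStats",
    "ImportanceLabel",
    "betweenness",
    "degree_stats",
    "density_and_clustering",
    "compute_stats",
    "important_grms",
]


@dataclass
class NetworkStats:
    per_node: pd.DataFrame  # index node, columns in_degree, out_degree, betweenness
    density: float
    mean_clustering_coefficient: float


@dataclass(frozen=True)
class ImportanceLabel:
    module_id: object
    flags: frozenset  # subset of {"I", "O", "B"}


def _simple(graph: nx.DiGraph) -> nx.DiGraph:
    g = graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def betweenness(graph: nx.DiGraph) -> dict:
    """Unnormalized directed betweenness (Brandes), self-loops ignored."""
    return nx.betweenness_centrality(_simple(graph), normalized=False)


def degree_stats(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node in/out degree, self-loops excluded."""
    g = _simple(graph)
    nodes = list(g.nodes)
    return pd.DataFrame(
        {
            "in_degree": [g.in_degree(v) for v in nodes],
            "out_degree": [g.out_degree(v) for v in nodes],
        },
        index=nodes,
    )


def density_and_clustering(graph: nx.DiGraph) -> tuple[float, float]:
    """Graph density (non-self edges over n(n-1)) and the mean clustering
    coefficient of the undirected projection (nodes of degree < 2
    contribute 0, averaged over all nodes)."""
    g = _simple(graph)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density is undefined for graphs with fewer than 2 nodes")
    density = g.number_of_edges() / (n * (n - 1))
    clustering = nx.average_clustering(g.to_undirected())
    return float(density), float(clustering)


def compute_stats(graph: nx.DiGraph) -> NetworkStats:
    deg = degree_stats(graph)
    bet = betweenness(graph)
    deg["betweenness"] = [bet[v] for v in deg.index]
    density, clustering = density_and_clustering(graph)
    return NetworkStats(per_node=deg, density=density, mean_clustering_coefficient=clustering)


_CRITERIA = (("in_degree", "I"), ("out_degree", "O"), ("betweenness", "B"))


def important_grms(
    stats: pd.DataFrame | NetworkStats,
    mode: str = "top_k",
    k: int = 20,
    percentile: float = 95.0,
) -> list[ImportanceLabel]:
    """Modules ranking highest on any of the three network criteria.

    ``mode="top_k"``: the k highest scores per criterion (ties at the
    cutoff all included).  ``mode="percentile"``: scores at or above the
    given percentile per criterion.  A module is listed iff it carries at
    least one flag.
    """
    df = stats.per_node if isinstance(stats, NetworkStats) else stats
    flags: dict[object, set] = {}
    for column, letter in _CRITERIA:
        scores = df[column].to_numpy(dtype=float)
        if scores.size == 0:
            continue
        if mode == "top_k":
            kk = min(k, scores.size)
            cutoff = np.sort(scores)[::-1][kk - 1]
        elif mode == "percentile":
            cutoff = np.percentile(scores, percentile)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for node, s in zip(df.index, scores):
            if s >= cutoff:
                flags.setdefault(node, set()).add(letter)
    return [
        ImportanceLabel(module_id=node, flags=frozenset(fl))
        for node, fl in sorted(flags.items(), key=lambda kv: str(kv[0]))
    ]
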