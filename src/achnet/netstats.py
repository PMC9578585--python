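"""Network summary statistics and centrality measures.

Density is the ratio of realized to potential edges, ``|E| / (n(n-1)/2)``.
Transitivity is the global clustering coefficient,
``3 x triangles / connected triples`` — the tendency of two organizations
with a common partner to also collaborate with each other.

Closeness is the *harmonic* form: the sum over all other nodes of the
inverse shortest-path distance, with unreachable nodes contributing zero.
The harmonic form is used deliberately instead of Freeman closeness because
coalition site networks are frequently disconnected (isolated organizations
are common among non-central members), and the inverse-distance sum is
well-defined there without special-casing. It is not normalized by (n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from achnet.netbuild import Pair, SiteNetwork

__all__ = [
    "density",
    "transitivity",
    "degree",
    "harmonic_closeness",
    "degree_vector",
    "closeness_vector",
    "layer_graph",
    "NetworkSummary",
    "summarize_site",
    "summary_table",
]

LAYERS = ("preexisting", "grant", "sustained")


def density(edges: Iterable[Pair], n: int) -> float:
    """Edge count over possible dyads, for an undirected simple graph."""
    if n < 2:
        raise ValueError(f"density undefined for n={n} nodes")
    return 2.0 * len(set(edges)) / (n * (n - 1))


def transitivity(edges: Iterable[Pair]) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples.

    Returns 0.0 when the graph has no connected triples.
    """
    g = nx.Graph()
    g.add_edges_from(edges)
    return nx.transitivity(g)


def layer_graph(network: SiteNetwork, layer: str) -> nx.Graph:
    """The named layer of a site network as a networkx graph over all nodes."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.layer(layer))
    return g


def degree(edges: Iterable[Pair], nodes: Sequence[str], node: str) -> int:
    """Number of edges incident to ``node``."""
    if node not in set(nodes):
        raise ValueError(f"unknown node {node!r}")
    return sum(node in pair for pair in set(edges))


def harmonic_closeness(edges: Iterable[Pair], nodes: Sequence[str], node: str) -> float:
    """Sum of inverse shortest-path distances from ``node`` to every other
    node, counting unreachable nodes as zero."""
    if node not in set(nodes):
        raise ValueError(f"unknown node {node!r}")
    return closeness_vector(edges, nodes)[list(nodes).index(node)]


def _adjacency(edges: Iterable[Pair], nodes: Sequence[str]) -> np.ndarray:
    index = {node: i for i, node in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
    for u, v in edges:
        adj[index[u], index[v]] = 1
        adj[index[v], index[u]] = 1
    return adj


def degree_vector(edges: Iterable[Pair], nodes: Sequence[str]) -> np.ndarray:
    """Degrees of all nodes, in roster order."""
    return _adjacency(edges, nodes).sum(axis=1).astype(float)


def closeness_vector(edges: Iterable[Pair], nodes: Sequence[str]) -> np.ndarray:
    """Harmonic closeness of all nodes, in roster order.

    Distances come from BFS over the unweighted adjacency matrix; ``1/inf``
    for unreachable pairs is taken as 0.
    """
    adj = _adjacency(edges, nodes)
    if adj.shape[0] == 0:
        return np.zeros(0)
    dist = shortest_path(adj, method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0  # self-distances and unreachable pairs
    return inv.sum(axis=1)


@dataclass
class NetworkSummary:
    """Per-site descriptive statistics across the three nested layers.

    ``density`` and ``transitivity`` are means over the imputed completions
    when the site required imputation; ``observed_edges`` counts edges in
    the pre-imputation data.
    """

    site_id: str
    n_nodes: int
    possible_dyads: int
    missing_dyads: int
    density: Dict[str, float] = field(default_factory=dict)
    transitivity: Dict[str, float] = field(default_factory=dict)
    edge_count: Dict[str, float] = field(default_factory=dict)
    observed_edges: Dict[str, int] = field(default_factory=dict)

    @property
    def missing_fraction(self) -> float:
        return self.missing_dyads / self.possible_dyads


def summarize_site(
    completions: Sequence[SiteNetwork], observed: SiteNetwork
) -> NetworkSummary:
    """Summarize one site over its ``m`` imputed completions.

    Density, transitivity and edge counts are averaged over completions per
    layer; observed (pre-imputation) edge counts are reported alongside.
    With a single completion and no missing dyads this reduces to direct
    statistics on the observed network.
    """
    if not completions:
        raise ValueError("need at least one completion")
    for comp in completions:
        if comp.site_id != observed.site_id:
            raise ValueError(
                f"completion site {comp.site_id!r} != observed site "
                f"{observed.site_id!r}"
            )
    summary = NetworkSummary(
        site_id=observed.site_id,
        n_nodes=observed.n,
        possible_dyads=observed.possible_dyads,
        missing_dyads=len(observed.missing),
    )
    for layer in LAYERS:
        dens = [density(c.layer(layer), c.n) for c in completions]
        trans = [transitivity(c.layer(layer)) for c in completions]
        counts = [len(c.layer(layer)) for c in completions]
        summary.density[layer] = float(np.mean(dens))
        summary.transitivity[layer] = float(np.mean(trans))
        summary.edge_count[layer] = float(np.mean(counts))
        summary.observed_edges[layer] = len(observed.layer(layer))
    summary.observed_edges["stimulated"] = len(observed.stimulated)
    return summary


def summary_table(summaries: Sequence[NetworkSummary]) -> pd.DataFrame:
    """Render summaries as a site-characteristics table (rows: measures,
    columns: sites)."""
    columns = {}
    for s in summaries:
        columns[s.site_id] = {
            "n_nodes": s.n_nodes,
            "possible_dyads": s.possible_dyads,
            "missing_dyads_pct": round(100.0 * s.missing_fraction, 1),
            "preexisting_edges_obs": s.observed_edges["preexisting"],
            "stimulated_edges_obs": s.observed_edges["stimulated"],
            "sustained_edges_obs": s.observed_edges["sustained"],
            "density_preexisting": round(s.density["preexisting"], 3),
            "density_grant": round(s.density["grant"], 3),
            "density_sustained": round(s.density["sustained"], 3),
            "transitivity_preexisting": round(s.transitivity["preexisting"], 3),
            "transitivity_grant": round(s.transitivity["grant"], 3),
            "transitivity_sustained": round(s.transitivity["sustained"], 3),
        }
    return pd.DataFrame(columns)
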