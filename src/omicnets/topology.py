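"""Topological profiling of inferred networks.

Summarizes the contrasts drawn between the three response networks:
small-world coefficient against Erdos-Renyi references, power-law degree
exponent by continuous MLE, and the low/mid/high degree bands used to
arrange nodes in hiveplots.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

__all__ = ["clustering_coefficient", "smallworld_sigma",
           "powerlaw_gamma_mle", "degree_classes", "TopologySummary",
           "summarize_topology"]


def clustering_coefficient(G: nx.Graph) -> float:
    """Average local clustering coefficient; degree<2 nodes contribute 0."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return float(nx.average_clustering(G))


def _largest_component(G: nx.Graph) -> nx.Graph:
    return G.subgraph(max(nx.connected_components(G), key=len))


def smallworld_sigma(G: nx.Graph, n_rand: int = 100,
                     seed: int | None = None) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    References are Erdos-Renyi graphs with the same node and edge counts;
    path lengths are measured on largest connected components.
    """
    if G.number_of_nodes() < 2 or G.number_of_edges() == 0:
        raise ValueError("graph too small for sigma")
    giant = _largest_component(G)
    C = clustering_coefficient(G)
    L = nx.average_shortest_path_length(giant)
    n, m = G.number_of_nodes(), G.number_of_edges()
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_rand):
        R = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        cs.append(nx.average_clustering(R))
        ls.append(nx.average_shortest_path_length(_largest_component(R)))
    c_rand, l_rand = float(np.mean(cs)), float(np.mean(ls))
    if C == 0 or c_rand == 0:
        return 0.0
    return (C / c_rand) / (L / l_rand)


def powerlaw_gamma_mle(degrees, kmin: int = 1) -> float:
    """Continuous-approximation MLE of the power-law degree exponent:
    ``gamma = 1 + n / sum(ln(k_i / (kmin - 0.5)))`` over degrees >= kmin."""
    degrees = np.asarray([d for d in degrees if d >= kmin], dtype=float)
    if degrees.size < 10:
        raise ValueError("need >= 10 degrees at or above kmin")
    if np.all(degrees == kmin):
        raise ValueError("all degrees equal kmin; exponent diverges")
    s = np.log(degrees / (kmin - 0.5)).sum()
    return float(1.0 + degrees.size / s)


def degree_classes(G: nx.Graph, lo: int = 30, hi: int = 80) -> dict:
    """Hiveplot bands: degree < lo -> low; lo <= degree <= hi -> mid;
    degree > hi -> high."""
    out = {}
    for node, deg in G.degree():
        out[node] = "low" if deg < lo else ("mid" if deg <= hi else "high")
    return out


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    max_degree: int
    global_clustering: float
    avg_path_length: float
    smallworld_sigma: float
    gamma: float
    degree_classes: dict

    def to_dict(self):
        return asdict(self)


def summarize_topology(G: nx.Graph, n_rand: int = 100,
                       seed: int | None = None) -> TopologySummary:
    degs = [d for _, d in G.degree()]
    giant = _largest_component(G) if G.number_of_edges() else G
    try:
        gamma = powerlaw_gamma_mle(degs)
    except ValueError:
        gamma = float("nan")
    try:
        sigma = smallworld_sigma(G, n_rand=n_rand, seed=seed)
    except ValueError:
        sigma = float("nan")
    return TopologySummary(
        n_nodes=G.number_of_nodes(),
        n_edges=G.number_of_edges(),
        mean_degree=float(np.mean(degs)) if degs else 0.0,
        max_degree=max(degs, default=0),
        global_clustering=clustering_coefficient(G) if degs else 0.0,
        avg_path_length=(nx.average_shortest_path_length(giant)
                         if giant.number_of_edges() else float("nan")),
        smallworld_sigma=sigma,
        gamma=gamma,
        degree_classes=degree_classes(G))
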