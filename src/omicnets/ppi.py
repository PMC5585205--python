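"""Empirical connectivity significance of a query gene set in an interactome.

A query's direct interaction network is compared with degree-matched random
node sets: each query node is replaced by a node drawn from its logarithmic
(base-2) degree bin, without replacement within a draw. Reported statistics
are the direct edge count and the mean direct degree, each with an empirical
permutation p-value of the form (1 + exceedances) / (1 + permutations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["direct_network", "permutation_test", "replicate_edges",
           "ConnectivityResult"]


@dataclass
class ConnectivityResult:
    n_direct_edges: int
    mean_direct_degree: float
    empirical_p_edges: float
    empirical_p_degree: float
    n_perm: int
    seed: int | None


def direct_network(query, net: nx.Graph) -> nx.Graph:
    """Induced subgraph of the interactome on the query genes."""
    query = set(query)
    present = query & set(net.nodes())
    absent = query - present
    if absent:
        warnings.warn(f"{len(absent)} query genes absent from the "
                      f"interactome (e.g. {sorted(absent)[:3]})")
    return net.subgraph(present).copy()


def _degree_bins(net: nx.Graph) -> dict[int, list]:
    """log2 degree bins: bin(k) = floor(log2(k)) (degree-0 nodes get -1)."""
    bins: dict[int, list] = {}
    for node, deg in net.degree():
        b = -1 if deg == 0 else int(np.log2(deg))
        bins.setdefault(b, []).append(node)
    return {b: sorted(members) for b, members in bins.items()}


def permutation_test(query, net: nx.Graph, n_perm: int = 1000,
                     seed: int | None = None) -> ConnectivityResult:
    """Degree-matched empirical significance of direct connectivity."""
    rng = np.random.default_rng(seed)
    present = sorted(set(query) & set(net.nodes()))
    if len(present) < 2:
        raise ValueError("need >= 2 query genes present in the interactome")

    nodes = sorted(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    A = nx.to_numpy_array(net, nodelist=nodes, weight=None).astype(bool)
    deg = A.sum(axis=1)

    def stats(idx):
        sub = A[np.ix_(idx, idx)]
        return int(sub.sum() // 2), float(deg[idx].mean())

    obs_idx = np.array([index[v] for v in present])
    obs_edges, obs_degree = stats(obs_idx)

    bins = _degree_bins(net)
    query_bins: dict[int, int] = {}
    for v in present:
        d = net.degree(v)
        b = -1 if d == 0 else int(np.log2(d))
        query_bins[b] = query_bins.get(b, 0) + 1

    bin_members = {}
    ordered_bins = sorted(bins)
    for b, need in query_bins.items():
        members = list(bins.get(b, []))
        width = 0
        while len(members) < need:
            width += 1
            members = []
            for bb in ordered_bins:
                if abs(bb - b) <= width:
                    members.extend(bins[bb])
            if width > len(ordered_bins):
                raise ValueError("cannot degree-match the query")
        if width:
            warnings.warn(f"degree bin {b} widened by {width} to reach "
                          f"{need} candidates")
        bin_members[b] = np.array([index[m] for m in members])

    exceed_edges = exceed_degree = 0
    for _ in range(n_perm):
        draw = []
        taken: set[int] = set()
        for b, need in query_bins.items():
            cand = bin_members[b]
            picked = rng.permutation(cand)
            got = 0
            for c in picked:
                if c not in taken:
                    taken.add(int(c))
                    draw.append(int(c))
                    got += 1
                    if got == need:
                        break
            if got < need:
                raise ValueError("degree bin exhausted during draw")
        e, d = stats(np.array(draw))
        exceed_edges += e >= obs_edges
        exceed_degree += d >= obs_degree

    return ConnectivityResult(
        n_direct_edges=obs_edges,
        mean_direct_degree=obs_degree,
        empirical_p_edges=(1 + exceed_edges) / (1 + n_perm),
        empirical_p_degree=(1 + exceed_degree) / (1 + n_perm),
        n_perm=n_perm, seed=seed)


def replicate_edges(edge_list, reference_net: nx.Graph
                    ) -> tuple[int, int, float]:
    """How many of the given edges exist in a reference interactome."""
    edge_list = list(edge_list)
    if not edge_list:
        raise ValueError("empty edge list")
    k = sum(reference_net.has_edge(u, v) for u, v in edge_list)
    return k, len(edge_list), k / len(edge_list)
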