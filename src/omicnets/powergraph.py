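"""Lossless power-graph decomposition and super-power-node detection.

A power graph re-expresses a simple graph with power nodes (sets of base
nodes) and power edges, where a power edge between disjoint sets U and V
abstracts every U-V base edge (a biclique) and a power edge from a set to
itself abstracts every internal pair (a clique). The decomposition here is
strict: every base edge is abstracted by exactly one power edge, and the
family of power nodes is laminar (any two are nested or disjoint), which
makes losslessness (``expand(decompose(G)) == E(G)``) directly checkable.

A super-power node (SPN) is a connected set of power nodes in the power
graph structure: power nodes are linked when they share a power edge or when
one is nested inside the other, and a connected component counts as an SPN
when it contains at least two power nodes of size >= 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = ["PowerGraph", "SPN", "candidate_power_nodes", "decompose",
           "expand", "find_spns", "edge_reduction", "power_graph_analysis"]


def _edge(u, v) -> frozenset:
    return frozenset((u, v))


def _laminar(a: frozenset, b: frozenset) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


@dataclass
class PowerGraph:
    base_nodes: list
    power_nodes: list[frozenset]            # the size->=2 family (laminar)
    power_edges: list[tuple[frozenset, frozenset, frozenset]]
    # each power edge: (U, V, set of abstracted base edges); U may equal V

    def n_base_edges(self) -> int:
        return sum(len(e) for *_, e in self.power_edges)

    def to_dict(self) -> dict:
        return {
            "base_nodes": sorted(map(str, self.base_nodes)),
            "power_nodes": [sorted(map(str, pn)) for pn in
                            sorted(self.power_nodes, key=lambda s: sorted(s))],
            "power_edges": [
                {"u": sorted(map(str, u)), "v": sorted(map(str, v)),
                 "edges": sorted(sorted(map(str, e)) for e in edges)}
                for u, v, edges in self.power_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PowerGraph":
        return cls(
            base_nodes=list(d["base_nodes"]),
            power_nodes=[frozenset(pn) for pn in d["power_nodes"]],
            power_edges=[(frozenset(pe["u"]), frozenset(pe["v"]),
                          frozenset(frozenset(e) for e in pe["edges"]))
                         for pe in d["power_edges"]])


@dataclass
class SPN:
    label: str
    member_power_nodes: list[frozenset]
    member_proteins: set
    hub: str

    sort_key: tuple = field(default=(), repr=False)


def _cut_sets(nodes: list, dist_condensed: np.ndarray) -> list[frozenset]:
    """All internal merge sets of an average-linkage dendrogram (laminar)."""
    n = len(nodes)
    if n < 2:
        return []
    Z = linkage(dist_condensed, method="average")
    clusters: dict[int, frozenset] = {i: frozenset([nodes[i]])
                                      for i in range(n)}
    out = []
    for k, (i, j, *_ ) in enumerate(Z):
        merged = clusters[int(i)] | clusters[int(j)]
        clusters[n + k] = merged
        out.append(merged)
    return out


def candidate_power_nodes(G: nx.Graph) -> list[frozenset]:
    """Candidate power nodes from average-linkage clustering of nodes under
    Jaccard similarity of neighborhoods.

    Run twice: on open neighborhoods N(v) (groups biclique sides) and on
    closed neighborhoods N(v) | {v} (groups cliques). Every dendrogram merge
    set of size >= 2 from either run is a candidate; the union is
    deduplicated. Each run's family is laminar by construction.
    """
    nodes = sorted(G.nodes())
    n = len(nodes)
    if n < 2:
        return []
    cands: set[frozenset] = set()
    for closed in (False, True):
        nbrs = []
        for v in nodes:
            s = set(G.neighbors(v))
            if closed:
                s.add(v)
            nbrs.append(s)
        d = np.zeros(n * (n - 1) // 2)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                union = len(nbrs[i] | nbrs[j])
                sim = 1.0 if union == 0 else len(nbrs[i] & nbrs[j]) / union
                d[k] = 1.0 - sim
                k += 1
        cands.update(_cut_sets(nodes, d))
    return sorted(cands, key=lambda s: (len(s), sorted(s)))


def _pair_key(U: frozenset, V: frozenset) -> tuple:
    a, b = sorted((sorted(map(str, U)), sorted(map(str, V))))
    return (a, b)


def decompose(G: nx.Graph, candidates: list[frozenset] | None = None
              ) -> PowerGraph:
    """Greedy strict decomposition.

    Repeatedly select the candidate pair (U, V) — disjoint sets, or U = V
    for a clique — whose required base edges are all present and all still
    uncovered, maximizing the number of edges abstracted (minimum 2); ties
    go to the smaller |U|+|V|, then to the lexicographically smallest pair.
    Selected power nodes must stay laminar. Remaining edges are emitted as
    singleton-singleton power edges.
    """
    if candidates is None:
        candidates = candidate_power_nodes(G)
    adj = {v: set(G.neighbors(v)) for v in G.nodes()}
    sets = sorted({frozenset(c) for c in candidates if len(c) >= 2},
                  key=lambda s: (len(s), sorted(map(str, s))))
    singletons = [frozenset([v]) for v in sorted(G.nodes())]
    pool = sets + singletons

    # static enumeration of valid (biclique/clique) pairs with priority
    common = {}
    for s in pool:
        it = iter(s)
        c = set(adj[next(it)])
        for v in it:
            c &= adj[v]
        common[s] = c
    pairs = []
    for i, U in enumerate(pool):
        cu = common[U]
        # clique pair (U, U): every internal pair is an edge
        if len(U) >= 3 and all(U - {u} <= adj[u] for u in U):
            edges = frozenset(_edge(a, b)
                              for a, b in itertools.combinations(U, 2))
            pairs.append((-len(edges), len(U) * 2, _pair_key(U, U),
                          U, U, edges))
        for V in pool[i + 1:]:
            if len(U) == 1 and len(V) == 1:
                continue
            if not U.isdisjoint(V) or not V <= cu:
                continue
            count = len(U) * len(V)
            if count < 2:
                continue
            edges = frozenset(_edge(a, b)
                              for a, b in itertools.product(U, V))
            pairs.append((-count, len(U) + len(V), _pair_key(U, V),
                          U, V, edges))
    pairs.sort(key=lambda t: t[:3])

    covered: set[frozenset] = set()
    chosen_nodes: list[frozenset] = []
    power_edges: list[tuple[frozenset, frozenset, frozenset]] = []
    for *_, U, V, edges in pairs:
        if edges & covered:
            continue
        ok = True
        for sel in chosen_nodes:
            if not (_laminar(U, sel) and _laminar(V, sel)):
                ok = False
                break
        if not ok or not _laminar(U, V) and U != V:
            continue
        if U != V and not U.isdisjoint(V):
            continue
        covered |= edges
        for s in (U, V):
            if len(s) >= 2 and s not in chosen_nodes:
                chosen_nodes.append(s)
        power_edges.append((U, V, edges))

    for u, v in sorted(map(sorted, G.edges())):
        e = _edge(u, v)
        if e not in covered:
            covered.add(e)
            power_edges.append((frozenset([u]), frozenset([v]),
                                frozenset([e])))
    return PowerGraph(base_nodes=list(G.nodes()),
                      power_nodes=chosen_nodes, power_edges=power_edges)


def expand(pg: PowerGraph) -> set[frozenset]:
    """Base edge set abstracted by the power graph; fails on any overlap
    between power edges (which would break the strict decomposition)."""
    out: set[frozenset] = set()
    for u, v, edges in pg.power_edges:
        if out & edges:
            raise ValueError("power edges overlap: decomposition invalid")
        out |= edges
    return out


def edge_reduction(pg: PowerGraph) -> float:
    """Compression ratio: base edges per power edge."""
    if not pg.power_edges:
        raise ValueError("power graph has no edges")
    return pg.n_base_edges() / len(pg.power_edges)


def find_spns(pg: PowerGraph, base_graph: nx.Graph | None = None
              ) -> list[SPN]:
    """Connected groups of power nodes.

    Meta-graph vertices are the size->=2 power nodes plus singletons
    incident to them through power edges; meta edges join the two endpoint
    power nodes of every power edge. Components containing >= 2 power nodes
    of size >= 2 are SPNs, sorted by protein count (descending). The hub of
    an SPN is its member of maximal base-graph degree (ties to the
    lexicographically smallest name).
    """
    big = [pn for pn in pg.power_nodes if len(pn) >= 2]
    meta = nx.Graph()
    meta.add_nodes_from(big)
    for u, v, _ in pg.power_edges:
        if len(u) >= 2 or len(v) >= 2:
            meta.add_edge(u, v)

    if base_graph is not None:
        degree = dict(base_graph.degree())
    else:
        degree = {}
        for u, v, edges in pg.power_edges:
            for e in edges:
                for x in e:
                    degree[x] = degree.get(x, 0) + 1

    spns = []
    for comp in nx.connected_components(meta):
        comp_big = [pn for pn in comp if len(pn) >= 2]
        if len(comp_big) < 2:
            continue
        proteins = set().union(*comp)
        hub = min(proteins, key=lambda p: (-degree.get(p, 0), str(p)))
        spns.append(SPN(label="", member_power_nodes=sorted(
                            comp, key=lambda s: (-len(s), sorted(map(str, s)))),
                        member_proteins=proteins, hub=hub,
                        sort_key=(-len(proteins), sorted(map(str, proteins)))))
    spns.sort(key=lambda s: s.sort_key)
    for i, s in enumerate(spns, start=1):
        s.label = f"SPN{i}"
    return spns


def power_graph_analysis(G: nx.Graph) -> tuple[PowerGraph, list[SPN]]:
    """Full pipeline: candidates -> decompose -> SPNs."""
    pg = decompose(G)
    return pg, find_spns(pg, base_graph=G)
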