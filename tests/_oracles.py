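"""Independent brute-force oracles used by the tests only."""

import itertools

import networkx as nx


def _pairs(nodes):
    sets = []
    for k in range(1, len(nodes) + 1):
        sets.extend(frozenset(c) for c in itertools.combinations(nodes, k))
    for i, U in enumerate(sets):
        if len(U) >= 3:
            yield U, U
        for V in sets[i + 1:]:
            if U.isdisjoint(V) and len(U) * len(V) >= 2:
                yield U, V


def _required(U, V):
    if U == V:
        return {frozenset(p) for p in itertools.combinations(U, 2)}
    return {frozenset(p) for p in itertools.product(U, V)}


def _laminar_ok(s, chosen):
    return all(s.isdisjoint(c) or s <= c or c <= s for c in chosen)


def oracle_decompose_edges(G: nx.Graph):
    """Brute-force greedy power-graph cover over ALL subset pairs.

    Re-evaluates every pair each round (no shared machinery with the
    implementation). Returns (power_edges, chosen_power_nodes) where each
    power edge is (U, V, abstracted edge set).
    """
    nodes = sorted(G.nodes())
    all_edges = {frozenset(e) for e in G.edges()}
    covered = set()
    chosen = []
    power_edges = []
    while True:
        best = None
        for U, V in _pairs(nodes):
            req = _required(U, V)
            if not req <= all_edges or req & covered:
                continue
            if not (_laminar_ok(U, chosen) and _laminar_ok(V, chosen)):
                continue
            key = (-len(req), len(U) + len(V),
                   sorted((sorted(map(str, U)), sorted(map(str, V)))))
            if best is None or key < best[0]:
                best = (key, U, V, req)
        if best is None:
            break
        _, U, V, req = best
        covered |= req
        power_edges.append((U, V, frozenset(req)))
        for s in (U, V):
            if len(s) >= 2 and s not in chosen:
                chosen.append(s)
    for e in sorted(sorted(map(str, e)) for e in all_edges - covered):
        u, v = e
        power_edges.append((frozenset([u]), frozenset([v]),
                            frozenset([frozenset([u, v])])))
    return power_edges, chosen


def enumerate_hypergeom_tail(k, K, n, N):
    """P(X >= k) by exhaustively enumerating all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += len(marked.intersection(draw)) >= k
    return hits / total
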