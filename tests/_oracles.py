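"""Independent brute-force oracles for small graphs.

Everything here works on plain adjacency dicts and enumerates simple paths
exhaustively; nothing imports networkx, so these are independent checks of
the package's graph computations (practical only for tiny graphs).
"""

from __future__ import annotations

import itertools

import numpy as np


def undirected_adj(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def all_simple_paths(adj, s, t, _seen=None):
    seen = _seen or {s}
    if s == t:
        yield (s,)
        return
    for w in adj[s]:
        if w not in seen:
            for rest in all_simple_paths(adj, w, t, seen | {w}):
                yield (s,) + rest


def shortest_paths(adj, s, t):
    """All shortest simple paths s..t, by full enumeration."""
    paths = list(all_simple_paths(adj, s, t))
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def brute_path_centralities(nodes, edges):
    """(betweenness, harmonic closeness, eccentricity) per node on the
    undirected view, from exhaustive shortest-path enumeration."""
    adj = undirected_adj(nodes, edges)
    bet = {v: 0.0 for v in nodes}
    harm = {v: 0.0 for v in nodes}
    ecc = {v: 0 for v in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = shortest_paths(adj, s, t)
        if not paths:
            continue
        d = len(paths[0]) - 1
        harm[s] += 1.0 / d
        harm[t] += 1.0 / d
        ecc[s] = max(ecc[s], d)
        ecc[t] = max(ecc[t], d)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    return bet, harm, ecc


def brute_edge_betweenness(nodes, edges):
    adj = undirected_adj(nodes, edges)
    keys = {tuple(sorted(e)) for e in edges}
    score = {e: 0.0 for e in keys}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = shortest_paths(adj, s, t)
        for p in paths:
            for a, b in zip(p, p[1:]):
                score[tuple(sorted((a, b)))] += 1.0 / len(paths)
    return score


def brute_alpha_series(nodes, dag_edges, alpha, e=1.0):
    """Alpha centrality by the power series sum_k alpha^k (A^T)^k e, summed
    to nilpotency (valid on DAGs)."""
    order = sorted(nodes)
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for u, v in dag_edges:
        a[idx[u], idx[v]] = 1.0
    evec = np.full(n, float(e))
    x = np.zeros(n)
    term = evec.copy()
    for _ in range(n + 1):
        x += term
        term = alpha * (a.T @ term)
        if not term.any():
            break
    return {v: x[idx[v]] for v in order}


def brute_degrees(nodes, directed_edges):
    ind = {v: 0 for v in nodes}
    outd = {v: 0 for v in nodes}
    for u, v in directed_edges:
        outd[u] += 1
        ind[v] += 1
    return ind, outd


def random_graph(rng, n, p):
    nodes = [f"n{i}" for i in range(n)]
    edges = [(nodes[i], nodes[j])
             for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return nodes, edges


def random_dag(rng, n, p):
    nodes = [f"n{i}" for i in range(n)]
    edges = [(nodes[i], nodes[j])
             for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return nodes, edges
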