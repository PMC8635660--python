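"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (plain BFS, explicit
summation, union-find) and deliberately avoids the library code paths it
checks.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


# -- graph helpers (adjacency dict of sets) ---------------------------------

def adjacency(nodes, edges) -> dict:
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_distances(adj, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


# -- per-node parameters -----------------------------------------------------

def bf_betweenness(adj) -> dict:
    """Normalized betweenness via per-source shortest-path counting.

    sigma[s][v] counts shortest s–v paths by DP over BFS layers; a node v
    lies on a shortest s–t path iff d(s,v) + d(v,t) = d(s,t), contributing
    sigma[s][v] * sigma[v][t] / sigma[s][t].
    """
    nodes = list(adj)
    n = len(nodes)
    raw = {v: 0.0 for v in nodes}
    dist = {s: bfs_distances(adj, s) for s in nodes}
    sigma = {}
    for s in nodes:
        counts = {s: 1}
        for u in sorted(dist[s], key=dist[s].get):
            if u == s:
                continue
            counts[u] = sum(counts[w] for w in adj[u]
                            if dist[s].get(w, math.inf) == dist[s][u] - 1)
        sigma[s] = counts

    for s, t in combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        for v in nodes:
            if v in (s, t):
                continue
            if dist[s].get(v, math.inf) + dist[v].get(t, math.inf) == d_st:
                raw[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    scale = (n - 1) * (n - 2) / 2
    return {v: (raw[v] / scale if scale > 0 else 0.0) for v in nodes}


def bf_closeness(adj) -> dict:
    """Per-component closeness (n_reached) / (sum of distances), 0 if isolated."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def bf_clustering(adj) -> dict:
    out = {}
    for v in adj:
        nbrs = list(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def bf_topological_coefficient(adj) -> dict:
    out = {}
    for v in adj:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        ratios = []
        for m in adj:
            if m == v:
                continue
            shared = len(adj[v] & adj[m])
            if shared == 0:
                continue
            ratios.append((shared + (1 if m in adj[v] else 0)) / k)
        out[v] = sum(ratios) / len(ratios) if ratios else 0.0
    return out


# -- network-level indicators ------------------------------------------------

def bf_network_centralization(adj) -> float:
    n = len(adj)
    degs = [len(adj[v]) for v in adj]
    n_edges = sum(degs) // 2
    density = 2.0 * n_edges / (n * (n - 1))
    return (n / (n - 2.0)) * (max(degs) / (n - 1.0) - density)


def bf_cpl(adj) -> float:
    total, pairs = 0, 0
    for s in adj:
        for t, d in bfs_distances(adj, s).items():
            if d > 0:
                total += d
                pairs += 1
    return total / pairs


def bf_heterogeneity(adj) -> float:
    degs = [len(adj[v]) for v in adj]
    mean = sum(degs) / len(degs)
    var = sum((d - mean) ** 2 for d in degs) / len(degs)
    return math.sqrt(var) / mean


def bf_robustness_unionfind(nodes, edges, n_original, n_removed) -> float:
    """Largest-component fraction via union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    sizes = {}
    for n in nodes:
        r = find(n)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values()) / (n_original - n_removed)


# -- entropy method ----------------------------------------------------------

def bf_entropy_method(x_rows, orientations):
    """Direct-summation entropy weighting on a list-of-rows matrix.

    x_rows: list of n rows of m values; orientations: list of m flags.
    Returns (z, b, e, d, w) as plain nested lists.
    """
    n, m = len(x_rows), len(x_rows[0])
    z = [[0.0] * m for _ in range(n)]
    for j in range(m):
        col = [x_rows[i][j] for i in range(n)]
        lo, hi = min(col), max(col)
        for i in range(n):
            if hi == lo:
                z[i][j] = 0.0
            elif orientations[j] == "positive":
                z[i][j] = (col[i] - lo) / (hi - lo)
            else:
                z[i][j] = (hi - col[i]) / (hi - lo)
    b = [[0.0] * m for _ in range(n)]
    e = [0.0] * m
    k = 1.0 / math.log(n)
    for j in range(m):
        colsum = sum(z[i][j] for i in range(n))
        if colsum == 0:
            e[j] = 1.0
            continue
        s = 0.0
        for i in range(n):
            b[i][j] = z[i][j] / colsum
            if b[i][j] > 0:
                s += b[i][j] * math.log(b[i][j])
        e[j] = -k * s
    d = [1.0 - ej for ej in e]
    dsum = sum(d)
    w = [dj / dsum for dj in d]
    return z, b, e, d, w


def bf_contribution_scores(z, w, r_index=3):
    """Weighted sums with the robustness weight doubled."""
    return [
        sum(zi[j] * w[j] * (2.0 if j == r_index else 1.0) for j in range(len(w)))
        for zi in z
    ]


# -- hypergeometric tail -----------------------------------------------------

def bf_hypergeom_tail(overlap, n_universe, n_set, n_selected) -> float:
    """P(X >= overlap) by exhaustive tail summation of the pmf."""
    def c(a, b):
        return math.comb(a, b) if 0 <= b <= a else 0

    denom = c(n_universe, n_selected)
    total = 0
    for x in range(overlap, min(n_set, n_selected) + 1):
        total += c(n_set, x) * c(n_universe - n_set, n_selected - x)
    return total / denom
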