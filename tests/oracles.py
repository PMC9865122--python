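"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration and
direct definitions — and shares no code path with the package.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up, from the definition.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, mapped back
    to the input order.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, pvalues[idx] * m / rank)
        q_sorted[rank - 1] = min(running_min, 1.0)
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return q


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def _shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s-t paths via BFS layering + DFS enumeration."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for v in adj[node]:
            if dist.get(v, -1) == dist[node] + 1 and dist[v] <= dist[t]:
                walk(v, path + [v])

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def betweenness(nodes: list, edges: list[tuple]) -> dict:
    """Unnormalized betweenness by exhaustive shortest-path enumeration.

    Each unordered pair of distinct endpoints contributes 1, split
    evenly over its shortest paths; endpoints are excluded.
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    result = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                result[v] += 1.0 / len(paths)
    return result


def _peel_kcore(nodes: set, edges: set, k: int) -> set:
    """Nodes surviving repeated removal of degree < k vertices."""
    nodes = set(nodes)
    while True:
        deg = {v: 0 for v in nodes}
        for a, b in edges:
            if a in nodes and b in nodes:
                deg[a] += 1
                deg[b] += 1
        low = {v for v in nodes if deg[v] < k}
        if not low:
            return nodes
        nodes -= low


def mcode_vertex_weight(nodes: list, edges: list[tuple], v) -> float:
    """Closed-neighborhood core weight by min-degree peeling.

    Builds v's closed neighborhood, finds the largest k whose k-core is
    non-empty by peeling, and returns k * density of that core.
    """
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    nbhd = {v} | adj[v]
    sub_edges = {(a, b) for a, b in edges
                 if a in nbhd and b in nbhd}
    if not sub_edges:
        return 0.0
    k_max, core = 0, set()
    k = 1
    while True:
        surviving = _peel_kcore(nbhd, sub_edges, k)
        if not surviving:
            break
        k_max, core = k, surviving
        k += 1
    core_edges = [(a, b) for a, b in sub_edges if a in core and b in core]
    m = len(core)
    density = 2.0 * len(core_edges) / (m * (m - 1)) if m > 1 else 0.0
    return k_max * density
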