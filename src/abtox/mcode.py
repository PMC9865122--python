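"""MCODE (Molecular Complex Detection) module finding.

Implements the Bader–Hogue scheme: each vertex is weighted by the
product of the highest k-core number of its closed neighborhood
(the vertex, its neighbors and all induced edges) and that core's
density 2E / (V(V−1)); complexes grow outward from the highest-weight
unvisited seed, admitting neighbors whose weight exceeds the seed
weight times (1 − node score cutoff), to a bounded depth.
Post-processing discards complexes lacking a k-core at the filter
level, optionally shaves degree-1 members (haircut) and optionally
adds dense-neighborhood boundary vertices (fluff).  Module score is
density × member count, and all orderings are deterministic with
lexicographic tie-breaks.

Defaults follow the settings used for the screen's network: node
score cutoff 0.2, k-core filter 2, max depth 100 (haircut on, fluff
off — the reference tool's defaults for the unstated flags).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["McodeParams", "Module", "vertex_weights", "find_modules",
           "annotate_module_labels"]


@dataclass(frozen=True)
class McodeParams:
    node_score_cutoff: float = 0.2
    kcore_filter: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.node_score_cutoff <= 1.0):
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.kcore_filter < 0:
            raise ValueError("kcore_filter must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (0.0 <= self.fluff_density_cutoff <= 1.0):
            raise ValueError("fluff_density_cutoff must be in [0, 1]")


@dataclass(frozen=True)
class Module:
    """One detected complex: sorted member tuple, density × size score."""

    members: tuple[str, ...]
    score: float
    seed: str
    rank: int = 0
    fluffed: tuple[str, ...] = field(default_factory=tuple)

    @property
    def size(self) -> int:
        return len(self.members)


def _density(H: nx.Graph) -> float:
    n = H.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * H.number_of_edges() / (n * (n - 1))


def _highest_kcore(H: nx.Graph) -> tuple[int, nx.Graph]:
    """(k_max, subgraph of the highest k-core) of a simple graph."""
    if H.number_of_edges() == 0:
        return 0, H.subgraph([])
    core_num = nx.core_number(H)
    k_max = max(core_num.values())
    nodes = [v for v, k in core_num.items() if k >= k_max]
    return k_max, H.subgraph(nodes)


def vertex_weights(G: nx.Graph) -> dict[str, float]:
    """Closed-neighborhood core weighting.

    weight(v) = k_max × density of the highest k-core of the subgraph
    induced by v and its neighbors; isolated vertices weigh 0.
    """
    weights: dict[str, float] = {}
    for v in G.nodes:
        nbrs = list(G[v])
        if not nbrs:
            weights[v] = 0.0
            continue
        H = G.subgraph([v] + nbrs)
        k_max, core = _highest_kcore(H)
        weights[v] = k_max * _density(core)
    return weights


def find_modules(G: nx.Graph,
                 params: McodeParams = McodeParams()) -> list[Module]:
    """Detect and rank complexes.

    Seeds are taken in descending weight order (ties lexicographic)
    among unvisited vertices; breadth-limited expansion from seed s
    adds an unvisited neighbor w when
    ``weight(w) > weight(s) * (1 - node_score_cutoff)``.  Every vertex
    touched by an expansion is marked visited even if its complex is
    later discarded, so complexes are vertex-disjoint (fluff, when
    enabled, may re-use boundary vertices and is reported separately).
    """
    if any(u == v for u, v in nx.selfloop_edges(G)):
        raise ValueError("graph must be simple (no self-loops)")
    weights = vertex_weights(G)
    order = sorted(G.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    raw: list[tuple[str, set]] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        queue = deque([(seed, 0)])
        while queue:
            u, depth = queue.popleft()
            if depth >= params.max_depth:
                continue
            for w in sorted(G[u], key=str):
                if w in visited or w in members:
                    continue
                if weights[w] > threshold:
                    members.add(w)
                    visited.add(w)
                    queue.append((w, depth + 1))
        raw.append((seed, members))

    modules: list[Module] = []
    for seed, members in raw:
        M = G.subgraph(members)
        # k-core filter: discard complexes without a core at the cutoff
        if params.kcore_filter > 0:
            core = nx.k_core(M, params.kcore_filter)
            if core.number_of_nodes() == 0:
                continue
        kept = set(members)
        if params.haircut:
            M_h = G.subgraph(kept).copy()
            while True:
                leaves = [v for v in M_h if M_h.degree(v) <= 1]
                if not leaves or M_h.number_of_nodes() <= len(leaves):
                    break
                M_h.remove_nodes_from(leaves)
            kept = set(M_h.nodes)
        fluffed: set = set()
        if params.fluff:
            for v in sorted(kept, key=str):
                for w in sorted(G[v], key=str):
                    if w in kept or w in fluffed:
                        continue
                    nbhd = G.subgraph([w] + list(G[w]))
                    if _density(nbhd) > params.fluff_density_cutoff:
                        fluffed.add(w)
        final = kept | fluffed
        sub = G.subgraph(final)
        score = _density(sub) * sub.number_of_nodes()
        modules.append(Module(members=tuple(sorted(kept, key=str)),
                              score=score, seed=seed,
                              fluffed=tuple(sorted(fluffed, key=str))))

    modules.sort(key=lambda m: (-m.score, m.members))
    return [Module(members=m.members, score=m.score, seed=m.seed,
                   rank=i + 1, fluffed=m.fluffed)
            for i, m in enumerate(modules)]


def annotate_module_labels(modules: list[Module],
                           labels: dict[str, str]) -> pd.DataFrame:
    """Per-module composition of hit labels.

    Genes absent from ``labels`` count as ``unclassified``.  Returns
    one row per module: rank, size, score and one count column per
    label present anywhere.
    """
    counters = []
    all_labels: set[str] = set()
    for mod in modules:
        counts = Counter(labels.get(g, "unclassified") for g in mod.members)
        counters.append(counts)
        all_labels.update(counts)
    rows = []
    for mod, counts in zip(modules, counters):
        row = {"rank": mod.rank, "size": mod.size, "score": mod.score}
        for lab in sorted(all_labels):
            row[f"n_{lab}"] = counts.get(lab, 0)
        rows.append(row)
    cols = ["rank", "size", "score"] + [f"n_{lab}"
                                        for lab in sorted(all_labels)]
    return pd.DataFrame(rows, columns=cols)
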