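"""Seed-based gene prioritization by random walk with restart (RWR).

Guilt-by-association: a walker starts on the seed genes and at each
step either follows a random edge (probability 1 − r) or restarts on
the seed distribution (probability r).  The stationary score vector p
solves

    p = (1 − r) W p + r p0

with W the column-stochastic degree-normalized adjacency and p0 the
normalized seed vector; genes are ranked by p.  Mass landing on
degree-0 nodes is redistributed to p0 so the iteration conserves
probability exactly.

This is a stand-in for service-based guilt-by-association scorers
(e.g. GUILDify's scoring family); output metadata says so.  A small
fixture seed list around the store-operated calcium entry (SOCE)
pathway (SURF4, STIM1, ORAI1, CRACR2A) ships for demonstration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["PropagationConfig", "propagate", "extract_subnetwork",
           "soce_seed_genes"]


@dataclass(frozen=True)
class PropagationConfig:
    """RWR parameters: restart r in (0, 1], L1 tolerance, iteration cap."""

    restart: float = 0.5
    tolerance: float = 1e-6
    max_iterations: int = 1000
    seed_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError("restart must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if any(w < 0 for w in self.seed_weights.values()):
            raise ValueError("seed weights must be >= 0")


def soce_seed_genes() -> list[str]:
    """Demonstration seed list (SOCE pathway genes)."""
    text = (resources.files("abtox.data") / "soce_seeds.txt").read_text()
    return [g.strip() for g in text.splitlines()
            if g.strip() and not g.startswith("#")]


def propagate(G: nx.Graph, seeds: list[str] | dict[str, float],
              config: PropagationConfig = PropagationConfig()) -> pd.Series:
    """Random walk with restart from the seed genes.

    ``seeds`` is a gene list (uniform weights) or a gene -> weight
    mapping; seeds absent from the network are ignored with a warning,
    and no seed in the network at all is an error.  Returns scores as
    a Series summing to 1, sorted descending with lexicographic
    tie-breaks; ``.attrs`` records iterations, residual and the
    approximation note.
    """
    if isinstance(seeds, dict):
        seed_weights = dict(seeds)
    else:
        seed_weights = {s: 1.0 for s in seeds}
    if not seed_weights or all(w == 0 for w in seed_weights.values()):
        raise ValueError("need at least one seed with positive weight")

    nodes = sorted(G.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")

    missing = sorted(set(seed_weights) - set(index))
    if missing:
        warnings.warn(f"{len(missing)} seed(s) not in network: {missing}",
                      stacklevel=2)
    present = {s: w for s, w in seed_weights.items()
               if s in index and w > 0}
    if not present:
        raise ValueError("no seed genes present in the network")

    p0 = np.zeros(n)
    for s, w in present.items():
        p0[index[s]] = w
    p0 /= p0.sum()

    A = nx.to_scipy_sparse_array(G, nodelist=nodes, format="csr",
                                 weight=None, dtype=float)
    deg = np.asarray(A.sum(axis=0)).ravel()
    dangling = deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))

    r = config.restart
    p = p0.copy()
    residual = np.inf
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        walked = A @ (p * inv_deg)          # column-stochastic step
        lost = float(p[dangling].sum())     # dangling mass -> restart
        p_new = (1.0 - r) * (walked + lost * p0) + r * p0
        residual = float(np.abs(p_new - p).sum())
        p = p_new
        if residual < config.tolerance:
            break
    else:
        warnings.warn(f"RWR did not converge in {config.max_iterations} "
                      f"iterations (L1 residual {residual:.2e})",
                      stacklevel=2)

    scores = pd.Series(p, index=nodes, name="score")
    scores = scores.sort_values(ascending=False, kind="mergesort")
    # stable descending sort on a lexicographically sorted index keeps
    # ties in lexicographic order
    scores.attrs.update({
        "iterations": iterations,
        "residual": residual,
        "restart": r,
        "method": ("random walk with restart; approximation standing in "
                   "for service-based guilt-by-association scoring"),
    })
    return scores


def extract_subnetwork(G: nx.Graph, scores: pd.Series, top_m: int,
                       seeds: list[str]) -> nx.Graph:
    """Induced subgraph on the seeds plus the top-scored non-seeds.

    Takes the ``top_m − len(seeds)`` highest-scoring non-seed genes
    (so ``top_m`` equal to the seed count returns the seeds alone) and
    annotates every node with its score and a seed flag.
    """
    if len(scores) == 0:
        raise ValueError("empty score map")
    seed_set = {s for s in seeds if s in G}
    if top_m < len(seed_set):
        raise ValueError(f"top_m={top_m} smaller than seed count "
                         f"{len(seed_set)}")
    non_seed = [g for g in scores.index if g not in seed_set and g in G]
    chosen = set(non_seed[:top_m - len(seed_set)])
    nodes = seed_set | chosen
    sub = G.subgraph(nodes).copy()
    for v in sub.nodes:
        sub.nodes[v]["score"] = float(scores.get(v, np.nan))
        sub.nodes[v]["is_seed"] = v in seed_set
    return sub
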