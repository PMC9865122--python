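"""Confidence-filtered interaction networks and topology metrics.

Builds an undirected gene network from a STRING-style scored edge list,
keeping an edge only when its combined confidence is at least the
medium cutoff (0.4) and at least one of the selected evidence channels
(experiments, curated database, gene fusion) is positive — the channel
selection the screen's interactome analysis used, with no additional
interactors beyond the input gene list.

Topology metrics are the ones used to read the network: degree (hubs),
betweenness centrality (bottlenecks; unnormalized pair counts with
endpoints excluded) and per-node average shortest path length within
the node's connected component (peripheral nodes score high).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["load_string_network", "compute_topology", "rank_topology",
           "write_edge_list", "CHANNEL_ALIASES"]

# STRING export dialects name channels inconsistently
CHANNEL_ALIASES: dict[str, tuple[str, ...]] = {
    "experiments": ("experiments", "experiment", "experimental"),
    "database": ("database", "databases"),
    "fusion": ("fusion", "gene_fusion", "fusions"),
}

DEFAULT_CHANNELS = ("experiments", "database", "fusion")


def _resolve_channel(columns, channel: str) -> str | None:
    for alias in CHANNEL_ALIASES.get(channel, (channel,)):
        if alias in columns:
            return alias
    return None


def load_string_network(edges: pd.DataFrame | str | Path,
                        genes: list[str] | None = None,
                        min_combined: float = 0.4,
                        channels: tuple[str, ...] = DEFAULT_CHANNELS,
                        ) -> nx.Graph:
    """Build the filtered undirected network from a scored edge list.

    Scores may be on the 0–1 or 0–1000 scale; the scale is detected
    from the maximum combined score and recorded in ``G.graph``.  An
    edge is kept iff combined >= ``min_combined`` (on the 0–1 scale)
    and at least one selected channel is positive.  When ``genes`` is
    given, the network is restricted to those genes and isolated input
    genes are retained as nodes.  Malformed rows are counted, skipped
    and reported in ``G.graph["skipped_rows"]``.
    """
    if not isinstance(edges, pd.DataFrame):
        edges = pd.read_csv(edges, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge table lacks columns {sorted(missing)}")

    channel_cols = []
    for ch in channels:
        col = _resolve_channel(edges.columns, ch)
        if col is not None:
            channel_cols.append(col)
    if channels and not channel_cols:
        raise ValueError(f"none of the channels {channels} present in table")

    combined = pd.to_numeric(edges["combined_score"], errors="coerce")
    score_cols = [combined] + [pd.to_numeric(edges[c], errors="coerce")
                               for c in channel_cols]
    overall_max = float(np.nanmax(combined.to_numpy())) if len(edges) else 0.0
    scale = 1000.0 if overall_max > 1.001 else 1.0

    G = nx.Graph()
    G.graph["score_scale"] = scale
    G.graph["min_combined"] = min_combined
    G.graph["channels"] = tuple(channel_cols)
    gene_set = set(genes) if genes is not None else None
    skipped = 0
    for idx in range(len(edges)):
        a = edges["protein1"].iat[idx]
        b = edges["protein2"].iat[idx]
        c = score_cols[0].iat[idx]
        if (not isinstance(a, str)) or (not isinstance(b, str)) or pd.isna(c):
            skipped += 1
            continue
        if a == b:
            skipped += 1  # self-loop
            continue
        if gene_set is not None and (a not in gene_set or b not in gene_set):
            continue
        c_scaled = float(c) / scale
        if c_scaled < min_combined:
            continue
        chans = {col: float(score_cols[k + 1].iat[idx]) / scale
                 for k, col in enumerate(channel_cols)}
        if channel_cols and not any(v > 0 for v in chans.values()):
            continue
        if G.has_edge(a, b):
            if c_scaled <= G[a][b]["combined"]:
                continue
        G.add_edge(a, b, combined=c_scaled, **chans)
    if gene_set is not None:
        G.add_nodes_from(sorted(gene_set))  # isolated inputs retained
    G.graph["skipped_rows"] = skipped
    return G


def compute_topology(G: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, ASPL and component id per node.

    Betweenness is exact (Brandes) and unnormalized: for undirected
    graphs each unordered pair of distinct endpoints contributes 1,
    split evenly across its shortest paths.  ASPL averages unweighted
    shortest-path lengths over the other nodes reachable from the node
    (NaN for isolated nodes).  Components are numbered by decreasing
    size, ties by smallest member name.
    """
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene", "degree", "betweenness",
                                     "aspl", "component"])
    betweenness = nx.betweenness_centrality(G, normalized=False)
    comps = sorted(nx.connected_components(G),
                   key=lambda c: (-len(c), min(c)))
    comp_of = {}
    for cid, comp in enumerate(comps):
        for node in comp:
            comp_of[node] = cid
    rows = []
    for node in sorted(G.nodes):
        lengths = nx.single_source_shortest_path_length(G, node)
        others = [d for tgt, d in lengths.items() if tgt != node]
        aspl = float(np.mean(others)) if others else np.nan
        rows.append((node, G.degree(node), float(betweenness[node]),
                     aspl, comp_of[node]))
    return pd.DataFrame(rows, columns=["gene", "degree", "betweenness",
                                       "aspl", "component"])


def rank_topology(table: pd.DataFrame, k: int,
                  labels: dict[str, str] | None = None,
                  ) -> dict[str, pd.DataFrame]:
    """Top-k genes by degree, betweenness and ASPL.

    Deterministic: sorted by metric descending, ties broken
    lexicographically by gene symbol.  Each returned frame carries a
    ``label`` column (hit classification, "unclassified" when absent)
    so the protective/enhancer composition of each list is readable.
    ``k`` larger than the table returns everything with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(table):
        warnings.warn(f"k={k} exceeds table size {len(table)}; returning all",
                      stacklevel=2)
        k = len(table)
    labels = labels or {}
    out = {}
    for metric in ("degree", "betweenness", "aspl"):
        ranked = table.sort_values([metric, "gene"],
                                   ascending=[False, True],
                                   kind="mergesort").head(k).copy()
        ranked["label"] = [labels.get(g, "unclassified")
                           for g in ranked["gene"]]
        out[metric] = ranked.reset_index(drop=True)
    return out


def write_edge_list(G: nx.Graph, path) -> None:
    """Edge-list TSV with combined and channel scores, sorted."""
    rows = []
    for a, b, data in G.edges(data=True):
        a, b = sorted((a, b))
        row = {"protein1": a, "protein2": b,
               "combined": data.get("combined", np.nan)}
        for col in G.graph.get("channels", ()):
            row[col] = data.get(col, 0.0)
        rows.append(row)
    cols = ["protein1", "protein2", "combined",
            *G.graph.get("channels", ())]
    df = pd.DataFrame(rows, columns=cols)
    if not df.empty:
        df = df.sort_values(["protein1", "protein2"])
    df.to_csv(path, sep="\t", index=False)
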