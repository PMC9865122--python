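"""Over-representation analysis (ORA) against GMT gene sets.

For a query list of n genes drawn from a universe of N genes, a set
with K members in the universe and overlap k is scored with

    enrichment ratio  ER = (k / n) / (K / N)
    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with Benjamini–Hochberg adjustment across all tested sets.  The
universe defaults to every gene annotated anywhere in the collection
("annotated" policy); results are ordered by FDR, then enrichment
ratio descending.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "write_gmt", "hypergeom_upper", "enrichment_ratio",
           "run_ora"]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {ln}: need name, description and "
                             "at least one gene")
        name = fields[0]
        if name in sets:
            raise ValueError(f"GMT line {ln}: duplicate set name {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path=None,
              descriptions: dict[str, str] | None = None) -> str:
    """Serialize gene sets to GMT text; write to ``path`` if given."""
    descriptions = descriptions or {}
    lines = []
    for name, members in sets.items():
        desc = descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if K > N or n > N:
        raise ValueError("set size and query size cannot exceed universe")
    if k > min(n, K):
        raise ValueError("overlap k cannot exceed min(n, K)")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts query genes landing in a K-member set when n genes are
    drawn from a universe of N.  Computed via the survival function in
    log space (exact to machine precision for the universe sizes that
    arise in gene-set testing); k = 0 gives exactly 1.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_ratio(k: int, K: int, n: int, N: int) -> float:
    """Observed/expected overlap: (k/n) / (K/N)."""
    _check_counts(k, K, n, N)
    if n == 0 or K == 0:
        raise ValueError("enrichment ratio undefined for n=0 or K=0")
    return (k / n) / (K / N)


def run_ora(query: list[str], gene_sets: dict[str, list[str]],
            universe: str | list[str] = "annotated",
            min_size: int = 5, max_size: int = 2000) -> pd.DataFrame:
    """Test every admissible gene set against the query.

    ``universe`` is either the string ``"annotated"`` (union of all
    genes in the collection, the default) or an explicit gene list.
    Sets whose in-universe size falls outside [min_size, max_size] are
    skipped; BH runs over the tested sets only.  Query genes are
    deduplicated and intersected with the universe before counting.

    Returns a DataFrame (set_name, N, K, n, k, er, p, q) sorted by
    q, then p, then er descending, then name.
    """
    if universe == "annotated":
        uni: set[str] = set()
        for members in gene_sets.values():
            uni.update(members)
    else:
        uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q_genes = set(query) & uni
    if not q_genes:
        raise ValueError(
            "query does not intersect the universe; check identifier "
            "conventions between query and gene-set collection")

    N, n = len(uni), len(q_genes)
    rows = []
    for name, members in gene_sets.items():
        m = set(members) & uni
        K = len(m)
        if K < min_size or K > max_size:
            continue
        k = len(m & q_genes)
        p = hypergeom_upper(k, K, n, N)
        er = enrichment_ratio(k, K, n, N)
        rows.append((name, N, K, n, k, er, p))
    out = pd.DataFrame(rows, columns=["set_name", "N", "K", "n", "k",
                                      "er", "p"])
    if out.empty:
        out["q"] = np.nan
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values(["q", "p", "er", "set_name"],
                          ascending=[True, True, False, True],
                          kind="mergesort")
    out.attrs["universe_policy"] = (
        "annotated" if universe == "annotated" else "user")
    return out.reset_index(drop=True)
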