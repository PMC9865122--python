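"""Yeast → mammalian ortholog mapping from an offline table.

Mapping is table-driven (TSV: yeast_gene, human_gene, source,
confidence) — no live database queries, so runs are reproducible
against a pinned table.  Yeast-to-human orthology is many-to-many;
the ``best_score`` policy keeps, per yeast gene, the human gene(s) of
maximal confidence (ties kept rather than broken arbitrarily), while
``all`` keeps every pair.  Output is deduplicated at the human-gene
level; a human gene inheriting conflicting hit labels from different
yeast genes is flagged ambiguous.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["read_ortholog_table", "map_orthologs"]

TABLE_COLUMNS = ["yeast_gene", "human_gene", "source", "confidence"]


def read_ortholog_table(path) -> pd.DataFrame:
    """Read and validate a TSV ortholog table."""
    table = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ortholog table lacks columns {sorted(missing)}")
    return validate_ortholog_table(table)


def validate_ortholog_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.duplicated(subset=["yeast_gene", "human_gene"]).any():
        raise ValueError("duplicate (yeast, human) pairs in ortholog table")
    if (table["confidence"] < 0).any():
        raise ValueError("ortholog confidence scores must be >= 0")
    return table


def map_orthologs(hit_calls: pd.DataFrame, table: pd.DataFrame,
                  policy: str = "best_score",
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Project hit calls onto mammalian orthologs.

    Parameters
    ----------
    hit_calls
        DataFrame with columns ``strain`` (yeast gene/ORF) and ``call``.
    table
        Ortholog table (see :data:`TABLE_COLUMNS`).
    policy
        ``best_score`` (max-confidence human gene(s) per yeast gene,
        ties kept) or ``all`` (every pair).

    Returns
    -------
    (mapped, unmapped)
        ``mapped``: one row per human gene with columns human_gene,
        call, ambiguous, yeast_genes, calls, max_confidence.  The
        ``call`` of an ambiguous gene is the literal ``"ambiguous"``;
        the inherited labels survive in ``calls``.
        ``unmapped``: yeast genes absent from the table.
    """
    if policy not in ("best_score", "all"):
        raise ValueError("policy must be 'best_score' or 'all'")
    validate_ortholog_table(table)
    if hit_calls.empty:
        return (pd.DataFrame(columns=["human_gene", "call", "ambiguous",
                                      "yeast_genes", "calls",
                                      "max_confidence"]), [])

    calls = hit_calls.set_index("strain")["call"].to_dict()
    sub = table[table["yeast_gene"].isin(calls)].copy()
    unmapped = sorted(set(calls) - set(sub["yeast_gene"]))

    if policy == "best_score" and not sub.empty:
        best = sub.groupby("yeast_gene")["confidence"].transform("max")
        sub = sub[sub["confidence"] == best]

    records: dict[str, dict] = {}
    for _, rec in sub.iterrows():
        hg = rec["human_gene"]
        entry = records.setdefault(hg, {"yeast": [], "labels": set(),
                                        "conf": 0.0})
        entry["yeast"].append(rec["yeast_gene"])
        entry["labels"].add(calls[rec["yeast_gene"]])
        entry["conf"] = max(entry["conf"], float(rec["confidence"]))

    rows = []
    for hg in sorted(records):
        entry = records[hg]
        labels = sorted(entry["labels"])
        ambiguous = len(labels) > 1
        rows.append((hg, "ambiguous" if ambiguous else labels[0], ambiguous,
                     ",".join(sorted(set(entry["yeast"]))),
                     ",".join(labels), entry["conf"]))
    mapped = pd.DataFrame(rows, columns=["human_gene", "call", "ambiguous",
                                         "yeast_genes", "calls",
                                         "max_confidence"])
    return mapped, unmapped
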