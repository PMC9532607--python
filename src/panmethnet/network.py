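"""Cross-cohort concordance networks from per-cohort correlations.

A feature pair becomes an edge when its correlation is significant in at
least ``min_cohorts`` cohorts (the gene–protein networks use ≥ 5, the
protein–protein networks ≥ 20). Concordance is the degree of agreement of
the correlation sign across the significant cohorts only: total_positive or
total_negative when every significant cohort agrees, partial when both
signs occur. Non-significant cohorts never enter the tally.

Edges are undirected (unordered pairs, self-pairs excluded) and exported as
SIF / GraphML / TSV for Cytoscape-class tools.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("panmethnet")

EDGE_COLUMNS = (
    "feature_a", "feature_b", "n_significant", "n_positive", "n_negative",
    "concordance", "mean_r",
)


def classify_concordance(n_positive: int, n_negative: int) -> str:
    """total_positive / total_negative when one sign count is zero,
    partial otherwise; both-zero is an error."""
    if n_positive < 0 or n_negative < 0:
        raise ValueError("sign counts must be non-negative")
    if n_positive + n_negative == 0:
        raise ValueError("concordance undefined with no significant cohorts")
    if n_negative == 0:
        return "total_positive"
    if n_positive == 0:
        return "total_negative"
    return "partial"


def aggregate_edges(correlations: pd.DataFrame, min_cohorts: int) -> pd.DataFrame:
    """Collapse per-cohort significant correlations into concordance edges.

    Input must be a per-cohort correlation table (pooled rows are an
    error); output has one row per unordered pair with
    n_significant ≥ min_cohorts, ordered lexicographically.
    """
    if (correlations["cohort"] == "pooled").any():
        raise ValueError("aggregate_edges requires per-cohort correlations, "
                         "found pooled rows")
    sig = correlations[correlations["significant"]].copy()
    pairs = [
        tuple(sorted((a, b)))
        for a, b in zip(sig["feature_a"], sig["feature_b"])
    ]
    sig["_pair"] = pairs
    sig = sig[sig["feature_a"] != sig["feature_b"]]
    rows = []
    for (fa, fb), sub in sig.groupby("_pair", sort=True):
        # a pair measured in both orientations contributes each cohort once
        sub = sub.drop_duplicates(subset=["cohort"])
        n_pos = int((sub["r"] > 0).sum())
        n_neg = int((sub["r"] < 0).sum())
        n_sig = n_pos + n_neg
        if n_sig < min_cohorts:
            continue
        rows.append((fa, fb, n_sig, n_pos, n_neg,
                     classify_concordance(n_pos, n_neg),
                     float(sub["r"].mean())))
    return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))


def export_network(edges: pd.DataFrame, fmt: str, path: str | Path) -> None:
    """Write edges as SIF (interaction type = concordance class), GraphML
    (all fields as edge attributes), or TSV, with deterministic row order."""
    path = Path(path)
    ordered = edges.sort_values(
        ["feature_a", "feature_b"], kind="stable"
    ).reset_index(drop=True)
    if fmt == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for _, row in ordered.iterrows():
                fh.write(f"{row['feature_a']}\t{row['concordance']}\t"
                         f"{row['feature_b']}\n")
    elif fmt == "graphml":
        graph = nx.Graph()
        for _, row in ordered.iterrows():
            graph.add_edge(
                row["feature_a"], row["feature_b"],
                n_significant=int(row["n_significant"]),
                n_positive=int(row["n_positive"]),
                n_negative=int(row["n_negative"]),
                concordance=str(row["concordance"]),
                mean_r=float(row["mean_r"]),
            )
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        ordered.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def multi_degree_nodes(
    edges: pd.DataFrame, anchor_features: Sequence[str]
) -> pd.DataFrame:
    """Features connected to ≥ 2 anchors, with the anchors they touch.

    Mirrors the hub question "which proteins correlate with two, or with all
    three, genes of the network simultaneously".
    """
    anchors = list(dict.fromkeys(anchor_features))
    touched: dict[str, set[str]] = {}
    for _, row in edges.iterrows():
        a, b = row["feature_a"], row["feature_b"]
        if a in anchors and b not in anchors:
            touched.setdefault(b, set()).add(a)
        elif b in anchors and a not in anchors:
            touched.setdefault(a, set()).add(b)
    rows = [
        (fid, len(conn), ",".join(sorted(conn)))
        for fid, conn in sorted(touched.items())
        if len(conn) >= 2
    ]
    return pd.DataFrame(rows, columns=["feature_id", "anchor_degree", "anchors"])
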