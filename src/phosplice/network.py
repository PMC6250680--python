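"""Pathological PPI network construction and betweenness-based core ranking.

Starting from the genes implicated by the splicing/GO stages, the network is
built by keeping the genes present in the interaction database, expanding by
one step (every database neighbor of a selected gene plus all database edges
among the resulting node set), and ranking nodes by unnormalized shortest-path
betweenness centrality. Nodes in the top quartile of betweenness are flagged
as core genes; ties at the boundary are all included.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "map_and_filter_ids",
    "build_pathological_network",
    "betweenness_scores",
    "core_genes",
]


def map_and_filter_ids(genes, known_ids) -> list:
    """Keep only genes present in the interaction database, order preserved."""
    genes = list(genes)
    known = set(known_ids)
    kept = [g for g in genes if g in known]
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info("map_and_filter_ids: dropped %d/%d genes absent from the database", dropped, len(genes))
    return kept


def build_pathological_network(selected, db: nx.Graph) -> nx.Graph:
    """One-step expansion of the selected genes on the interaction database.

    The result contains the selected nodes, every database node adjacent to a
    selected node, and all database edges among that node set.
    """
    selected = list(selected)
    missing = [s for s in selected if s not in db]
    if missing:
        raise KeyError(f"selected genes absent from the database: {missing[:5]}")
    if not selected:
        logger.warning("build_pathological_network: empty selection, returning empty graph")
        return nx.Graph()
    nodes = set(selected)
    for s in selected:
        nodes.update(db.neighbors(s))
    return nx.Graph(db.subgraph(nodes))


def betweenness_scores(g: nx.Graph) -> pd.DataFrame:
    """Unnormalized shortest-path betweenness for every node.

    Each unordered node pair is counted once, endpoints excluded, with
    fractional credit when several shortest paths tie. Returns a DataFrame
    (node, betweenness, rank) sorted by descending betweenness, ties broken
    by node ID for deterministic reports.
    """
    bc = nx.betweenness_centrality(g, normalized=False)
    out = pd.DataFrame({"node": list(bc.keys()), "betweenness": list(bc.values())})
    out["node"] = out["node"].astype(str)
    out = out.sort_values(["betweenness", "node"], ascending=[False, True], kind="stable")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


def core_genes(scores: pd.DataFrame, top_fraction: float = 0.25) -> pd.DataFrame:
    """Flag the top quartile of betweenness scores as core genes.

    The ``ceil(top_fraction * n)`` highest-scoring nodes are core; nodes tied
    with the boundary score are all included.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    out = scores.copy()
    if len(out) == 0:
        out["is_core"] = pd.Series(dtype=bool)
        return out
    out = out.sort_values(["betweenness", "node"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )
    k = math.ceil(top_fraction * len(out))
    cutoff = out["betweenness"].iloc[k - 1]
    out["is_core"] = out["betweenness"] >= cutoff
    out["rank"] = range(1, len(out) + 1)
    return out
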