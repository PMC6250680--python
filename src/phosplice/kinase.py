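"""Kinase-downstream pathway enrichment on a PPI graph.

The downstream set of one or more seed kinases is taken as all proteins
within a fixed number of degrees of separation (shortest-path distance) on
the protein-protein interaction graph, seeds included. Enrichment of
phosphorylation changes inside that set is tested by Fisher's exact test on
the 2x2 table {inside downstream (seeds excluded), outside} x
{changed, unchanged}; proteins never detected by mass spectrometry are left
out of the table entirely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from .stats import fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "downstream_nodes", "downstream_enrichment"]

CHANGED = "changed"
UNCHANGED = "unchanged"
UNDETECTED = "undetected"
STATUSES = (CHANGED, UNCHANGED, UNDETECTED)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 phospho-change enrichment inside vs outside the downstream set."""

    n_changed_in: int
    n_detected_in: int
    n_changed_out: int
    n_detected_out: int
    odds_ratio: float
    p: float

    @property
    def table(self):
        return [
            [self.n_changed_in, self.n_detected_in - self.n_changed_in],
            [self.n_changed_out, self.n_detected_out - self.n_changed_out],
        ]


def downstream_nodes(g: nx.Graph, seeds, max_degree: int = 2) -> set:
    """Nodes within ``max_degree`` degrees of separation from any seed kinase."""
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    seeds = list(seeds)
    for s in seeds:
        if s not in g:
            raise KeyError(f"seed kinase {s!r} is not a node of the graph")
    out: set = set()
    for s in seeds:
        out.update(nx.single_source_shortest_path_length(g, s, cutoff=max_degree))
    return out


def downstream_enrichment(
    g: nx.Graph,
    seeds,
    status: dict,
    max_degree: int = 2,
    include_seeds: bool = False,
) -> EnrichmentResult:
    """Test whether phospho-changes concentrate in the kinase-downstream set.

    ``status`` maps protein IDs to "changed", "unchanged" or "undetected"
    (missing proteins count as undetected). Seeds are excluded from the table
    by default — they are the hypothesis, not evidence. An empty detected
    stratum yields a sentinel result with p = NaN.
    """
    seeds = list(seeds)
    inside = downstream_nodes(g, seeds, max_degree=max_degree)
    if not include_seeds:
        inside = inside - set(seeds)
    counts = {True: [0, 0], False: [0, 0]}  # stratum -> [changed, detected]
    for node in g.nodes:
        if not include_seeds and node in seeds:
            continue
        s = status.get(node, UNDETECTED)
        if s not in STATUSES:
            raise ValueError(f"unknown phospho status {s!r} for {node!r}")
        if s == UNDETECTED:
            continue
        stratum = counts[node in inside]
        stratum[1] += 1
        if s == CHANGED:
            stratum[0] += 1
    c_in, d_in = counts[True]
    c_out, d_out = counts[False]
    if d_in == 0 or d_out == 0:
        logger.warning(
            "downstream_enrichment: empty stratum (detected inside=%d, outside=%d)", d_in, d_out
        )
        return EnrichmentResult(c_in, d_in, c_out, d_out, math.nan, math.nan)
    res = fisher_exact_two_sided([[c_in, d_in - c_in], [c_out, d_out - c_out]])
    return EnrichmentResult(c_in, d_in, c_out, d_out, res.statistic, res.p_value)
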