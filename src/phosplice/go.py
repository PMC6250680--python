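"""GO-term enrichment and shared-gene clustering of enriched terms.

Enrichment of a selected gene list against a term->genes annotation table is
scored by the hypergeometric upper tail (probability of an overlap at least
as large as observed when drawing the selection from the universe at random),
with Benjamini-Hochberg q-values across all tested terms; terms are called
enriched at q < 0.01 by default. Enriched terms are then grouped by how many
annotated genes they share: Jaccard distance between their gene sets,
agglomerated with Ward linkage (Lance-Williams update on the precomputed
distance matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _sch
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "TermClustering",
    "enrich",
    "term_distance",
    "cluster_terms",
]


@dataclass
class AnnotationTable:
    """term ID -> set of annotated gene IDs, with an explicit gene universe."""

    term_to_genes: dict
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.term_to_genes = {t: set(g) for t, g in self.term_to_genes.items()}
        annotated = set().union(*self.term_to_genes.values()) if self.term_to_genes else set()
        if not self.universe:
            self.universe = annotated
        else:
            self.universe = set(self.universe)
            stray = annotated - self.universe
            if stray:
                raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")


def enrich(selected, ann: AnnotationTable, q_threshold: float = 0.01) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene selection.

    Returns one row per term: overlap k, term size K, selection size n,
    universe size N, fold enrichment (k/n)/(K/N), p (upper tail at >= k),
    q (BH across all terms) and the enriched flag.
    """
    selected = set(selected)
    stray = selected - ann.universe
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:5]}")
    n_sel = len(selected)
    n_uni = len(ann.universe)
    if n_sel == 0:
        logger.warning("enrich: empty gene selection, no terms tested")
    rows = []
    for term in sorted(ann.term_to_genes):
        genes = ann.term_to_genes[term]
        k = len(selected & genes)
        big_k = len(genes)
        fold = (k / n_sel) / (big_k / n_uni) if n_sel and big_k else np.nan
        p = float(hypergeom.sf(k - 1, n_uni, big_k, n_sel)) if n_sel else 1.0
        rows.append(
            {"term": term, "k": k, "K": big_k, "n": n_sel, "N": n_uni, "fold": fold, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "fold", "p"])
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out["enriched"] = out["q"] < q_threshold
    else:
        out["q"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out


def term_distance(genes_a, genes_b) -> float:
    """Jaccard distance 1 - |A∩B|/|A∪B| between two terms' gene sets."""
    a, b = set(genes_a), set(genes_b)
    if not a or not b:
        raise ValueError("term gene sets must be non-empty")
    return 1.0 - len(a & b) / len(a | b)


@dataclass
class TermClustering:
    """Ward merge tree over enriched terms.

    ``linkage`` is a scipy linkage matrix whose leaves correspond, in order,
    to ``terms``.
    """

    terms: list
    linkage: np.ndarray | None  # None for a singleton clustering

    def cut(self, n_clusters: int) -> dict:
        """Assign terms to ``n_clusters`` flat clusters (term -> cluster id)."""
        if self.linkage is None or len(self.terms) <= 1:
            return {t: 1 for t in self.terms}
        labels = _sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.terms, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Render the merge tree as a Newick string for inspection."""
        if self.linkage is None or len(self.terms) <= 1:
            inner = ",".join(str(t) for t in self.terms)
            return f"({inner});" if inner else "();"
        tree = _sch.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return f"{self.terms[node.id]}:{node.dist:.6g}"
            left = render(node.get_left())
            right = render(node.get_right())
            return f"({left},{right}):{node.dist:.6g}"

        return f"({render(tree.get_left())},{render(tree.get_right())});"


def cluster_terms(results: pd.DataFrame, ann: AnnotationTable) -> TermClustering:
    """Ward clustering of enriched terms by shared annotated genes.

    ``results`` is an :func:`enrich` output; only rows with ``enriched`` are
    clustered. Fewer than two enriched terms yield a singleton clustering.
    """
    terms = sorted(results.loc[results["enriched"].astype(bool), "term"])
    if len(terms) < 2:
        return TermClustering(terms=terms, linkage=None)
    n = len(terms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = term_distance(ann.term_to_genes[terms[i]], ann.term_to_genes[terms[j]])
            dist[i, j] = dist[j, i] = d
    z = _sch.linkage(squareform(dist, checks=False), method="ward")
    return TermClustering(terms=terms, linkage=z)
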