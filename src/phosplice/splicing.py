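"""Exon skipping analysis from junction read counts.

For each internal exon of a gene model two read classes are counted:
*inclusion reads*, which overlap the exon body by at least one base, and
*skipping reads*, which carry a splice junction joining the two exons
flanking that exon (both junction boundaries matched to the annotation).
Differential skipping between two groups is called from the 2x2 table of
(skipping, inclusion) counts by a two-sided Fisher exact test, with
Benjamini-Hochberg q-values across all testable exons; the effect size is the
log2 skipping/inclusion ratio of the case group adjusted to (divided by) the
control group's ratio.

Coordinates are 0-based half-open throughout. Replicates are summed within a
group before the contingency table is built. Exons with a zero in any cell
fail the positive-integer rule and are excluded from testing (and from the BH
family) rather than being assigned p = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "SplicedAlignment",
    "count_inclusion_skipping",
    "count_all_exons",
    "adjusted_log2_ratio",
    "test_exon",
    "analyze_counts",
    "call_significant",
    "rpkm",
    "overlap_significant",
    "recovery_analysis",
]

RESULT_COLUMNS = [
    "gene",
    "exon",
    "S_case",
    "I_case",
    "S_ctrl",
    "I_ctrl",
    "adjusted_log2",
    "p",
    "q",
    "tested",
    "significant",
]


@dataclass(frozen=True)
class GeneModel:
    """Ordered, non-overlapping exons of one gene (0-based half-open)."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str | None = None  # provenance only; counting ignores strand

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.gene_id}: exon with start >= end ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are out of order")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class SplicedAlignment:
    """One aligned read as ordered blocks; gaps between blocks are junctions."""

    read_id: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple((int(s), int(e)) for s, e in self.blocks))
        prev_end = None
        for start, end in self.blocks:
            if start >= end:
                raise ValueError(f"{self.read_id}: block with start >= end ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.read_id}: blocks overlap or are out of order")
            prev_end = end

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """(gap_start, gap_end) for each gap between consecutive blocks."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        )


def count_inclusion_skipping(
    model: GeneModel,
    alignments,
    exon_index: int,
    junction_tolerance: int = 0,
) -> tuple[int, int]:
    """Count inclusion and skipping reads for one internal exon.

    A read is an inclusion read when any block overlaps the exon by >= 1 bp;
    a skipping read when it carries a junction spanning from the end of exon
    ``i-1`` to the start of exon ``i+1``, each boundary matched within
    ``junction_tolerance`` bases (default exact). A read counts at most once
    per category.
    """
    if not (0 < exon_index < model.n_exons - 1):
        raise ValueError(
            f"exon_index {exon_index} is not internal for {model.gene_id} "
            f"({model.n_exons} exons); skipping needs flanking exons"
        )
    ex_start, ex_end = model.exons[exon_index]
    donor = model.exons[exon_index - 1][1]  # end of upstream neighbor
    acceptor = model.exons[exon_index + 1][0]  # start of downstream neighbor
    inclusion = 0
    skipping = 0
    for aln in alignments:
        if any(bs < ex_end and be > ex_start for bs, be in aln.blocks):
            inclusion += 1
        if any(
            abs(js - donor) <= junction_tolerance and abs(je - acceptor) <= junction_tolerance
            for js, je in aln.junctions
        ):
            skipping += 1
    return inclusion, skipping


def count_all_exons(
    model: GeneModel,
    alignments,
    junction_tolerance: int = 0,
) -> pd.DataFrame:
    """Inclusion/skipping counts for every internal exon of one gene."""
    rows = []
    for i in range(1, model.n_exons - 1):
        inc, skp = count_inclusion_skipping(model, alignments, i, junction_tolerance)
        rows.append({"gene": model.gene_id, "exon": i, "inclusion": inc, "skipping": skp})
    return pd.DataFrame(rows, columns=["gene", "exon", "inclusion", "skipping"])


def adjusted_log2_ratio(s_case: int, i_case: int, s_ctrl: int, i_ctrl: int) -> float:
    """log2 of the case skipping/inclusion ratio adjusted to the control ratio.

    Returns NaN (exon not computable) when any count is zero.
    """
    for v in (s_case, i_case, s_ctrl, i_ctrl):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if min(s_case, i_case, s_ctrl, i_ctrl) == 0:
        return math.nan
    return math.log2((s_case / i_case) / (s_ctrl / i_ctrl))


def test_exon(s_case: int, i_case: int, s_ctrl: int, i_ctrl: int) -> dict:
    """Fisher test of one exon's 2x2 skipping/inclusion table.

    Applies the positive-integer rule: if any cell is < 1 the exon is not
    testable (``tested=False``, no p-value).
    """
    for v in (s_case, i_case, s_ctrl, i_ctrl):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if min(s_case, i_case, s_ctrl, i_ctrl) < 1:
        return {"tested": False, "p": math.nan, "adjusted_log2": math.nan}
    res = fisher_exact_two_sided([[s_case, i_case], [s_ctrl, i_ctrl]])
    return {
        "tested": True,
        "p": res.p_value,
        "adjusted_log2": adjusted_log2_ratio(s_case, i_case, s_ctrl, i_ctrl),
    }


def analyze_counts(
    counts: pd.DataFrame,
    case_group: str,
    control_group: str,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential exon skipping between two groups of an ExonCounts table.

    ``counts`` has columns gene, exon, group, replicate, inclusion, skipping.
    Replicates are summed within each group before the 2x2 table is built.
    Returns one row per (gene, exon) with counts, adjusted log2 ratio, p, q,
    tested and significant flags.
    """
    required = {"gene", "exon", "group", "inclusion", "skipping"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns: {sorted(missing)}")
    pooled = (
        counts[counts["group"].isin([case_group, control_group])]
        .groupby(["gene", "exon", "group"], sort=True)[["inclusion", "skipping"]]
        .sum()
        .unstack("group")
    )
    rows = []
    for (gene, exon), r in pooled.iterrows():
        i_case = int(r.get(("inclusion", case_group), 0) or 0)
        s_case = int(r.get(("skipping", case_group), 0) or 0)
        i_ctrl = int(r.get(("inclusion", control_group), 0) or 0)
        s_ctrl = int(r.get(("skipping", control_group), 0) or 0)
        t = test_exon(s_case, i_case, s_ctrl, i_ctrl)
        rows.append(
            {
                "gene": gene,
                "exon": exon,
                "S_case": s_case,
                "I_case": i_case,
                "S_ctrl": s_ctrl,
                "I_ctrl": i_ctrl,
                "adjusted_log2": t["adjusted_log2"],
                "p": t["p"],
                "tested": t["tested"],
            }
        )
    out = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c not in ("q", "significant")])
    n_untested = int((~out["tested"]).sum()) if len(out) else 0
    if n_untested:
        logger.info(
            "analyze_counts: %d/%d exons fail the positive-integer rule and are untested",
            n_untested,
            len(out),
        )
    return call_significant(out, q_threshold=q_threshold)


def call_significant(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """BH-adjust p-values across tested exons and flag q < threshold.

    Untested exons (positive-integer rule failures) are excluded from the BH
    family and get q = NaN, significant = False.
    """
    out = results.copy()
    out["q"] = math.nan
    out["significant"] = False
    tested = out["tested"].to_numpy(dtype=bool)
    if tested.any():
        q = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
        out.loc[tested, "q"] = q
        out.loc[tested, "significant"] = q < q_threshold
    return out.reset_index(drop=True)


def rpkm(read_count: int, feature_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_bp <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return read_count / (feature_length_bp / 1e3) / (library_size / 1e6)


def _significant_set(results: pd.DataFrame) -> set[tuple]:
    sig = results[results["significant"].astype(bool)]
    return set(zip(sig["gene"], sig["exon"]))


def overlap_significant(results_a: pd.DataFrame, results_b: pd.DataFrame):
    """Exons significant in both comparisons, and their distinct gene count."""
    shared = sorted(_significant_set(results_a) & _significant_set(results_b))
    n_genes = len({g for g, _ in shared})
    return shared, n_genes


def recovery_analysis(
    disease_vs_ctrl: pd.DataFrame,
    treated_vs_ctrl: pd.DataFrame,
    shared,
):
    """Fraction of shared exons rescued by treatment.

    An exon is *recovered* when it is significant in the disease-vs-control
    comparison but no longer significant (q >= threshold, or untestable) in
    the treated-vs-control comparison. Returns (recovered exon list,
    fraction); the fraction is NaN for an empty shared set.
    """
    shared = list(shared)
    if not shared:
        return [], math.nan
    disease_sig = _significant_set(disease_vs_ctrl)
    treated_sig = _significant_set(treated_vs_ctrl)
    known = set(zip(disease_vs_ctrl["gene"], disease_vs_ctrl["exon"])) & set(
        zip(treated_vs_ctrl["gene"], treated_vs_ctrl["exon"])
    )
    unknown = [e for e in shared if tuple(e) not in known]
    if unknown:
        raise ValueError(f"shared exons absent from a result set: {unknown[:5]}")
    recovered = [e for e in shared if tuple(e) in disease_sig and tuple(e) not in treated_sig]
    return recovered, len(recovered) / len(shared)
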