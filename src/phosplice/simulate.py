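"""Synthetic-data generators with planted ground truth for every stage.

Each simulator is a pure function of its config (including the seed): rerun
with the same config it reproduces its output bit for bit. The models are
deliberately the simplest ones consistent with the analysis assumptions:

* reporter intensities are log-normal around a channel-bias times
  base-intensity mean, with planted log2 fold changes on chosen sites;
* junction counts are Poisson around ``depth * psi`` (inclusion) and
  ``depth * (1 - psi)`` (skipping), with planted inclusion-level changes in
  the case group;
* interaction graphs are Erdos-Renyi, with phospho-change probabilities that
  differ inside vs outside the seeded kinase neighborhood;
* term annotations are random gene subsets.

Stage-level substreams are derived from one global seed with
:func:`derive_seed` so each stage can be rerun independently.
"""

from __future__ import annotations

import zlib
from collections import namedtuple
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .go import AnnotationTable
from .kinase import downstream_nodes
from .phospho import META_COLUMNS, ReporterMatrix
from .splicing import GeneModel, SplicedAlignment

__all__ = [
    "derive_seed",
    "PhosphoSimConfig",
    "SplicingSimConfig",
    "NetworkSimConfig",
    "AnnotationSimConfig",
    "simulate_phospho",
    "simulate_splicing_counts",
    "simulate_spliced_reads",
    "simulate_ppi",
    "simulate_annotations",
    "PPISim",
    "ReadSim",
]


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage substream seed from one global seed."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# phosphoproteome


@dataclass
class PhosphoSimConfig:
    """Log-normal reporter-ion simulator configuration.

    Each protein carries one phosphorylation site covered by
    ``peptides_per_protein`` peptides of ``fragments_per_peptide`` MS/MS
    fragments. ``spiked_sites`` lists (protein, site, delta) with delta the
    planted log2 case/control fold change; all other sites have delta = 0.
    """

    n_proteins: int = 1000
    peptides_per_protein: int = 2
    fragments_per_peptide: int = 3
    n_channels_case: int = 3
    n_channels_control: int = 3
    channel_bias: tuple = ()  # empty -> all ones
    base_intensity: float = 1e4
    log_noise_sd: float = 0.1
    spiked_sites: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.peptides_per_protein < 1 or self.fragments_per_peptide < 1:
            raise ValueError("counts must be >= 1")
        if self.n_channels_case < 1 or self.n_channels_control < 1:
            raise ValueError("need at least one channel per group")
        n_ch = self.n_channels_case + self.n_channels_control
        if self.channel_bias and len(self.channel_bias) != n_ch:
            raise ValueError(f"channel_bias must have length {n_ch}")
        if self.channel_bias and any(b <= 0 for b in self.channel_bias):
            raise ValueError("channel biases must be positive")
        if self.log_noise_sd <= 0:
            raise ValueError("log_noise_sd must be positive")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")


def protein_name(i: int) -> str:
    return f"P{i:04d}"


def simulate_phospho(cfg: PhosphoSimConfig) -> ReporterMatrix:
    """Simulate a fragment-level reporter matrix with planted fold changes."""
    rng = np.random.default_rng(cfg.seed)
    case_ch = [f"case{i + 1}" for i in range(cfg.n_channels_case)]
    ctrl_ch = [f"control{i + 1}" for i in range(cfg.n_channels_control)]
    channels = case_ch + ctrl_ch
    bias = np.asarray(cfg.channel_bias if cfg.channel_bias else [1.0] * len(channels))
    is_case = np.array([1.0] * len(case_ch) + [0.0] * len(ctrl_ch))

    delta = {}
    for protein, site, d in cfg.spiked_sites:
        delta[(protein, site)] = float(d)

    rows = []
    for ip in range(cfg.n_proteins):
        protein = protein_name(ip)
        site = "S1"
        d = delta.get((protein, site), 0.0)
        mean = bias * cfg.base_intensity * 2.0 ** (d * is_case)
        for jp in range(cfg.peptides_per_protein):
            for kf in range(cfg.fragments_per_peptide):
                noise = rng.normal(0.0, cfg.log_noise_sd, size=len(channels))
                inten = mean * np.exp(noise)
                rows.append(
                    [f"{protein}_pep{jp}", kf, protein, site, 0.99, True, False, *inten]
                )
    data = pd.DataFrame(rows, columns=META_COLUMNS + channels)
    groups = {c: "case" for c in case_ch} | {c: "control" for c in ctrl_ch}
    return ReporterMatrix(data=data, channels=channels, groups=groups)


# ---------------------------------------------------------------------------
# splicing


@dataclass
class SplicingSimConfig:
    """Poisson junction-count simulator configuration.

    ``psi`` is the baseline inclusion level: per exon and replicate,
    inclusion reads are Poisson(depth * psi) and skipping reads
    Poisson(depth * (1 - psi)). ``spiked_exons`` lists (gene, exon,
    psi_case) inclusion levels used in the case group only.
    """

    n_genes: int = 250
    exons_per_gene: int = 8
    depth: float = 100.0
    psi: float = 0.8
    spiked_exons: tuple = ()
    replicates_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.psi < 1:
            raise ValueError("psi must lie strictly in (0, 1)")
        for gene, exon, psi_case in self.spiked_exons:
            if not 0 < psi_case < 1:
                raise ValueError(f"psi_case for ({gene}, {exon}) must lie strictly in (0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_genes < 1 or self.exons_per_gene < 1 or self.replicates_per_group < 1:
            raise ValueError("sizes must be >= 1")


def gene_name(i: int) -> str:
    return f"G{i:04d}"


def simulate_splicing_counts(
    cfg: SplicingSimConfig,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-exon inclusion/skipping counts for a case and a control group.

    Returns an ExonCounts table (gene, exon, group, replicate, inclusion,
    skipping) with ``replicates_per_group`` replicates per group.
    """
    rng = np.random.default_rng(cfg.seed)
    spiked = {(g, e): float(pc) for g, e, pc in cfg.spiked_exons}
    rows = []
    for ig in range(cfg.n_genes):
        gene = gene_name(ig)
        for exon in range(cfg.exons_per_gene):
            psi_case = spiked.get((gene, exon), cfg.psi)
            for group, psi in ((case_label, psi_case), (control_label, cfg.psi)):
                for rep in range(cfg.replicates_per_group):
                    inc = int(rng.poisson(cfg.depth * psi))
                    skp = int(rng.poisson(cfg.depth * (1.0 - psi)))
                    rows.append([gene, exon, group, rep, inc, skp])
    return pd.DataFrame(
        rows, columns=["gene", "exon", "group", "replicate", "inclusion", "skipping"]
    )


ReadSim = namedtuple("ReadSim", ["models", "alignments", "truth"])

_EXON_LEN = 100
_INTRON_LEN = 100
_GENE_SPACING = 100_000
_READ_LEN = 50
_ANCHOR = 30


def simulate_spliced_reads(cfg: SplicingSimConfig) -> ReadSim:
    """Simulate gene models plus spliced alignments exercising read counting.

    Every exon receives inclusion reads (one block inside the exon body);
    every internal exon additionally receives skipping reads whose single
    junction joins the annotated end of the upstream neighbor to the
    annotated start of the downstream neighbor. ``truth`` holds the exact
    per-internal-exon counts the counting stage must reproduce, including
    the inclusion credit skipping reads give to the flanking exons they
    touch.
    """
    if cfg.exons_per_gene < 3:
        raise ValueError("need exons_per_gene >= 3 so internal exons have flanks")
    rng = np.random.default_rng(cfg.seed)
    spiked = {(g, e): float(pc) for g, e, pc in cfg.spiked_exons}

    models: dict[str, GeneModel] = {}
    alignments: list[SplicedAlignment] = []
    truth_rows = []
    for ig in range(cfg.n_genes):
        gene = gene_name(ig)
        origin = ig * _GENE_SPACING
        exons = tuple(
            (origin + i * (_EXON_LEN + _INTRON_LEN), origin + i * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN)
            for i in range(cfg.exons_per_gene)
        )
        models[gene] = GeneModel(gene_id=gene, exons=exons)

        n_inc = np.zeros(cfg.exons_per_gene, dtype=int)
        n_skip = np.zeros(cfg.exons_per_gene, dtype=int)
        for i in range(cfg.exons_per_gene):
            psi = spiked.get((gene, i), cfg.psi)
            n_inc[i] = rng.poisson(cfg.depth * psi)
            if 0 < i < cfg.exons_per_gene - 1:
                n_skip[i] = rng.poisson(cfg.depth * (1.0 - psi))

        for i in range(cfg.exons_per_gene):
            start, end = exons[i]
            for r in range(n_inc[i]):
                alignments.append(
                    SplicedAlignment(f"{gene}_e{i}_inc{r}", ((start, start + _READ_LEN),))
                )
            if 0 < i < cfg.exons_per_gene - 1:
                donor = exons[i - 1][1]
                acceptor = exons[i + 1][0]
                for r in range(n_skip[i]):
                    alignments.append(
                        SplicedAlignment(
                            f"{gene}_e{i}_skip{r}",
                            ((donor - _ANCHOR, donor), (acceptor, acceptor + _ANCHOR)),
                        )
                    )

        for i in range(1, cfg.exons_per_gene - 1):
            inc_total = int(n_inc[i])
            # skipping reads for neighboring internal exons overlap this exon body
            if i - 1 >= 1:
                inc_total += int(n_skip[i - 1])
            if i + 1 <= cfg.exons_per_gene - 2:
                inc_total += int(n_skip[i + 1])
            truth_rows.append(
                {"gene": gene, "exon": i, "inclusion": inc_total, "skipping": int(n_skip[i])}
            )
    truth = pd.DataFrame(truth_rows, columns=["gene", "exon", "inclusion", "skipping"])
    return ReadSim(models=models, alignments=alignments, truth=truth)


# ---------------------------------------------------------------------------
# PPI graph


@dataclass
class NetworkSimConfig:
    """Erdos-Renyi PPI simulator with a planted kinase-downstream effect."""

    n_nodes: int = 250
    edge_prob: float = 0.016
    seed_kinases: tuple = ("P0000", "P0001")
    max_degree_sep: int = 2
    p_changed_in: float = 0.8
    p_changed_out: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0 < self.edge_prob < 1:
            raise ValueError("edge_prob must lie in (0, 1)")
        if not 0 <= self.p_changed_in <= 1 or not 0 <= self.p_changed_out <= 1:
            raise ValueError("change probabilities must lie in [0, 1]")
        if self.max_degree_sep < 1:
            raise ValueError("max_degree_sep must be >= 1")


PPISim = namedtuple("PPISim", ["graph", "status", "downstream"])


def simulate_ppi(cfg: NetworkSimConfig) -> PPISim:
    """Random PPI graph with phospho-change labels planted around the seeds.

    Nodes within ``max_degree_sep`` of a seed kinase are labelled changed
    with probability ``p_changed_in``, all others with ``p_changed_out``.
    Returns the graph, the status map, and the planted downstream node set.
    """
    rng = np.random.default_rng(cfg.seed)
    graph_seed = int(rng.integers(0, 2**31))
    g = nx.fast_gnp_random_graph(cfg.n_nodes, cfg.edge_prob, seed=graph_seed)
    g = nx.relabel_nodes(g, {i: protein_name(i) for i in g.nodes})
    missing = [s for s in cfg.seed_kinases if s not in g]
    if missing:
        raise ValueError(f"seed kinases absent from the simulated graph: {missing}")
    inside = downstream_nodes(g, cfg.seed_kinases, max_degree=cfg.max_degree_sep)
    status = {}
    for node in sorted(g.nodes):
        p = cfg.p_changed_in if node in inside else cfg.p_changed_out
        status[node] = "changed" if rng.random() < p else "unchanged"
    return PPISim(graph=g, status=status, downstream=inside)


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSimConfig:
    """Random term->genes annotation simulator."""

    n_genes: int = 500
    n_terms: int = 100
    genes_per_term_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1 or self.n_genes < 1:
            raise ValueError("sizes must be >= 1")
        if self.genes_per_term_mean <= 0:
            raise ValueError("genes_per_term_mean must be positive")


def simulate_annotations(cfg: AnnotationSimConfig) -> AnnotationTable:
    """Annotate each term with a random gene subset of Poisson-mean size."""
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([gene_name(i) for i in range(cfg.n_genes)])
    term_to_genes = {}
    for it in range(cfg.n_terms):
        size = int(np.clip(rng.poisson(cfg.genes_per_term_mean), 1, cfg.n_genes))
        chosen = rng.choice(genes, size=size, replace=False)
        term_to_genes[f"T{it:04d}"] = set(chosen.tolist())
    return AnnotationTable(term_to_genes=term_to_genes, universe=set(genes.tolist()))
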