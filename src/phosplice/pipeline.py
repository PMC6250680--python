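"""End-to-end demo pipeline tying all stages together on simulated data.

The scenario mirrors the study design the package implements: a
phosphoproteome comparison with planted fold changes, a kinase-downstream
enrichment on a random PPI graph, exon-skipping comparisons for two disease
models against a common background, the overlap of their significant exons,
a treated group in which a fixed fraction of the shared exons is reverted to
the background inclusion level (rescue), GO enrichment of the splicing-hit
genes, and betweenness ranking of the one-step-expanded PPI network around
those genes.

All randomness derives from one global seed via labelled substreams, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import go as go_mod
from . import io as io_mod
from . import kinase as kinase_mod
from . import network as network_mod
from . import splicing as splicing_mod
from .phospho import site_differential_test
from .simulate import (
    AnnotationSimConfig,
    NetworkSimConfig,
    PhosphoSimConfig,
    SplicingSimConfig,
    derive_seed,
    gene_name,
    protein_name,
    simulate_annotations,
    simulate_phospho,
    simulate_ppi,
    simulate_splicing_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds, simulated-data sizes and stage toggles for the demo run."""

    seed: int = 0

    # analysis thresholds
    q_splicing: float = 0.05
    q_go: float = 0.01
    alpha: float = 0.05
    confidence: float = 0.95
    top_fraction: float = 0.25
    max_degree: int = 2

    # phosphoproteome scenario
    n_sites: int = 1000
    n_spiked_sites: int = 50
    delta_log2: float = 2.0
    phospho_noise_sd: float = 0.1
    n_replicates_phospho: int = 3

    # splicing scenario
    n_genes: int = 250
    exons_per_gene: int = 8
    depth: float = 100.0
    psi: float = 0.8
    psi_case: float = 0.2
    n_spiked_exons: int = 50
    replicates_per_group: int = 3
    revert_fraction: float = 0.4
    spiked_exon_index: int = 3

    # kinase / network scenario
    n_ppi_nodes: int = 250
    ppi_edge_prob: float = 0.016
    p_changed_in: float = 0.8
    p_changed_out: float = 0.1

    # GO scenario
    n_terms: int = 100
    genes_per_term_mean: float = 20.0
    n_planted_terms: int = 3

    # stage toggles
    run_phospho: bool = True
    run_kinase: bool = True
    run_splicing: bool = True
    run_go: bool = True
    run_network: bool = True

    def __post_init__(self) -> None:
        for name in ("q_splicing", "q_go", "alpha", "confidence", "top_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.revert_fraction <= 1:
            raise ValueError("revert_fraction must lie in [0, 1]")
        if not 0 < self.spiked_exon_index < self.exons_per_gene - 1:
            raise ValueError("spiked_exon_index must be an internal exon")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _package_version() -> str:
    try:
        return _pkg_version("phosplice")
    except PackageNotFoundError:  # pragma: no cover - running from a source tree
        return "unknown"


def balanced_spikes(n: int, delta: float) -> tuple:
    """Planted phospho fold changes, half up and half down.

    Balanced signs keep the differential signal mass compositionally neutral,
    matching the equal-total-signal assumption behind channel bias correction
    (and real phosphoproteomes, where both increases and decreases occur).
    """
    return tuple(
        (protein_name(i), "S1", delta if i % 2 == 0 else -delta) for i in range(n)
    )


def _phospho_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    spiked = balanced_spikes(cfg.n_spiked_sites, cfg.delta_log2)
    n_ch = 2 * cfg.n_replicates_phospho
    bias = tuple(1.0 + 0.2 * ((-1) ** i) * (1 + i % 3) / 3 for i in range(n_ch))
    sim_cfg = PhosphoSimConfig(
        n_proteins=cfg.n_sites,
        n_channels_case=cfg.n_replicates_phospho,
        n_channels_control=cfg.n_replicates_phospho,
        channel_bias=bias,
        log_noise_sd=cfg.phospho_noise_sd,
        spiked_sites=spiked,
        seed=derive_seed(cfg.seed, "phospho"),
    )
    matrix = simulate_phospho(sim_cfg)
    results = site_differential_test(matrix, alpha=cfg.alpha, min_confidence=cfg.confidence)
    io_mod.write_table(results, outdir / "phospho_sites.tsv")

    planted = {(p, s): d for p, s, d in spiked}
    keys = list(zip(results["protein"], results["site"]))
    is_spiked = pd.Series([k in planted for k in keys], index=results.index)
    sign = pd.Series([np.sign(planted.get(k, 1.0)) for k in keys], index=results.index)
    recall = float(results.loc[is_spiked, "significant"].mean()) if is_spiked.any() else float("nan")
    null_rate = (
        float(results.loc[~is_spiked, "significant"].mean()) if (~is_spiked).any() else float("nan")
    )
    # signed error vs the planted effect, averaged over spiked sites
    bias_est = float(
        (results.loc[is_spiked, "log2_ratio"] * sign[is_spiked] - cfg.delta_log2).mean()
    )
    changed = sorted(results.loc[results["significant"], "protein"].unique())
    return {
        "n_sites": int(len(results)),
        "n_significant": int(results["significant"].sum()),
        "spiked_recall": recall,
        "null_significant_rate": null_rate,
        "spiked_log2_bias": bias_est,
        "changed_proteins": changed,
    }


def _kinase_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    sim_cfg = NetworkSimConfig(
        n_nodes=cfg.n_ppi_nodes,
        edge_prob=cfg.ppi_edge_prob,
        max_degree_sep=cfg.max_degree,
        p_changed_in=cfg.p_changed_in,
        p_changed_out=cfg.p_changed_out,
        seed=derive_seed(cfg.seed, "kinase"),
    )
    sim = simulate_ppi(sim_cfg)
    res = kinase_mod.downstream_enrichment(
        sim.graph, sim_cfg.seed_kinases, sim.status, max_degree=cfg.max_degree
    )
    row = pd.DataFrame(
        [
            {
                "n_changed_in": res.n_changed_in,
                "n_detected_in": res.n_detected_in,
                "n_changed_out": res.n_changed_out,
                "n_detected_out": res.n_detected_out,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
            }
        ]
    )
    io_mod.write_table(row, outdir / "kinase_enrichment.tsv")
    io_mod.write_graph(sim.graph, outdir / "kinase_ppi.sif")
    return {
        "downstream_size": len(sim.downstream),
        "odds_ratio": float(res.odds_ratio),
        "p": float(res.p),
    }


def _splicing_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    spiked = tuple(
        (gene_name(i), cfg.spiked_exon_index, cfg.psi_case) for i in range(cfg.n_spiked_exons)
    )
    n_revert = int(round(cfg.revert_fraction * len(spiked)))
    treated_spiked = spiked[n_revert:]  # first n_revert exons rescued to baseline

    results = {}
    for label, spiked_list in (
        ("model_a", spiked),
        ("model_b", spiked),
        ("treated", treated_spiked),
    ):
        sim_cfg = SplicingSimConfig(
            n_genes=cfg.n_genes,
            exons_per_gene=cfg.exons_per_gene,
            depth=cfg.depth,
            psi=cfg.psi,
            spiked_exons=spiked_list,
            replicates_per_group=cfg.replicates_per_group,
            seed=derive_seed(cfg.seed, f"splicing_{label}"),
        )
        counts = simulate_splicing_counts(sim_cfg)
        res = splicing_mod.analyze_counts(counts, "case", "control", q_threshold=cfg.q_splicing)
        io_mod.write_table(res, outdir / f"splicing_{label}.tsv")
        results[label] = res

    shared, n_shared_genes = splicing_mod.overlap_significant(
        results["model_a"], results["model_b"]
    )
    io_mod.write_table(
        pd.DataFrame(shared, columns=["gene", "exon"]), outdir / "shared_exons.tsv"
    )
    recovered, fraction = splicing_mod.recovery_analysis(
        results["model_b"], results["treated"], shared
    )
    io_mod.write_table(
        pd.DataFrame(recovered, columns=["gene", "exon"]), outdir / "recovered_exons.tsv"
    )

    sig_a = results["model_a"].loc[results["model_a"]["significant"]]
    spiked_set = {(g, e) for g, e, _ in spiked}
    called_a = set(zip(sig_a["gene"], sig_a["exon"]))
    return {
        "n_shared_exons": len(shared),
        "n_shared_genes": n_shared_genes,
        "n_recovered": len(recovered),
        "recovered_fraction": float(fraction),
        "power_model_a": len(called_a & spiked_set) / len(spiked_set) if spiked_set else float("nan"),
        "selected_genes": sorted({g for g, _ in called_a}),
    }


def _go_stage(cfg: PipelineConfig, outdir: Path, selected_genes: list) -> dict:
    ann_cfg = AnnotationSimConfig(
        n_genes=cfg.n_genes,
        n_terms=cfg.n_terms,
        genes_per_term_mean=cfg.genes_per_term_mean,
        seed=derive_seed(cfg.seed, "annotations"),
    )
    ann = simulate_annotations(ann_cfg)
    # plant terms concentrated on the selected genes so the term-grouping
    # stage has structure to find
    rng = np.random.default_rng(derive_seed(cfg.seed, "go_planted"))
    universe = sorted(ann.universe)
    selected = [g for g in selected_genes if g in ann.universe]
    for i in range(cfg.n_planted_terms):
        n_hit = min(12, len(selected))
        hits = rng.choice(selected, size=n_hit, replace=False) if n_hit else []
        fillers = rng.choice(universe, size=5, replace=False)
        ann.term_to_genes[f"PLANTED{i}"] = set(hits) | set(fillers)
    io_mod.write_annotations(ann, outdir / "annotations.tsv")

    res = go_mod.enrich(set(selected), ann, q_threshold=cfg.q_go)
    io_mod.write_table(res, outdir / "go_enrichment.tsv")
    clustering = go_mod.cluster_terms(res, ann)
    (outdir / "go_terms.nwk").write_text(clustering.to_newick() + "\n")
    return {
        "n_terms_tested": int(len(res)),
        "n_enriched": int(res["enriched"].sum()),
        "enriched_terms": sorted(res.loc[res["enriched"], "term"]),
    }


def _network_stage(cfg: PipelineConfig, outdir: Path, selected_genes: list) -> dict:
    rng = np.random.default_rng(derive_seed(cfg.seed, "network_db"))
    db_seed = int(rng.integers(0, 2**31))
    db = nx.fast_gnp_random_graph(cfg.n_genes, cfg.ppi_edge_prob, seed=db_seed)
    db = nx.relabel_nodes(db, {i: gene_name(i) for i in db.nodes})
    # a hub wired to every selected gene: the expected top-betweenness node
    hub = "HUB0001"
    db.add_node(hub)
    for g in selected_genes:
        if g in db:
            db.add_edge(hub, g)

    kept = network_mod.map_and_filter_ids(selected_genes, set(db.nodes))
    graph = network_mod.build_pathological_network(kept, db)
    scores = network_mod.betweenness_scores(graph)
    scores = network_mod.core_genes(scores, top_fraction=cfg.top_fraction)
    io_mod.write_table(scores, outdir / "network_scores.tsv")
    io_mod.write_graph(graph, outdir / "pathological_network.sif")

    hub_rank = int(scores.loc[scores["node"] == hub, "rank"].iloc[0]) if hub in set(scores["node"]) else -1
    return {
        "n_selected": len(kept),
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_core": int(scores["is_core"].sum()),
        "hub_rank": hub_rank,
    }


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the enabled stages in dependency order and write all artifacts.

    Returns the summary dictionary (also written as ``summary.json``); the
    run manifest (``manifest.json``) records the package version, the config
    and a SHA-256 digest of every output file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    if cfg.run_phospho:
        summary["phospho"] = _phospho_stage(cfg, outdir)
    if cfg.run_kinase:
        summary["kinase"] = _kinase_stage(cfg, outdir)
    selected_genes: list = []
    if cfg.run_splicing:
        summary["splicing"] = _splicing_stage(cfg, outdir)
        selected_genes = summary["splicing"].pop("selected_genes")
    if cfg.run_go:
        summary["go"] = _go_stage(cfg, outdir, selected_genes)
    if cfg.run_network:
        summary["network"] = _network_stage(cfg, outdir, selected_genes)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    outputs = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "phosplice",
        "version": _package_version(),
        "config": asdict(cfg),
        "stages": [k for k in ("phospho", "kinase", "splicing", "go", "network") if k in summary],
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
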