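"""Readers and writers for the pipeline's TSV dialects, SIF/edge-list graphs,
gene models, spliced alignments and annotation tables.

TSV is the canonical dialect: UTF-8, tab-separated, '.' decimal, mandatory
header (except graph edge lists). All writers round-trip losslessly through
the corresponding reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .go import AnnotationTable
from .phospho import META_COLUMNS, ReporterMatrix
from .splicing import GeneModel, SplicedAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_phospho_table",
    "write_phospho_table",
    "read_counts_table",
    "write_counts_table",
    "read_gene_models",
    "write_gene_models",
    "read_alignments",
    "write_alignments",
    "bed12_to_alignments",
    "read_graph",
    "write_graph",
    "read_annotations",
    "write_annotations",
    "write_table",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _infer_group(channel: str) -> str | None:
    low = channel.lower()
    if low.startswith("case"):
        return "case"
    if low.startswith("control") or low.startswith("ctrl"):
        return "control"
    return None


def read_phospho_table(path, groups: dict | None = None) -> ReporterMatrix:
    """Read a fragment-level reporter TSV.

    Columns: the metadata columns of :data:`phosplice.phospho.META_COLUMNS`
    followed by one intensity column per channel. Channel groups are taken
    from ``groups`` or inferred from channel names prefixed ``case``/
    ``control``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        logger.warning("read_phospho_table: %s is empty", path)
        return ReporterMatrix(
            data=pd.DataFrame(columns=META_COLUMNS), channels=[], groups={}
        )
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    channels = [c for c in df.columns if c not in META_COLUMNS]
    if groups is None:
        groups = {}
        for c in channels:
            g = _infer_group(c)
            if g is None:
                raise ParseError(
                    f"{path}: cannot infer group for channel {c!r}; pass groups= explicitly"
                )
            groups[c] = g
    for c in channels:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0)]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise ParseError(f"{path}: non-numeric or negative intensity at line {bad[0] + 2}")
        df[c] = vals
    df["has_itraq_label"] = df["has_itraq_label"].astype(bool)
    df["shared_spectrum"] = df["shared_spectrum"].astype(bool)
    return ReporterMatrix(data=df, channels=channels, groups=groups)


def write_phospho_table(m: ReporterMatrix, path) -> None:
    m.data[META_COLUMNS + m.channels].to_csv(path, sep="\t", index=False)


def read_counts_table(path) -> pd.DataFrame:
    """Read an ExonCounts TSV (gene, exon, group, replicate, inclusion, skipping)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "exon", "group", "replicate", "inclusion", "skipping"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for c in ("exon", "replicate", "inclusion", "skipping"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals != np.floor(vals.fillna(-1)))]
        if len(bad):
            raise ParseError(f"{path}: column {c!r} not a non-negative integer at line {bad[0] + 2}")
        df[c] = vals.astype(int)
    return df[required]


def write_counts_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> dict[str, GeneModel]:
    """Read gene models from a TSV (gene, exon_index, start, end[, strand])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "exon_index", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    models: dict[str, GeneModel] = {}
    for gene, sub in df.groupby("gene", sort=True):
        sub = sub.sort_values("exon_index")
        strand = None
        if "strand" in sub.columns and sub["strand"].notna().any():
            strand = str(sub["strand"].iloc[0])
        exons = tuple((int(s), int(e)) for s, e in zip(sub["start"], sub["end"]))
        models[str(gene)] = GeneModel(gene_id=str(gene), exons=exons, strand=strand)
    return models


def write_gene_models(models: dict[str, GeneModel], path) -> None:
    rows = []
    for gene in sorted(models):
        m = models[gene]
        for i, (s, e) in enumerate(m.exons):
            rows.append({"gene": gene, "exon_index": i, "start": s, "end": e, "strand": m.strand or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignments(path) -> list[SplicedAlignment]:
    """Read spliced alignments from a TSV (read_id, blocks).

    ``blocks`` is a comma-separated list of ``start-end`` half-open intervals,
    e.g. ``50-100,400-450``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("read_id", "blocks") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            blocks = tuple(
                (int(part.split("-")[0]), int(part.split("-")[1]))
                for part in str(row["blocks"]).split(",")
            )
            out.append(SplicedAlignment(read_id=str(row["read_id"]), blocks=blocks))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed blocks at line {idx + 2}: {exc}") from exc
    return out


def write_alignments(alignments, path) -> None:
    rows = [
        {"read_id": a.read_id, "blocks": ",".join(f"{s}-{e}" for s, e in a.blocks)}
        for a in alignments
    ]
    pd.DataFrame(rows, columns=["read_id", "blocks"]).to_csv(path, sep="\t", index=False)


def bed12_to_alignments(path) -> list[SplicedAlignment]:
    """Convert BED12 records (blockSizes/blockStarts) to spliced alignments.

    Coordinates stay 0-based half-open; the chromosome column is ignored, so
    all records are assumed to live on one shared coordinate axis.
    """
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 BED fields, got {len(fields)}")
            chrom_start = int(fields[1])
            name = fields[3]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise ParseError(f"{path}: line {lineno}: blockSizes/blockStarts mismatch")
            blocks = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            out.append(SplicedAlignment(read_id=name, blocks=blocks))
    return out


def read_graph(path, fmt: str | None = None) -> nx.Graph:
    """Read an undirected simple graph from a 2-column edge list or SIF file.

    Self-loops are dropped with a warning and duplicate edges collapse to one.
    ``fmt`` is ``"edgelist"`` or ``"sif"``; default by file extension.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "edgelist"
    if fmt not in ("edgelist", "sif"):
        raise ValueError("fmt must be 'edgelist' or 'sif'")
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "edgelist":
                if len(fields) == 1:
                    g.add_node(fields[0])  # isolated node
                    continue
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) == 1:
                    g.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}: line {lineno}: SIF needs source, interaction, target(s)"
                    )
                # interaction type (fields[1]) is ignored
                pairs = [(fields[0], t) for t in fields[2:]]
            for u, v in pairs:
                if u == v:
                    n_loops += 1
                    continue
                g.add_edge(u, v)
    if n_loops:
        logger.warning("read_graph: dropped %d self-loop line(s) from %s", n_loops, path)
    return g


def write_graph(g: nx.Graph, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "edgelist"
    with open(path, "w") as fh:
        for u, v in sorted((sorted((str(a), str(b))) for a, b in g.edges())):
            if fmt == "sif":
                fh.write(f"{u}\tpp\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        for n in sorted(str(n) for n in nx.isolates(g)):
            fh.write(f"{n}\n")


def read_annotations(path) -> AnnotationTable:
    """Read a term->gene annotation TSV (term, gene)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("term", "gene") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    term_to_genes: dict[str, set] = {}
    for term, sub in df.groupby("term", sort=True):
        term_to_genes[str(term)] = set(sub["gene"].astype(str))
    return AnnotationTable(term_to_genes=term_to_genes)


def write_annotations(ann: AnnotationTable, path) -> None:
    rows = [
        {"term": term, "gene": gene}
        for term in sorted(ann.term_to_genes)
        for gene in sorted(ann.term_to_genes[term])
    ]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table in the canonical TSV dialect."""
    df.to_csv(path, sep="\t", index=False)
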