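"""Packaged published tables for Halomonas zincidurans B6 (JNCK00000000).

Small plain-text copies of the published genome-report numbers for the
type strain: the 31 heavy-metal-resistance genes with their closest
database relatives, the COG category counts, and the headline
nucleotide/gene-count figures.  These serve as inputs for reproducing
the published report statistics and the closest-hit taxonomy tally;
the genome sequence itself is not shipped (users supply the FASTA).
"""

from __future__ import annotations

import importlib.resources
import json

import pandas as pd

from .seqio import GeneAnnotation

_DATA = importlib.resources.files("hgtscan.data")


def _read_tsv(name: str) -> pd.DataFrame:
    with importlib.resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t")


def metal_resistance_genes() -> pd.DataFrame:
    """The 31 heavy-metal-resistance genes: coordinates as published
    (minus-strand rows high-to-low), products, and closest relatives."""
    return _read_tsv("halomonas_zincidurans_metal_genes.tsv")


def metal_gene_hits() -> pd.DataFrame:
    """Closest-relative hit table (gene_id, organism, taxon_class,
    identity percent, accession) for the 31 metal-resistance genes."""
    df = metal_resistance_genes()
    out = df[["gene_id", "organism", "taxon_class", "identity", "accession"]].copy()
    out["identity"] = out["identity"].str.rstrip("%").astype(float)
    return out


def metal_gene_annotations(contig_id: str = "JNCK01000001.1") -> list[GeneAnnotation]:
    """Published coordinates as normalized GeneAnnotations (start <= end,
    strand from the published strand column)."""
    out = []
    for row in metal_resistance_genes().itertuples(index=False):
        start, end = int(row.position_start), int(row.position_end)
        if start > end:
            start, end = end, start
        out.append(GeneAnnotation(row.gene_id, contig_id, start, end,
                                  row.strand, row.product))
    return out


def cog_counts() -> tuple[dict[str, int], int, int]:
    """(per-category counts, not_in_cogs, total_genes) as published."""
    df = _read_tsv("halomonas_zincidurans_cog_counts.tsv")
    counts = {r.code: int(r.count) for r in df.itertuples(index=False)}
    report = genome_report()
    return counts, int(report["not_in_cogs"]), int(report["total_genes"])


def genome_report() -> dict:
    """Published headline genome figures (contig sizes, coding bp, gene
    counts)."""
    with importlib.resources.as_file(
        _DATA / "halomonas_zincidurans_genome_report.json"
    ) as path:
        return json.loads(path.read_text())
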