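"""Genome report statistics: N50, nucleotide/gene content, COG tables.

Reproduces the conventions of standard-genomic-report tables:
percentages are always recomputed from counts (never trusted from
input), printed to two decimals with half-up rounding, and the COG
category table supports the dual-denominator convention used in such
reports (category percentages over the total number of category
assignments; the not-in-COGs percentage over the total gene count).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .seqio import GeneAnnotation, SequenceSet

#: The 25 one-letter COG functional category codes.
COG_CODES = "JAKLBDYVTMNZWUOCGEFHIPQRS"

COG_DESCRIPTIONS = {
    "J": "Translation",
    "A": "RNA processing and modification",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "B": "Chromatin structure and dynamics",
    "D": "Cell cycle control, mitosis and meiosis",
    "Y": "Nuclear structure",
    "V": "Defense mechanisms",
    "T": "Signal transduction mechanisms",
    "M": "Cell wall/membrane biogenesis",
    "N": "Cell motility",
    "Z": "Cytoskeleton",
    "W": "Extracellular structures",
    "U": "Intracellular trafficking and secretion",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "C": "Energy production and conversion",
    "G": "Carbohydrate transport and metabolism",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
}


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded half-up to ``decimals`` places (report style)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def n50(contig_lengths: list[int]) -> int:
    """N50: the smallest length L such that contigs of length >= L hold
    at least half the assembly (sort descending, accumulate, first
    length crossing total/2)."""
    if not contig_lengths:
        raise ValueError("empty contig length list")
    if any(length <= 0 for length in contig_lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(contig_lengths, reverse=True)
    half = sum(ordered) / 2
    running = 0
    for length in ordered:
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def assembly_size(contig_lengths: list[int]) -> int:
    """Total assembly size (sum of contig lengths)."""
    if any(length <= 0 for length in contig_lengths):
        raise ValueError("contig lengths must be positive")
    return int(sum(contig_lengths))


@dataclass(frozen=True)
class GenomeSummary:
    """Nucleotide-content and gene-count rows of a genome report."""

    genome_size_bp: int
    n_contigs: int
    n50_bp: int
    dna_coding_bp: int
    dna_coding_percent: float
    gc_bp: int
    gc_percent: float
    total_genes: int
    protein_coding_genes: int
    protein_coding_percent: float
    rna_genes: int
    rna_percent: float


def _coding_footprint_bp(seqs: SequenceSet, genes: list[GeneAnnotation]) -> int:
    """Genomic positions covered by at least one gene (overlaps counted once)."""
    total = 0
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig_id, members in by_contig.items():
        if contig_id not in seqs:
            raise ValueError(f"annotation contig {contig_id!r} not in sequence set")
        length = len(seqs[contig_id])
        mask = np.zeros(length, dtype=bool)
        for g in members:
            if g.end > length:
                raise ValueError(
                    f"{g.gene_id}: coordinates exceed contig {contig_id!r}"
                )
            mask[g.start - 1:g.end] = True
        total += int(mask.sum())
    return total


def genome_summary(seqs: SequenceSet, genes: list[GeneAnnotation]) -> GenomeSummary:
    """Compute the genome report from sequences and typed annotations.

    ``genes`` carry ``gene_type`` tags ("protein" or "rna"); coding bp
    is the union footprint of all genes so overlapping features are not
    double-counted.  GC is counted from the sequence, never taken from
    metadata.
    """
    lengths = list(seqs.lengths.values())
    size = assembly_size(lengths)
    coding = _coding_footprint_bp(seqs, genes) if genes else 0
    gc_bp = sum(seq.count("G") + seq.count("C") for seq in seqs.entries.values())
    protein = sum(1 for g in genes if g.gene_type == "protein")
    rna = sum(1 for g in genes if g.gene_type == "rna")
    total_genes = len(genes)
    return GenomeSummary(
        genome_size_bp=size,
        n_contigs=len(seqs),
        n50_bp=n50(lengths),
        dna_coding_bp=coding,
        dna_coding_percent=percent(coding, size) if size else 0.0,
        gc_bp=gc_bp,
        gc_percent=percent(gc_bp, size),
        total_genes=total_genes,
        protein_coding_genes=protein,
        protein_coding_percent=percent(protein, total_genes) if total_genes else 0.0,
        rna_genes=rna,
        rna_percent=percent(rna, total_genes) if total_genes else 0.0,
    )


def cog_table_from_counts(
    counts: dict[str, int],
    not_in_cogs: int,
    total_genes: int,
    uniform_denominator: bool = False,
) -> pd.DataFrame:
    """COG category table from per-category assignment counts.

    Default (report) convention uses two denominators: category rows
    divide by the sum of all category assignment counts (a gene with
    two categories contributes twice); the not-in-COGs row divides by
    ``total_genes``.  ``uniform_denominator=True`` divides every row by
    ``total_genes`` instead.
    """
    unknown = set(counts) - set(COG_CODES)
    if unknown:
        raise ValueError(f"unknown COG category letters: {sorted(unknown)}")
    assignments_total = sum(counts.values())
    cat_denominator = total_genes if uniform_denominator else assignments_total
    rows = []
    for code in COG_CODES:
        n = counts.get(code, 0)
        rows.append({
            "code": code,
            "count": n,
            "percent": percent(n, cat_denominator) if cat_denominator else 0.0,
            "description": COG_DESCRIPTIONS[code],
        })
    rows.append({
        "code": "-",
        "count": not_in_cogs,
        "percent": percent(not_in_cogs, total_genes) if total_genes else 0.0,
        "description": "Not in COGs",
    })
    df = pd.DataFrame(rows)
    df.attrs["category_denominator"] = cat_denominator
    df.attrs["not_in_cogs_denominator"] = total_genes
    return df


def cog_percentages(
    assignments: dict[str, list[str]],
    total_genes: int,
    uniform_denominator: bool = False,
) -> pd.DataFrame:
    """COG table from per-gene category assignments.

    ``assignments`` maps gene_id -> list of category letters; genes
    absent from the mapping (or mapped to an empty list) count as not
    in COGs.
    """
    counts: dict[str, int] = {}
    in_cogs = 0
    for gene_id, codes in assignments.items():
        if codes:
            in_cogs += 1
        for code in codes:
            if code not in COG_CODES:
                raise ValueError(f"{gene_id}: unknown COG category {code!r}")
            counts[code] = counts.get(code, 0) + 1
    if in_cogs > total_genes:
        raise ValueError("more genes assigned to COGs than total_genes")
    return cog_table_from_counts(
        counts, total_genes - in_cogs, total_genes, uniform_denominator
    )
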