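"""Synthetic coding-sequence sets with controlled codon-usage structure.

Emulates the compositional situation a horizontal-transfer screen
faces: a large background population of genes drawn from one codon
profile (typically GC3-rich, as in a high-GC halophile genome) with a
few planted "alien" genes drawn from a divergent profile, plus truth
labels and a synthetic closest-relative hit table.  Everything is
deterministic under a single seed, with per-gene substreams so adding
genes never changes earlier genes' sequences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import GeneticCode
from .seqio import (
    GeneAnnotation,
    GeneRecord,
    SequenceSet,
    reverse_complement,
    write_fasta,
)

_NT = "ACGT"


@dataclass
class CodonProfile:
    """Per-amino-acid codon probabilities plus amino-acid frequencies."""

    label: str
    codon_probs: dict[str, dict[str, float]]   # aa -> codon -> probability
    aa_frequencies: dict[str, float]

    def __post_init__(self) -> None:
        for aa, probs in self.codon_probs.items():
            s = sum(probs.values())
            if not np.isclose(s, 1.0):
                raise ValueError(f"codon probabilities for {aa!r} sum to {s}")
        s = sum(self.aa_frequencies.values())
        if not np.isclose(s, 1.0):
            raise ValueError(f"amino-acid frequencies sum to {s}")


def make_profile(
    gc3_bias: float,
    alpha: float = 0.0,
    seed: int = 0,
    code: GeneticCode | None = None,
    label: str = "profile",
) -> CodonProfile:
    """Codon profile with expected synonymous-GC3 ~= ``gc3_bias``.

    Within each synonymous family, probability mass ``gc3_bias`` is
    spread uniformly over G/C-ending codons and ``1 - gc3_bias`` over
    A/T-ending codons; families lacking one class put all mass on the
    other.  ``alpha > 0`` adds Dirichlet jitter around that base profile
    (concentration = base / alpha, so alpha -> 0 recovers the
    deterministic base); the jitter is fixed by ``seed``.

    Amino-acid frequencies default to uniform over the 20 amino acids:
    the screen is RSCU-based and insensitive to amino-acid composition.
    """
    if not 0.0 <= gc3_bias <= 1.0:
        raise ValueError("gc3_bias must be in [0, 1]")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    code = code or GeneticCode.from_table_id(11)
    rng = np.random.default_rng(seed)
    codon_probs: dict[str, dict[str, float]] = {}
    for aa, codons in code.families.items():
        gc_ending = [c for c in codons if c[2] in "GC"]
        at_ending = [c for c in codons if c[2] in "AT"]
        probs: dict[str, float] = {}
        if not at_ending:
            for c in gc_ending:
                probs[c] = 1.0 / len(gc_ending)
        elif not gc_ending:
            for c in at_ending:
                probs[c] = 1.0 / len(at_ending)
        else:
            for c in gc_ending:
                probs[c] = gc3_bias / len(gc_ending)
            for c in at_ending:
                probs[c] = (1.0 - gc3_bias) / len(at_ending)
        if alpha > 0:
            support = [c for c in codons if probs[c] > 0]
            if len(support) > 1:
                conc = np.array([probs[c] / alpha for c in support])
                jittered = rng.dirichlet(conc)
                for c, p in zip(support, jittered):
                    probs[c] = float(p)
        codon_probs[aa] = probs
    aas = sorted(code.families)
    aa_freq = {aa: 1.0 / len(aas) for aa in aas}
    return CodonProfile(label, codon_probs, aa_freq)


@dataclass
class SyntheticGenome:
    """A simulated CDS set with truth labels and a host contig."""

    genes: list[GeneRecord]
    truth: dict[str, str]              # gene_id -> "background" | "alien"
    contigs: SequenceSet
    annotations: list[GeneAnnotation]
    seed: int
    params: dict = field(default_factory=dict)


def _simulate_gene(
    gene_id: str,
    n_aa: int,
    profile: CodonProfile,
    code: GeneticCode,
    rng: np.random.Generator,
) -> str:
    aas = sorted(profile.aa_frequencies)
    aa_p = np.array([profile.aa_frequencies[a] for a in aas])
    chosen = rng.choice(len(aas), size=n_aa, p=aa_p)
    parts = ["ATG"]
    for idx in chosen:
        probs = profile.codon_probs[aas[idx]]
        codons = sorted(probs)
        p = np.array([probs[c] for c in codons])
        parts.append(codons[rng.choice(len(codons), p=p)])
    stops = sorted(code.stop_codons)
    parts.append(stops[rng.choice(len(stops))])
    return "".join(parts)


def simulate_genome(
    n_background: int,
    n_alien: int,
    len_codons_range: tuple[int, int],
    bg_profile: CodonProfile,
    alien_profile: CodonProfile,
    seed: int,
    out_dir: str | os.PathLike | None = None,
) -> SyntheticGenome:
    """Simulate a CDS population with planted alien genes.

    Each gene is an ATG start, ``L`` iid amino acids drawn from the
    profile's amino-acid frequencies and translated through its codon
    probabilities, and a stop codon, with ``L`` uniform in
    ``len_codons_range``.  Genes are laid head-to-tail on one synthetic
    contig with short random spacers and random strands, so annotation
    extraction is exercised end to end.  All randomness derives from
    ``seed`` via per-gene substreams.

    When ``out_dir`` is given, writes genes.fasta, contig.fasta,
    annotations.tsv and truth.tsv there.
    """
    if n_background < 0 or n_alien < 0:
        raise ValueError("gene counts must be >= 0")
    if n_background + n_alien == 0:
        raise ValueError("at least one gene required")
    lo, hi = len_codons_range
    if lo < 10 or hi < lo:
        raise ValueError("length range must satisfy 10 <= lo <= hi")
    code = GeneticCode.from_table_id(11)

    n_total = n_background + n_alien
    streams = np.random.SeedSequence(seed).spawn(n_total + 1)
    layout_rng = np.random.default_rng(streams[-1])

    genes: list[GeneRecord] = []
    truth: dict[str, str] = {}
    contig_parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 0
    contig_id = "synth_contig_1"
    for k in range(n_total):
        is_alien = k >= n_background
        label = "alien" if is_alien else "background"
        profile = alien_profile if is_alien else bg_profile
        gene_id = f"SYN_{label.upper()[:2]}{k:04d}"
        rng = np.random.default_rng(streams[k])
        n_aa = int(rng.integers(lo, hi + 1))
        seq = _simulate_gene(gene_id, n_aa, profile, code, rng)

        spacer_len = int(layout_rng.integers(5, 51))
        spacer = "".join(_NT[i] for i in layout_rng.integers(0, 4, size=spacer_len))
        strand = "+" if layout_rng.random() < 0.5 else "-"
        contig_parts.append(spacer)
        pos += spacer_len
        start = pos + 1
        end = pos + len(seq)
        contig_parts.append(seq if strand == "+" else reverse_complement(seq))
        pos = end
        ann = GeneAnnotation(gene_id, contig_id, start, end, strand,
                             product=f"synthetic {label} gene")
        annotations.append(ann)
        genes.append(GeneRecord(gene_id, seq, ann))
        truth[gene_id] = label

    contigs = SequenceSet()
    contigs.add(contig_id, "".join(contig_parts), "synthetic contig")
    genome = SyntheticGenome(
        genes=genes, truth=truth, contigs=contigs, annotations=annotations,
        seed=seed,
        params={
            "n_background": n_background, "n_alien": n_alien,
            "len_codons_range": [lo, hi],
            "bg_profile": bg_profile.label, "alien_profile": alien_profile.label,
        },
    )
    if out_dir is not None:
        write_outputs(genome, out_dir)
    return genome


def write_outputs(genome: SyntheticGenome, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    gene_set = SequenceSet()
    for g in genome.genes:
        gene_set.add(g.gene_id, g.sequence, genome.truth[g.gene_id])
    write_fasta(gene_set, os.path.join(out_dir, "genes.fasta"))
    write_fasta(genome.contigs, os.path.join(out_dir, "contig.fasta"))
    with open(os.path.join(out_dir, "annotations.tsv"), "w") as fh:
        for a in genome.annotations:
            fh.write(f"{a.gene_id}\t{a.contig_id}\t{a.start}\t{a.end}\t"
                     f"{a.strand}\t{a.product}\n")
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("gene_id\tlabel\n")
        for g in genome.genes:
            fh.write(f"{g.gene_id}\t{genome.truth[g.gene_id]}\n")


#: Organism pools for synthetic hit tables: family members vs outsiders.
DEFAULT_SELF_ORGANISMS = (
    "Halomonas lutea", "Halomonas smyrnensis", "Halomonas sp.",
    "Chromohalobacter salexigens", "Cobetia marina",
)
DEFAULT_FOREIGN_ORGANISMS = (
    "Burkholderia cepacia", "Pseudomonas putida", "Paraglaciecola polaris",
    "Stenotrophomonas maltophilia", "Idiomarina sediminum",
    "Sphingopyxis baekryungensis", "Hyphomonas neptunium",
)


def simulate_hit_table(
    truth: dict[str, str],
    self_organisms: tuple[str, ...] = DEFAULT_SELF_ORGANISMS,
    foreign_organisms: tuple[str, ...] = DEFAULT_FOREIGN_ORGANISMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic closest-relative table consistent with truth labels.

    Background genes draw organisms from ``self_organisms``, alien genes
    from ``foreign_organisms``; identities are uniform in [40, 99].
    """
    if not self_organisms or not foreign_organisms:
        raise ValueError("organism lists must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for k, (gene_id, label) in enumerate(truth.items()):
        pool = foreign_organisms if label == "alien" else self_organisms
        organism = pool[rng.integers(0, len(pool))]
        rows.append({
            "gene_id": gene_id,
            "organism": organism,
            "taxon_class": "synthetic",
            "identity": float(rng.integers(40, 100)),
            "accession": f"SYN_{k:06d}",
        })
    return pd.DataFrame(rows)
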