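"""Codon-usage composition: codon counts, GC metrics and RSCU.

These are the per-gene and pooled-background quantities a codon-usage
analysis tool (CodonW-style) reports: total and positional G+C content,
synonymous third-position G+C (GC3s), and relative synonymous codon
usage.

RSCU of codon *c* encoding amino acid *a* with synonymous family size
``k_a``::

    RSCU_c = n_c / ((1 / k_a) * sum_{c' in syn(a)} n_{c'})

i.e. the observed count divided by the count expected under uniform use
of the family.  Amino acids never observed in the gene leave their
codons' RSCU *undefined* (``None``), which is distinct from an RSCU of
0 (the family used but this codon avoided).

Under the bacterial genetic code (translation table 11) the degenerate
codon universe — sense codons of amino acids with at least two
synonymous codons — contains exactly 59 codons: the 61 sense codons
minus ATG (Met) and TGG (Trp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from .seqio import GeneRecord

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("TCAG", repeat=3)
)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino acid translation table with synonymous families.

    ``degenerate`` is the set of codons belonging to amino acids with
    family size >= 2, excluding stops — the universe over which RSCU
    fold changes and GC3s are evaluated.
    """

    table_id: int
    forward: dict[str, str]          # sense codon -> amino acid
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]]  # amino acid -> synonymous codons
    degenerate: frozenset[str]

    @classmethod
    @lru_cache(maxsize=None)
    def from_table_id(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(table.forward_table)
        stops = frozenset(table.stop_codons)
        families: dict[str, list[str]] = {}
        for codon, aa in forward.items():
            families.setdefault(aa, []).append(codon)
        fam = {aa: tuple(sorted(cs)) for aa, cs in families.items()}
        degenerate = frozenset(
            c for aa, cs in fam.items() if len(cs) >= 2 for c in cs
        )
        code = cls(table_id, forward, stops, fam, degenerate)
        if table_id == 11 and len(code.degenerate) != 59:
            raise AssertionError(
                "translation table 11 must yield a 59-codon degenerate universe"
            )
        return code

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.forward[codon]]

    def family_size(self, codon: str) -> int:
        return len(self.family_of(codon))


@dataclass
class CodonCountTable:
    """Counts of the 64 codons plus a tally of ambiguity-excluded codons."""

    counts: dict[str, int]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        full.update(self.counts)
        unknown = set(full) - set(ALL_CODONS)
        if unknown:
            raise ValueError(f"non-codon keys in count table: {sorted(unknown)}")
        self.counts = full

    @property
    def n_codons_total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        summed = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCountTable(summed, self.n_excluded + other.n_excluded)


@dataclass(frozen=True)
class CompositionProfile:
    """Derived composition metrics for one codon count table.

    All GC fractions are in [0, 1].  ``gc3_all`` is over third positions
    of every counted codon (stops included); ``gc3_syn`` restricts to the
    degenerate codon universe (GC3s).  ``rscu`` maps each sense codon to
    a non-negative value or ``None`` when the amino acid is absent.
    """

    gc: float
    gc1: float
    gc2: float
    gc3_all: float
    gc3_syn: float
    rscu: dict[str, float | None] = field(hash=False)
    n_codons: int = 0


def count_codons(gene: GeneRecord | str) -> CodonCountTable:
    """Count consecutive non-overlapping codons from position 1.

    A trailing partial codon (length not divisible by 3) is dropped;
    triplets containing non-ACGT characters are excluded and tallied in
    ``n_excluded``.
    """
    seq = gene.sequence if isinstance(gene, GeneRecord) else gene
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    counts: dict[str, int] = {}
    excluded = 0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if set(codon) <= set("ACGT"):
            counts[codon] = counts.get(codon, 0) + 1
        else:
            excluded += 1
    return CodonCountTable(counts, excluded)


def gc_metrics(
    table: CodonCountTable, code: GeneticCode | None = None
) -> tuple[float, float, float, float, float]:
    """(gc, gc1, gc2, gc3_all, gc3_syn) for a count table.

    ``gc`` is over all counted codon positions; positional metrics over
    the corresponding position of every counted codon.  ``gc3_syn`` is
    computed over third positions of degenerate-universe codons only
    (stops and the single-codon amino acids ATG/TGG excluded).
    """
    code = code or GeneticCode.from_table_id(11)
    total = table.n_codons_total
    if total == 0:
        raise ValueError("empty codon count table")
    pos_gc = [0, 0, 0]
    for codon, n in table.counts.items():
        if n == 0:
            continue
        for k in range(3):
            if codon[k] in "GC":
                pos_gc[k] += n
    gc1, gc2, gc3_all = (p / total for p in pos_gc)
    gc = sum(pos_gc) / (3 * total)
    syn_total = sum(table.counts[c] for c in code.degenerate)
    syn_gc = sum(table.counts[c] for c in code.degenerate if c[2] in "GC")
    gc3_syn = syn_gc / syn_total if syn_total else float("nan")
    return gc, gc1, gc2, gc3_all, gc3_syn


def rscu(table: CodonCountTable, code: GeneticCode | None = None) -> dict[str, float | None]:
    """RSCU for every sense codon; ``None`` where the amino acid is absent.

    Stop codons never receive a value.
    """
    code = code or GeneticCode.from_table_id(11)
    out: dict[str, float | None] = {}
    for aa, codons in code.families.items():
        fam_total = sum(table.counts[c] for c in codons)
        if fam_total == 0:
            for c in codons:
                out[c] = None
        else:
            k = len(codons)
            for c in codons:
                out[c] = table.counts[c] * k / fam_total
    return out


def compute_profile(
    table: CodonCountTable, code: GeneticCode | None = None
) -> CompositionProfile:
    """Full composition profile (GC metrics + RSCU) for one count table."""
    code = code or GeneticCode.from_table_id(11)
    gc, gc1, gc2, gc3_all, gc3_syn = gc_metrics(table, code)
    return CompositionProfile(
        gc=gc, gc1=gc1, gc2=gc2, gc3_all=gc3_all, gc3_syn=gc3_syn,
        rscu=rscu(table, code), n_codons=table.n_codons_total,
    )


def pool_background(
    genes: list[GeneRecord], code: GeneticCode | None = None
) -> tuple[CodonCountTable, CompositionProfile]:
    """Pool all genes into one background count table and profile.

    The profile is computed from the pooled counts, not averaged over
    per-gene profiles, matching the convention of comparing a gene
    against the totality of protein-coding genes.
    """
    if not genes:
        raise ValueError("cannot pool an empty gene list")
    code = code or GeneticCode.from_table_id(11)
    pooled = count_codons(genes[0])
    for g in genes[1:]:
        pooled = pooled + count_codons(g)
    return pooled, compute_profile(pooled, code)


def composition_table(genes: list[GeneRecord], code: GeneticCode | None = None):
    """Per-gene metrics as a DataFrame (one row per gene, 64 RSCU columns).

    Undefined RSCU values serialize as NA.
    """
    import pandas as pd

    code = code or GeneticCode.from_table_id(11)
    rows = []
    for g in genes:
        table = count_codons(g)
        p = compute_profile(table, code)
        row: dict[str, object] = {
            "gene_id": g.gene_id,
            "n_codons": table.n_codons_total,
            "gc": p.gc, "gc1": p.gc1, "gc2": p.gc2,
            "gc3_all": p.gc3_all, "gc3_syn": p.gc3_syn,
        }
        for c in ALL_CODONS:
            row[f"rscu_{c}"] = p.rscu.get(c)
        rows.append(row)
    return pd.DataFrame(rows)
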