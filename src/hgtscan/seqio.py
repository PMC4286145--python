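"""Sequence and annotation I/O.

Reads genome contigs (FASTA), CDS annotations (GFF3 or a 6-column TSV
dialect), and closest-relative hit tables (TSV), and extracts in-frame
coding sequences with correct strand handling.

Coordinates are 1-based inclusive throughout, the convention used by GFF3
and by published gene tables.  Minus-strand annotations may be written
high-to-low (descending positions); the readers normalize them to
``start <= end`` and set the strand to ``-``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes accepted in input sequences.
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")


class SeqFormatError(ValueError):
    """Malformed sequence or annotation input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes preserved)."""
    return str(_bio_revcomp(seq))


@dataclass
class SequenceSet:
    """Ordered collection of named nucleotide sequences (e.g. contigs).

    ``entries`` maps identifier -> uppercase sequence; ``descriptions``
    keeps any FASTA header text after the first whitespace.
    """

    entries: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: str) -> str:
        return self.entries[key]

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __iter__(self):
        return iter(self.entries)

    def add(self, identifier: str, seq: str, description: str = "") -> None:
        if not identifier:
            raise SeqFormatError("empty sequence identifier")
        if identifier in self.entries:
            raise SeqFormatError(f"duplicate sequence identifier: {identifier!r}")
        seq = seq.upper()
        if not seq:
            raise SeqFormatError(f"empty sequence for record {identifier!r}")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise SeqFormatError(
                f"record {identifier!r} contains non-IUPAC nucleotide "
                f"characters: {sorted(bad)}"
            )
        self.entries[identifier] = seq
        self.descriptions[identifier] = description

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.entries.items()}


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature on a contig, 1-based inclusive, start <= end.

    ``strand`` conveys orientation; ``gene_type`` distinguishes protein
    CDS from RNA genes for report statistics.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    gene_type: str = "protein"

    def __post_init__(self) -> None:
        if self.start <= 0 or self.end <= 0:
            raise SeqFormatError(
                f"{self.gene_id}: coordinates must be positive "
                f"({self.start}-{self.end})"
            )
        if self.start > self.end:
            raise SeqFormatError(
                f"{self.gene_id}: start > end after normalization "
                f"({self.start} > {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise SeqFormatError(
                f"{self.gene_id}: unknown strand symbol {self.strand!r}"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRecord:
    """A CDS in reading-frame orientation (5'->3' of the coding strand)."""

    gene_id: str
    sequence: str
    source: GeneAnnotation | None = None

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> SequenceSet:
    """Read a (multi-record, possibly wrapped) FASTA file.

    Rejects empty files, duplicate identifiers and non-IUPAC characters,
    naming the offending record.
    """
    seqs = SequenceSet()
    for record in SeqIO.parse(str(path), "fasta"):
        description = record.description
        if description.startswith(record.id):
            description = description[len(record.id):].strip()
        seqs.add(record.id, str(record.seq), description)
    if len(seqs) == 0:
        raise SeqFormatError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: SequenceSet, path: str | os.PathLike, width: int = 70) -> None:
    """Write a SequenceSet as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in seqs.entries.items():
            desc = seqs.descriptions.get(name, "")
            header = f">{name} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _normalize_coords(gene_id: str, start: int, end: int, strand: str) -> tuple[int, int, str]:
    """Normalize descending coordinate pairs (published minus-strand style)."""
    if start > end:
        start, end = end, start
        strand = "-"
    return start, end, strand


def _read_annotations_tsv(path: str | os.PathLike) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SeqFormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns "
                    f"(gene_id, contig_id, start, end, strand, product), "
                    f"got {len(fields)}"
                )
            gene_id, contig_id, start_s, end_s, strand, product = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise SeqFormatError(
                    f"{path}:{lineno}: non-integer coordinates for {gene_id!r}"
                ) from exc
            start, end, strand = _normalize_coords(gene_id, start, end, strand)
            out.append(GeneAnnotation(gene_id, contig_id, start, end, strand, product))
    return out


def _read_annotations_gff3(path: str | os.PathLike) -> list[GeneAnnotation]:
    # gffutils builds an in-memory db; only CDS-type features are retained.
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneAnnotation] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        start, end, strand = _normalize_coords(gene_id, feat.start, feat.end, feat.strand)
        out.append(GeneAnnotation(gene_id, feat.seqid, start, end, strand, product))
    return out


def read_annotations(path: str | os.PathLike, dialect: str = "tsv") -> list[GeneAnnotation]:
    """Read CDS annotations from GFF3 (CDS features only) or 6-column TSV."""
    if dialect == "tsv":
        return _read_annotations_tsv(path)
    if dialect == "gff3":
        return _read_annotations_gff3(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def extract_cds(seqs: SequenceSet, annotations: list[GeneAnnotation]) -> list[GeneRecord]:
    """Extract in-frame CDS sequences in annotation order.

    Plus strand: the inclusive slice [start, end]; minus strand: its
    reverse complement.  A length not divisible by 3 is allowed (draft
    feature tables contain such records) and logged; the trailing partial
    codon is dropped later, during codon counting.
    """
    records: list[GeneRecord] = []
    for ann in annotations:
        if ann.contig_id not in seqs:
            raise SeqFormatError(
                f"{ann.gene_id}: contig {ann.contig_id!r} not in sequence set"
            )
        contig = seqs[ann.contig_id]
        if ann.end > len(contig):
            raise SeqFormatError(
                f"{ann.gene_id}: coordinates {ann.start}-{ann.end} exceed "
                f"contig {ann.contig_id!r} length {len(contig)}"
            )
        seq = contig[ann.start - 1:ann.end]
        if ann.strand == "-":
            seq = reverse_complement(seq)
        if len(seq) % 3 != 0:
            logger.warning(
                "%s: CDS length %d not divisible by 3; trailing %d nt will be "
                "ignored in codon analysis", ann.gene_id, len(seq), len(seq) % 3,
            )
        records.append(GeneRecord(ann.gene_id, seq, ann))
    return records


#: Column names required in a hit table.
HIT_TABLE_COLUMNS = ("gene_id", "organism", "taxon_class", "identity", "accession")

# Header aliases accepted when reading hit tables written by other tools.
_HIT_ALIASES = {"class": "taxon_class", "identity_percent": "identity"}


def read_hit_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a closest-relative hit table (TSV with header).

    Columns: gene_id, organism, taxon_class (alias: class), identity
    (``44`` or ``44%`` forms), accession.  Returns a DataFrame with
    identity as float percent in [0, 100].
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df = df.rename(columns=_HIT_ALIASES)
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SeqFormatError(f"hit table {path} missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise SeqFormatError(f"hit table {path} has duplicate gene ids: {dups}")

    def _parse_identity(value: str) -> float:
        try:
            pct = float(str(value).rstrip("%"))
        except ValueError as exc:
            raise SeqFormatError(f"unparseable identity value: {value!r}") from exc
        if not 0.0 <= pct <= 100.0:
            raise SeqFormatError(f"identity {pct} outside [0, 100]")
        return pct

    df["identity"] = df["identity"].map(_parse_identity)
    return df[list(HIT_TABLE_COLUMNS)].reset_index(drop=True)


def write_hit_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
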