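"""Compositional + taxonomic screen for horizontally transferred genes.

A gene is compositionally atypical when the RSCU of more than a
threshold fraction (default 25%) of the degenerate codons it uses
changes more than a threshold fold (default 2x, symmetric) relative to
the pooled codon usage of all protein-coding genes, or when its G+C /
synonymous-GC3 deviates from the genome background by more than a
percentage-point cutoff.  Independently, a gene whose closest database
relative falls outside the genome's own family (for Halomonas genomes,
Halomonadaceae) carries taxonomic evidence of transfer.  The two
evidence channels are reported separately and combined into an
evidence class, never forced into a single boolean.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .composition import (
    CodonCountTable,
    CompositionProfile,
    GeneticCode,
    compute_profile,
    count_codons,
    pool_background,
)
from .seqio import GeneRecord

logger = logging.getLogger(__name__)

EVIDENCE_CLASSES = ("both", "composition_only", "taxonomy_only", "none")


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of the screen.

    fold_threshold
        Symmetric RSCU fold-change cutoff (strictly greater than).
    fraction_threshold
        Fraction of used degenerate codons that must exceed the fold
        cutoff for the gene-level flag (strictly greater than).
    gc_delta_threshold
        Percentage-point deviation in GC or synonymous GC3 that raises
        the GC flag; deviations are always reported raw alongside.
    self_family
        Taxon family counted as "self" when classifying closest hits.
    strict_inequalities
        Use > (default) rather than >= for both thresholds.
    use_gc3_syn
        Compare synonymous-only GC3 (GC3s, default) rather than GC3
        over all codons.
    """

    fold_threshold: float = 2.0
    fraction_threshold: float = 0.25
    gc_delta_threshold: float = 5.0
    self_family: str = "Halomonadaceae"
    strict_inequalities: bool = True
    use_gc3_syn: bool = True

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.fraction_threshold < 1:
            raise ValueError("fraction_threshold must be in (0, 1)")
        if self.gc_delta_threshold <= 0:
            raise ValueError("gc_delta_threshold must be positive")

    def _exceeds(self, value: float, threshold: float) -> bool:
        return value > threshold if self.strict_inequalities else value >= threshold


@dataclass
class TaxonomyMap:
    """Genus -> family lookup for closest-hit classification.

    Unknown genera resolve to ``"unknown"`` — never silently to self.
    """

    genus_to_family: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "TaxonomyMap":
        """Packaged lookup covering Halomonadaceae genera and the genera
        occurring in published Halomonas heavy-metal-gene hit tables."""
        ref = importlib.resources.files("hgtscan.data") / "genus_families.tsv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["genus"], df["family"])))

    def family_of_organism(self, organism: str) -> tuple[str, str]:
        """(genus, family) for an organism name; genus is the first
        whitespace token, so 'Halomonas sp.' resolves by genus."""
        organism = organism.strip()
        if not organism:
            raise ValueError("empty organism name")
        genus = organism.split()[0].strip("*")
        return genus, self.genus_to_family.get(genus, "unknown")


@dataclass(frozen=True)
class AtypicalityResult:
    """Per-gene compositional screen output.

    ``n_used`` counts degenerate-universe codons present in the gene
    with a defined background RSCU; ``fraction_changed`` divides by
    ``n_used`` (authoritative), ``fraction_changed_of_59`` by the full
    degenerate-universe size for comparison.
    """

    gene_id: str
    n_used: int
    n_changed: int
    fraction_changed: float
    fraction_changed_of_59: float
    rscu_flag: bool
    gc_delta: float
    gc3_delta: float
    gc_flag: bool


@dataclass(frozen=True)
class HGTCall:
    """Combined per-gene verdict of the two evidence channels."""

    gene_id: str
    rscu_flag: bool
    gc_flag: bool
    foreign_hit: bool | None   # None: no hit or unresolvable genus
    evidence_class: str

    def __post_init__(self) -> None:
        composition = self.rscu_flag or self.gc_flag
        taxonomy = self.foreign_hit is True
        expected = _evidence_class(composition, taxonomy)
        if self.evidence_class != expected:
            raise ValueError(
                f"{self.gene_id}: evidence_class {self.evidence_class!r} "
                f"inconsistent with flags (expected {expected!r})"
            )


def _evidence_class(composition: bool, taxonomy: bool) -> str:
    if composition and taxonomy:
        return "both"
    if composition:
        return "composition_only"
    if taxonomy:
        return "taxonomy_only"
    return "none"


def fold_change(
    rscu_gene: float | None, rscu_bg: float | None
) -> float | None:
    """Symmetric RSCU fold change: max(g/b, b/g).

    Returns ``math.inf`` when the gene uses a codon whose background
    RSCU is exactly 0, and ``None`` (not applicable) when the gene does
    not use the codon or the background value is undefined.
    """
    if rscu_gene is None or rscu_gene == 0 or rscu_bg is None:
        return None
    if rscu_bg == 0:
        return math.inf
    return max(rscu_gene / rscu_bg, rscu_bg / rscu_gene)


def screen_gene(
    gene_profile: CompositionProfile,
    gene_counts: CodonCountTable,
    bg_profile: CompositionProfile,
    params: ScreenParams | None = None,
    code: GeneticCode | None = None,
    gene_id: str = "",
) -> AtypicalityResult:
    """Evaluate the fold-change rule and GC deviation for one gene."""
    params = params or ScreenParams()
    code = code or GeneticCode.from_table_id(11)
    n_used = 0
    n_changed = 0
    for codon in code.degenerate:
        if gene_counts.counts[codon] == 0:
            continue
        fc = fold_change(gene_profile.rscu.get(codon), bg_profile.rscu.get(codon))
        if fc is None:
            continue
        n_used += 1
        if params._exceeds(fc, params.fold_threshold):
            n_changed += 1
    if n_used == 0:
        raise ValueError(
            f"gene {gene_id or '<unnamed>'} has no degenerate codons to screen"
        )
    fraction = n_changed / n_used
    bg_gc3 = bg_profile.gc3_syn if params.use_gc3_syn else bg_profile.gc3_all
    gene_gc3 = gene_profile.gc3_syn if params.use_gc3_syn else gene_profile.gc3_all
    gc_delta = (gene_profile.gc - bg_profile.gc) * 100.0
    gc3_delta = (gene_gc3 - bg_gc3) * 100.0
    return AtypicalityResult(
        gene_id=gene_id,
        n_used=n_used,
        n_changed=n_changed,
        fraction_changed=fraction,
        fraction_changed_of_59=n_changed / len(code.degenerate),
        rscu_flag=params._exceeds(fraction, params.fraction_threshold),
        gc_delta=gc_delta,
        gc3_delta=gc3_delta,
        gc_flag=(
            abs(gc_delta) > params.gc_delta_threshold
            or abs(gc3_delta) > params.gc_delta_threshold
        ),
    )


def classify_hit(
    organism: str,
    taxmap: TaxonomyMap | None = None,
    params: ScreenParams | None = None,
) -> tuple[bool | None, str]:
    """(foreign_hit, family) for one closest-relative organism name.

    ``foreign_hit`` is True when the resolved family differs from
    ``params.self_family``, False when it matches, and None when the
    genus is not in the taxonomy map (excluded from tallies, logged).
    """
    taxmap = taxmap or TaxonomyMap.default()
    params = params or ScreenParams()
    genus, family = taxmap.family_of_organism(organism)
    if family == "unknown":
        logger.warning("genus %r not in taxonomy map; hit left unclassified", genus)
        return None, family
    return family != params.self_family, family


@dataclass
class ScreenResult:
    """Output of a genome-wide screen: per-gene calls, the tabular
    report, and a summary with 'X of N' style tallies."""

    calls: list[HGTCall]
    atypicality: list[AtypicalityResult]
    report: pd.DataFrame
    summary: dict


def screen_genome(
    genes: list[GeneRecord],
    hits: pd.DataFrame | None = None,
    subset: list[str] | None = None,
    params: ScreenParams | None = None,
    code: GeneticCode | None = None,
    taxmap: TaxonomyMap | None = None,
) -> ScreenResult:
    """Screen every (or a subset of) gene(s) against the pooled background.

    The background is always pooled from ALL supplied genes, even when
    ``subset`` restricts which genes are reported — the comparison set
    is the totality of protein-coding genes.
    """
    if not genes:
        raise ValueError("no genes supplied")
    params = params or ScreenParams()
    code = code or GeneticCode.from_table_id(11)
    taxmap = taxmap or TaxonomyMap.default()

    if subset is not None:
        known = {g.gene_id for g in genes}
        missing = [g for g in subset if g not in known]
        if missing:
            raise ValueError(f"subset gene ids absent from gene set: {missing}")
        report_ids = set(subset)
    else:
        report_ids = {g.gene_id for g in genes}

    _, bg_profile = pool_background(genes, code)
    hit_rows = {}
    if hits is not None:
        hit_rows = {r.gene_id: r for r in hits.itertuples(index=False)}

    calls: list[HGTCall] = []
    atypicality: list[AtypicalityResult] = []
    rows = []
    for gene in genes:
        if gene.gene_id not in report_ids:
            continue
        counts = count_codons(gene)
        profile = compute_profile(counts, code)
        atyp = screen_gene(profile, counts, bg_profile, params, code, gene.gene_id)
        atypicality.append(atyp)
        hit = hit_rows.get(gene.gene_id)
        if hit is not None:
            foreign, family = classify_hit(hit.organism, taxmap, params)
            organism = hit.organism
        else:
            foreign, family, organism = None, "", ""
        call = HGTCall(
            gene_id=gene.gene_id,
            rscu_flag=atyp.rscu_flag,
            gc_flag=atyp.gc_flag,
            foreign_hit=foreign,
            evidence_class=_evidence_class(
                atyp.rscu_flag or atyp.gc_flag, foreign is True
            ),
        )
        calls.append(call)
        rows.append({
            "gene_id": gene.gene_id,
            "n_used": atyp.n_used,
            "n_changed": atyp.n_changed,
            "fraction_changed": atyp.fraction_changed,
            "fraction_changed_of_59": atyp.fraction_changed_of_59,
            "rscu_flag": atyp.rscu_flag,
            "gc_delta": atyp.gc_delta,
            "gc3_delta": atyp.gc3_delta,
            "gc_flag": atyp.gc_flag,
            "hit_organism": organism,
            "hit_family": family,
            "foreign_hit": foreign,
            "evidence_class": call.evidence_class,
        })

    report = pd.DataFrame(rows)
    n_classified = sum(1 for c in calls if c.foreign_hit is not None)
    n_foreign = sum(1 for c in calls if c.foreign_hit is True)
    class_counts = {k: 0 for k in EVIDENCE_CLASSES}
    for c in calls:
        class_counts[c.evidence_class] += 1
    summary = {
        "n_genes_reported": len(calls),
        "n_rscu_flag": sum(c.rscu_flag for c in calls),
        "n_gc_flag": sum(c.gc_flag for c in calls),
        "n_hits_classified": n_classified,
        "n_foreign_hits": n_foreign,
        "foreign_hit_tally": f"{n_foreign} of {n_classified}",
        "evidence_class_counts": class_counts,
    }
    return ScreenResult(calls, atypicality, report, summary)
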