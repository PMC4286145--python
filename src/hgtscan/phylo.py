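"""Distance-based phylogenetics on pre-aligned nucleotide sequences.

The classical 16S-style pipeline: pairwise identity and Kimura
2-parameter (K2P) distances with pairwise deletion of gapped/ambiguous
sites, Saitou-Nei neighbor-joining, and nonparametric bootstrap support
for the internal bipartitions of the full-data tree.

K2P distance from the transition proportion P and transversion
proportion Q over comparable sites::

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

Trees are Bio.Phylo objects serialized to newick; the NJ tree is
unrooted, represented with a basal trifurcation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Clade, Tree

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distances undefined: substitution saturation for a sequence pair."""


@dataclass
class Alignment:
    """Ordered taxa -> equal-length gapped sequences (A/C/G/T/-/N)."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.seqs) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self.seqs = {t: s.upper() for t, s in self.seqs.items()}

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.seqs)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.seqs.values())))

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns drawn with replacement."""
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        return Alignment({t: "".join(s[i] for i in idx) for t, s in self.seqs.items()})


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file."""
    seqs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate taxon in alignment: {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return Alignment(seqs)


def _comparable(row_i: str, row_j: str):
    for a, b in zip(row_i, row_j):
        if a in "ACGT" and b in "ACGT":
            yield a, b


def k2p_distance(row_i: str, row_j: str, pair: tuple[str, str] = ("?", "?")) -> float:
    """Kimura 2-parameter distance with pairwise deletion.

    Raises SaturationError when the log arguments are non-positive,
    naming the pair.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows of unequal length")
    n = transitions = transversions = 0
    for a, b in _comparable(row_i, row_j):
        n += 1
        if a == b:
            continue
        same_class = ({a, b} <= _PURINES) or ({a, b} <= _PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError(f"no comparable sites between {pair[0]!r} and {pair[1]!r}")
    p, q = transitions / n, transversions / n
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance saturated for pair ({pair[0]!r}, {pair[1]!r}): "
            f"P={p:.3f}, Q={q:.3f}"
        )
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def pairwise_identity(row_i: str, row_j: str) -> float:
    """Percent identity over comparable (both unambiguous, ungapped) sites."""
    n = matches = 0
    for a, b in _comparable(row_i, row_j):
        n += 1
        matches += a == b
    if n == 0:
        raise ValueError("no comparable sites")
    return 100.0 * matches / n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distances")
        self.matrix = (self.matrix + self.matrix.T) / 2.0
        np.fill_diagonal(self.matrix, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t", index_label="taxon"
        )


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    taxa = aln.taxa
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(aln.seqs[taxa[i]], aln.seqs[taxa[j]], (taxa[i], taxa[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa, m)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.debug("negative branch length %.6g clamped to 0 (%s)", length, context)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor-joining on the Q-criterion.

    Ties in Q are broken by the lowest (i, j) index pair under the
    current node ordering, so runs are reproducible.  Negative estimated
    branch lengths are clamped to 0 (deficit logged).  The returned tree
    is unrooted (basal trifurcation).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    nodes: list[Clade] = [Clade(name=t) for t in dm.taxa]
    d = dm.matrix.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # Q(i, j) = (m - 2) d(i, j) - r_i - r_j
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # first = lowest (i, j)
        i, j = min(best), max(best)
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        ci, cj = nodes[i], nodes[j]
        ci.branch_length = _clamp(li, f"join of {ci.name or 'internal'}")
        cj.branch_length = _clamp(lj, f"join of {cj.name or 'internal'}")
        new = Clade(clades=[ci, cj])
        # distances from the new node to every remaining node
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.branch_length = _clamp(0.5 * (dab + dac - dbc), "final join")
    b.branch_length = _clamp(0.5 * (dab + dbc - dac), "final join")
    c.branch_length = _clamp(0.5 * (dac + dbc - dab), "final join")
    return Tree(root=Clade(clades=[a, b, c]), rooted=False)


def bipartitions(tree: Tree) -> set[frozenset]:
    """Internal-edge bipartitions as canonical leaf-name frozensets.

    Each internal edge splits the leaves in two; the side NOT containing
    the lexicographically smallest taxon is the canonical representative.
    Trivial splits (single leaf) are excluded.
    """
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    ref = min(all_leaves)
    out: set[frozenset] = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        canonical = side if ref not in side else all_leaves - side
        if 1 < len(canonical) < len(all_leaves) - 1:
            out.add(canonical)
    return out


def bootstrap(
    aln: Alignment, replicates: int, seed: int
) -> tuple[Tree, int]:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``replicates`` times; each
    replicate goes through K2P + NJ.  Support for each internal
    bipartition of the full-data tree is the percentage of successful
    replicates containing it (saturated replicates are skipped and
    counted; the count is returned).  Identical seeds give identical
    output.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(k2p_matrix(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    skipped = 0
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = nj_tree(k2p_matrix(rep))
        except SaturationError as exc:
            skipped += 1
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    effective = replicates - skipped
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    ref = min(all_leaves)
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        canonical = side if ref not in side else all_leaves - side
        if not 1 < len(canonical) < len(all_leaves) - 1:
            continue
        support = 100.0 * counts.get(canonical, 0) / effective if effective else 0.0
        clade.confidence = round(support)
    return tree, skipped


def write_newick(tree: Tree, path=None, min_support_shown: int | None = None) -> str:
    """Serialize to newick; returns the string, optionally writing a file.

    ``min_support_shown`` blanks confidences below a display cutoff
    (e.g. 60, the usual "values above 60% are shown" convention) in the
    written string only; the tree object keeps all values.
    """
    out = tree
    if min_support_shown is not None:
        import copy

        out = copy.deepcopy(tree)
        for clade in out.get_nonterminals():
            if clade.confidence is not None and clade.confidence < min_support_shown:
                clade.confidence = None
    handle = io.StringIO()
    Phylo.write(out, handle, "newick", format_branch_length="%.10g")
    text = handle.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> Tree:
    """Parse a newick string or file into a Bio.Phylo tree."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        return Phylo.read(io.StringIO(source), "newick")
    return Phylo.read(str(source), "newick")
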