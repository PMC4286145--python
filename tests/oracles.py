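"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: positional
character counting for GC metrics, a direct formula evaluation for
RSCU, a definition-level N50, and exhaustive unrooted-topology
enumeration with least-squares branch fitting for neighbor-joining.
"""

from __future__ import annotations

import itertools

import numpy as np

# Codon -> amino acid for the bacterial code, written out by hand so the
# oracle does not share the package's table construction.
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TO_AA = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
FAMILIES: dict[str, list[str]] = {}
for codon, aa in CODON_TO_AA.items():
    if aa != "*":
        FAMILIES.setdefault(aa, []).append(codon)
DEGENERATE = {c for cs in FAMILIES.values() if len(cs) >= 2 for c in cs}


def codons_of(seq: str) -> list[str]:
    seq = seq.upper()
    usable = len(seq) - len(seq) % 3
    return [
        seq[i:i + 3]
        for i in range(0, usable, 3)
        if set(seq[i:i + 3]) <= set("ACGT")
    ]


def gc_metrics_bruteforce(seq: str) -> tuple[float, float, float, float, float]:
    """Positional character counting over clean codons of a sequence."""
    cods = codons_of(seq)
    n = len(cods)
    gc_pos = [sum(c[k] in "GC" for c in cods) / n for k in range(3)]
    gc = sum(sum(ch in "GC" for ch in c) for c in cods) / (3 * n)
    syn = [c for c in cods if c in DEGENERATE]
    gc3s = sum(c[2] in "GC" for c in syn) / len(syn) if syn else float("nan")
    return gc, gc_pos[0], gc_pos[1], gc_pos[2], gc3s


def rscu_bruteforce(seq: str) -> dict[str, float | None]:
    cods = codons_of(seq)
    out: dict[str, float | None] = {}
    for aa, family in FAMILIES.items():
        total = sum(cods.count(c) for c in family)
        for c in family:
            out[c] = None if total == 0 else cods.count(c) * len(family) / total
    return out


def n50_bruteforce(lengths: list[int]) -> int:
    """Largest length L in the list such that contigs of length >= L
    hold at least half the assembly (direct definition scan)."""
    total = sum(lengths)
    candidates = [
        L for L in set(lengths)
        if sum(x for x in lengths if x >= L) >= total / 2
    ]
    return max(candidates)


# --- exhaustive unrooted-tree oracle --------------------------------------

def enumerate_topologies(leaves: tuple[str, ...]) -> list[dict]:
    """All unrooted binary topologies as adjacency dicts.

    Internal nodes are negative integers.  Built by sequentially
    attaching each leaf to every edge of every smaller topology
    (1, 3, 15, 105 ... trees for 3, 4, 5, 6 leaves).
    """
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    first = {-1: {leaves[0], leaves[1], leaves[2]},
             leaves[0]: {-1}, leaves[1]: {-1}, leaves[2]: {-1}}
    trees = [first]
    next_internal = -2
    for leaf in leaves[3:]:
        grown = []
        for adj in trees:
            edges = {
                frozenset((u, v)) for u, nb in adj.items() for v in nb
            }
            for edge in edges:
                u, v = tuple(edge)
                new = {k: set(nb) for k, nb in adj.items()}
                w = next_internal
                new[u].discard(v)
                new[v].discard(u)
                new[u].add(w)
                new[v].add(w)
                new[w] = {u, v, leaf}
                new[leaf] = {w}
                grown.append(new)
        trees = grown
        next_internal -= 1
    return trees


def _paths(adj: dict, leaves: tuple[str, ...]) -> dict[tuple[str, str], list[frozenset]]:
    """Leaf-pair -> list of edges on the connecting path (DFS)."""
    out = {}
    for a, b in itertools.combinations(leaves, 2):
        stack = [(a, [a])]
        seen = {a}
        while stack:
            node, path = stack.pop()
            if node == b:
                out[(a, b)] = [
                    frozenset((path[i], path[i + 1])) for i in range(len(path) - 1)
                ]
                break
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, path + [nxt]))
    return out


def fit_topology(adj: dict, leaves: tuple[str, ...], dmat: np.ndarray):
    """Least-squares branch lengths for a topology; returns (residual,
    edge length map)."""
    edges = sorted(
        {frozenset((u, v)) for u, nb in adj.items() for v in nb},
        key=lambda e: sorted(map(str, e)),
    )
    index = {e: k for k, e in enumerate(edges)}
    paths = _paths(adj, leaves)
    rows, target = [], []
    for (a, b), path in paths.items():
        row = np.zeros(len(edges))
        for e in path:
            row[index[e]] = 1.0
        rows.append(row)
        target.append(dmat[leaves.index(a), leaves.index(b)])
    A, y = np.array(rows), np.array(target)
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.linalg.norm(A @ x - y))
    return residual, dict(zip(edges, x))


def topology_splits(adj: dict, leaves: tuple[str, ...]) -> set[frozenset]:
    """Canonical internal-edge bipartitions of an adjacency topology."""
    ref = min(leaves)
    splits = set()
    internal_edges = {
        frozenset((u, v))
        for u, nb in adj.items() for v in nb
        if isinstance(u, int) and isinstance(v, int)
    }
    for edge in internal_edges:
        u, v = tuple(edge)
        # leaves reachable from u without crossing the edge
        stack, seen = [u], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if not isinstance(node, int):
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        canonical = frozenset(side) if ref not in side else frozenset(leaves) - side
        if 1 < len(canonical) < len(leaves) - 1:
            splits.add(canonical)
    return splits


def best_topology_splits(leaves: tuple[str, ...], dmat: np.ndarray) -> set[frozenset]:
    """Splits of the (unique, for additive input) zero-residual topology."""
    best, best_res = None, np.inf
    for adj in enumerate_topologies(leaves):
        res, _ = fit_topology(adj, leaves, dmat)
        if res < best_res:
            best, best_res = adj, res
    assert best_res < 1e-8, "input matrix is not additive"
    return topology_splits(best, leaves)


def random_additive_tree(leaves: tuple[str, ...], rng: np.random.Generator):
    """Random topology + random branch lengths; returns (adjacency,
    leaf distance matrix)."""
    topologies = enumerate_topologies(leaves)
    adj = topologies[rng.integers(0, len(topologies))]
    edges = {frozenset((u, v)) for u, nb in adj.items() for v in nb}
    lengths = {e: float(rng.uniform(0.1, 2.0)) for e in edges}
    n = len(leaves)
    dmat = np.zeros((n, n))
    paths = _paths(adj, leaves)
    for (a, b), path in paths.items():
        d = sum(lengths[e] for e in path)
        i, j = leaves.index(a), leaves.index(b)
        dmat[i, j] = dmat[j, i] = d
    return adj, dmat
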