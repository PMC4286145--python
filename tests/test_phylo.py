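import math

import numpy as np
import pytest

from hgtscan.phylo import (
    Alignment,
    DistanceMatrix,
    SaturationError,
    bipartitions,
    bootstrap,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    pairwise_identity,
    read_newick,
    write_newick,
)

from oracles import best_topology_splits, random_additive_tree


def leaf_set(*names):
    return frozenset(names)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_transition_closed_form(self):
        # P = 0.25, Q = 0: d = -0.5 ln(0.5)
        assert k2p_distance("ACGT", "GCGT") == pytest.approx(0.5 * math.log(2))

    def test_single_transversion_closed_form(self):
        # P = 0, Q = 0.25: d = -0.5 ln(0.75) - 0.25 ln(0.5)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.5)
        assert k2p_distance("ACGT", "CCGT") == pytest.approx(expected)

    def test_saturation_error_names_pair(self):
        with pytest.raises(SaturationError, match="'x'.*'y'"):
            k2p_distance("AAAA", "CCCC", pair=("x", "y"))

    def test_pairwise_deletion(self):
        # gapped/N sites dropped before P and Q are computed
        assert k2p_distance("AC-TN", "ACGTA") == 0.0

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p_distance("----", "ACGT")

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 100))
            b = list(a)
            for i in rng.choice(100, size=10, replace=False):
                b[i] = rng.choice(list("ACGT"))
            assert k2p_distance(a, "".join(b)) >= 0.0


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGT", "ACGT") == 100.0

    def test_direct_count(self):
        assert pairwise_identity("ACGT", "GCGT") == 75.0

    def test_gap_sites_excluded(self):
        assert pairwise_identity("AC-T", "ACGT") == 100.0


class TestNeighborJoining:
    def test_three_taxa_solves_exactly(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(dm)
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        # a = (dAB + dAC - dBC)/2 = 1, b = 2, c = 3
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:2,D:3)) -> path-length matrix
        m = np.array([[0, 3, 4, 5],
                      [3, 0, 5, 6],
                      [4, 5, 0, 5],
                      [5, 6, 5, 0]], float)
        dm = DistanceMatrix(("A", "B", "C", "D"), m)
        tree = nj_tree(dm)
        assert bipartitions(tree) == {leaf_set("C", "D")}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree.distance(a, b) == pytest.approx(m[i, j])

    def test_equidistant_matrix_uses_documented_tiebreak(self):
        m = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), m))
        # lowest index pair (A, B) joined first
        assert bipartitions(tree) == {leaf_set("C", "D")}

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_additive_recovery_vs_exhaustive_enumeration(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        leaves = tuple("ABCDEF"[:n_leaves])
        for _ in range(3):
            _, dmat = random_additive_tree(leaves, rng)
            tree = nj_tree(DistanceMatrix(leaves, dmat))
            assert bipartitions(tree) == best_topology_splits(leaves, dmat)
            for i, a in enumerate(leaves):
                for j, b in enumerate(leaves):
                    if i < j:
                        assert tree.distance(a, b) == pytest.approx(dmat[i, j])

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            pts = rng.normal(size=(5, 3))
            m = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            tree = nj_tree(DistanceMatrix(tuple("ABCDE"), m))
            for clade in tree.find_clades():
                if clade.branch_length is not None:
                    assert clade.branch_length >= 0.0

    def test_matches_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(21)
        pts = rng.normal(size=(6, 4))
        m = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        taxa = tuple("ABCDEF")
        ours = bipartitions(nj_tree(DistanceMatrix(taxa, m)))
        sk_tree = sk_nj(SkDM(m, ids=list(taxa)))
        theirs = set()
        all_leaves = frozenset(taxa)
        ref = min(taxa)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            canonical = side if ref not in side else all_leaves - side
            if 1 < len(canonical) < len(taxa) - 1:
                theirs.add(canonical)
        assert ours == theirs

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


def _divergent_alignment(seed=1, n_sites=300):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), n_sites))

    def mutate(s, n):
        s = list(s)
        for i in rng.choice(len(s), size=n, replace=False):
            s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
        return "".join(s)

    other = mutate(base, int(n_sites * 0.4))
    return Alignment({
        "A1": mutate(base, 5), "A2": mutate(base, 5),
        "B1": mutate(other, 5), "B2": mutate(other, 5),
    })


class TestBootstrap:
    def test_clear_split_gets_full_support(self):
        tree, skipped = bootstrap(_divergent_alignment(), 100, seed=3)
        assert skipped == 0
        supports = [c.confidence for c in tree.get_nonterminals()
                    if c.confidence is not None]
        assert supports == [100]

    def test_same_seed_identical_output(self):
        aln = _divergent_alignment()
        t1, _ = bootstrap(aln, 50, seed=7)
        t2, _ = bootstrap(aln, 50, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_single_replicate_supports_are_binary(self):
        tree, _ = bootstrap(_divergent_alignment(), 1, seed=5)
        for c in tree.get_nonterminals():
            if c.confidence is not None:
                assert c.confidence in (0, 100)

    def test_duplicated_columns_preserve_tree(self):
        aln = _divergent_alignment()
        doubled = Alignment({t: s + s for t, s in aln.seqs.items()})
        assert bipartitions(nj_tree(k2p_matrix(doubled))) == \
            bipartitions(nj_tree(k2p_matrix(aln)))


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self):
        tree, _ = bootstrap(_divergent_alignment(), 20, seed=2)
        parsed = read_newick(write_newick(tree))
        assert bipartitions(parsed) == bipartitions(tree)
        for a in ("A1", "A2", "B1", "B2"):
            for b in ("A1", "A2", "B1", "B2"):
                if a < b:
                    assert parsed.distance(a, b) == pytest.approx(
                        tree.distance(a, b), abs=1e-9)
        originals = sorted(c.confidence for c in tree.get_nonterminals()
                           if c.confidence is not None)
        recovered = sorted(int(c.confidence) for c in parsed.get_nonterminals()
                           if c.confidence is not None)
        assert recovered == originals

    def test_low_supports_hidden_only_in_output(self):
        tree, _ = bootstrap(_divergent_alignment(), 20, seed=2)
        for clade in tree.get_nonterminals():
            if clade.confidence is not None:
                clade.confidence = 45
        text = write_newick(tree, min_support_shown=60)
        assert "45" not in text
        # the tree object keeps the value
        assert any(c.confidence == 45 for c in tree.get_nonterminals())
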