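"""Alignment, distance, NJ and bootstrap checks.

The pairwise aligners are validated against an explicit enumeration oracle
that walks every possible gapped alignment of two short sequences and
scores affine gap runs directly.
"""

import numpy as np
import pytest

from wrkycensus.msa import MultipleAlignment, progressive_msa
from wrkycensus.pairwise import (
    load_matrix,
    needleman_wunsch,
    smith_waterman,
)
from wrkycensus.phylo import (
    DistanceMatrix,
    bootstrap_supports,
    neighbor_joining,
    p_distance_matrix,
)
from wrkycensus.records import ProteinRecord, SequenceSet
from wrkycensus.tree import PhyloTree

ALPHA = "ACDE"  # 4-letter alphabet for the enumeration oracle


def _pair_score(x, y, alphabet, subst):
    return subst[alphabet.index(x), alphabet.index(y)]


def brute_force_global(a, b, gap_open, gap_extend, matrix="BLOSUM62"):
    """Enumerate every alignment; a gap run of length L costs
    open + (L-1)*extend. Exponential, for tiny inputs only."""
    alphabet, subst = load_matrix(matrix)
    best = [-np.inf]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(
                i + 1, j + 1,
                score + _pair_score(a[i], b[j], alphabet, subst), "M",
            )
        if i < len(a):
            cost = gap_extend if last == "X" else gap_open
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if last == "Y" else gap_open
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "start")
    return best[0]


def brute_force_local(a, b, gap_open, gap_extend, matrix="BLOSUM62"):
    """Best global score over all substring pairs, floored at 0."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    score = brute_force_global(
                        a[i1:i2], b[j1:j2], gap_open, gap_extend, matrix
                    )
                    best = max(best, score)
    return best


def random_pairs(rng, n_pairs, max_len):
    for _ in range(n_pairs):
        la = int(rng.integers(1, max_len + 1))
        lb = int(rng.integers(1, max_len + 1))
        yield (
            "".join(rng.choice(list(ALPHA), la)),
            "".join(rng.choice(list(ALPHA), lb)),
        )


class TestNeedlemanWunsch:
    def test_identical_sequences_align_gap_free(self):
        aln = needleman_wunsch("MKVLWR", "MKVLWR")
        assert aln.aligned_a == aln.aligned_b == "MKVLWR"
        alphabet, subst = load_matrix("BLOSUM62")
        expected = sum(_pair_score(c, c, alphabet, subst) for c in "MKVLWR")
        assert aln.score == expected

    def test_empty_versus_single_residue(self):
        aln = needleman_wunsch("A", "")
        assert (aln.aligned_a, aln.aligned_b) == ("A", "-")
        assert aln.score == -10.0

    def test_alignment_degaps_to_inputs(self):
        aln = needleman_wunsch("HEAGAWGHEE", "PAWHEAE")
        assert aln.aligned_a.replace("-", "") == "HEAGAWGHEE"
        assert aln.aligned_b.replace("-", "") == "PAWHEAE"

    def test_matches_brute_force_on_short_pairs(self):
        rng = np.random.default_rng(42)
        for a, b in random_pairs(rng, 25, 6):
            expected = brute_force_global(a, b, 10.0, 0.5)
            got = needleman_wunsch(a, b).score
            assert got == pytest.approx(expected), (a, b)

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError, match="not in"):
            needleman_wunsch("A1", "AA")


class TestSmithWaterman:
    def test_identical_sequences_score_full_diagonal(self):
        aln = smith_waterman("MKVLWR", "MKVLWR")
        assert aln.aligned_a == "MKVLWR"
        assert aln.identity() == 1.0

    def test_disjoint_low_similarity_sequences_yield_empty_or_low(self):
        # No positive substitution scores between these residue sets
        aln = smith_waterman("PPPP", "GGGG")
        assert aln.score == 0.0 and aln.columns == 0

    def test_matches_brute_force_on_short_pairs(self):
        rng = np.random.default_rng(7)
        for a, b in random_pairs(rng, 12, 5):
            expected = brute_force_local(a, b, 10.0, 0.5)
            got = smith_waterman(a, b).score
            assert got == pytest.approx(expected), (a, b)


class TestProgressiveMSA:
    def test_identical_sequences_align_without_gaps(self):
        seqs = SequenceSet(
            [ProteinRecord(f"s{i}", "MKVLWRAGAE") for i in range(3)], "protein"
        )
        aln = progressive_msa(seqs)
        assert aln.columns == 10
        assert all(r == "MKVLWRAGAE" for r in aln.rows)

    def test_two_sequences_reduce_to_pairwise(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        seqs = SequenceSet(
            [ProteinRecord("a", a), ProteinRecord("b", b)], "protein"
        )
        aln = progressive_msa(seqs)
        pw = needleman_wunsch(a, b)
        assert aln.rows == [pw.aligned_a, pw.aligned_b]

    def test_substitution_only_family_recovers_site_homology(self):
        rng = np.random.default_rng(3)
        ancestor = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        records = []
        for i in range(5):
            seq = list(ancestor)
            for pos in rng.choice(60, size=6, replace=False):
                seq[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            records.append(ProteinRecord(f"t{i}", "".join(seq)))
        aln = progressive_msa(SequenceSet(records, "protein"))
        assert aln.columns == 60  # gap-free: homologous sites line up
        for i, rec in enumerate(records):
            assert aln.rows[aln.ids.index(rec.id)] == rec.seq

    def test_single_sequence_passthrough(self):
        seqs = SequenceSet([ProteinRecord("only", "MKV")], "protein")
        aln = progressive_msa(seqs)
        assert aln.ids == ["only"] and aln.rows == ["MKV"]


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment(["a", "b"], ["MKVL", "MKVL"])
        assert p_distance_matrix(aln).matrix[0, 1] == 0.0

    def test_one_mismatch_in_four_sites(self):
        aln = MultipleAlignment(["a", "b"], ["AAAA", "AAAT"])
        assert p_distance_matrix(aln).matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_skips_gap_columns(self):
        aln = MultipleAlignment(["a", "b"], ["A-CG", "AACG"])
        d = p_distance_matrix(aln)
        assert d.matrix[0, 1] == 0.0
        assert d.site_counts[0, 1] == 3

    def test_no_comparable_sites_is_an_error(self):
        aln = MultipleAlignment(["a", "b"], ["A--", "-AA"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            p_distance_matrix(aln)

    def test_premetric_properties(self):
        rng = np.random.default_rng(5)
        rows = [
            "".join(rng.choice(list("ACDE-"), 30)) for _ in range(4)
        ]
        rows = [r if r.replace("-", "") else "A" * 30 for r in rows]
        aln = MultipleAlignment(list("wxyz"), rows)
        try:
            d = p_distance_matrix(aln).matrix
        except ValueError:
            pytest.skip("degenerate random draw")
        assert np.allclose(d, d.T)
        assert np.all(d >= 0) and np.all(d <= 1)
        assert np.all(np.diag(d) == 0)


def random_tree_matrix(rng, n_taxa):
    """Path-length matrix of a random bifurcating tree (positive lengths)."""
    ids = [f"T{i}" for i in range(n_taxa)]
    # each cluster: dict leaf -> distance to cluster root
    clusters = [({leaf: 0.0}, leaf) for leaf in ids]
    D = {leaf: {} for leaf in ids}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        da, _ = clusters[i]
        db, _ = clusters[j]
        la, lb = rng.uniform(0.5, 3.0, size=2)
        for x, vx in da.items():
            for y, vy in db.items():
                D[x][y] = D[y][x] = vx + la + vy + lb
        merged = {k: v + la for k, v in da.items()}
        merged.update({k: v + lb for k, v in db.items()})
        clusters[i] = (merged, "internal")
        clusters.pop(j)
    m = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(n_taxa):
            if a != b:
                m[a, b] = D[ids[a]][ids[b]]
    return ids, m


class TestNeighborJoining:
    def test_three_taxa_solve_closed_form(self):
        ids = ["a", "b", "c"]
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids, m))
        d = tree.distances_from("a")
        assert d["b"] == pytest.approx(5.0, abs=1e-9)
        assert d["c"] == pytest.approx(9.0, abs=1e-9)
        # closed form: l(a) = (dab + dac - dbc)/2 = 2
        lengths = {leaf.label: leaf.length for leaf in tree.leaves()}
        assert lengths["a"] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_are_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(4):
            ids, m = random_tree_matrix(rng, n_taxa)
            tree = neighbor_joining(DistanceMatrix(ids, m))
            for i, a in enumerate(ids):
                d = tree.distances_from(a)
                for j, b in enumerate(ids):
                    if i != j:
                        assert d[b] == pytest.approx(m[i, j], abs=1e-9)

    def test_taxon_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(77)
        ids, m = random_tree_matrix(rng, 6)
        tree1 = neighbor_joining(DistanceMatrix(ids, m))
        perm = list(rng.permutation(6))
        ids2 = [ids[p] for p in perm]
        m2 = m[np.ix_(perm, perm)]
        tree2 = neighbor_joining(DistanceMatrix(ids2, m2))
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], m))


class TestBootstrap:
    def _two_clade_alignment(self):
        left, right = "AAAAAAAAAACCCCCCCCCC", "TTTTTTTTTTGGGGGGGGGG"
        rows = [left, left, left[:-1] + "G", right, right, right[:-1] + "A"]
        ids = [f"L{i}" for i in range(3)] + [f"R{i}" for i in range(3)]
        return MultipleAlignment(ids, rows)

    def test_strong_signal_gives_high_central_support(self):
        tree = bootstrap_supports(
            self._two_clade_alignment(), n_replicates=200, seed=5
        )
        central = frozenset(["R0", "R1", "R2"])
        supports = {
            bp: None for bp in tree.bipartitions()
        }
        assert central in supports
        # find the node carrying that bipartition
        found = [
            n.support
            for n in _internal_nodes(tree)
            if n.support is not None and n.support >= 95.0
        ]
        assert found, "central split should be supported at >= 95%"

    def test_same_seed_reproduces_supports(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_supports(aln, n_replicates=50, seed=9)
        t2 = bootstrap_supports(aln, n_replicates=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_degenerate_identical_rows_do_not_crash(self):
        aln = MultipleAlignment(
            ["a", "b", "c", "d"], ["ACGT", "ACGT", "ACGT", "ACGT"]
        )
        tree = bootstrap_supports(aln, n_replicates=20, seed=1)
        assert set(tree.leaf_labels()) == {"a", "b", "c", "d"}


def _internal_nodes(tree: PhyloTree):
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            yield node
            stack.extend(node.children)
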