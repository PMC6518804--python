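"""Distance computation, neighbor joining, UPGMA, outgroup rooting."""

import numpy as np
import pytest

from oracles import (least_squares_topology, manual_average_linkage,
                     newick_splits, path_distance_matrix,
                     random_additive_tree, tree_splits)
from tcskit.align import MultipleAlignment
from tcskit.phylogeny import (DistanceMatrix, neighbor_joining,
                              protein_distance, root_on_outgroup, upgma)


def _msa(rows):
    return MultipleAlignment(ids=[f"s{i}" for i in range(len(rows))],
                             rows=rows,
                             column_index=list(range(1, len(rows[0]) + 1)))


class TestProteinDistance:
    def test_identical_rows_have_zero_distance(self):
        dm = protein_distance(_msa(["MKVH", "MKVH"]))
        assert dm.values[0, 1] == 0.0

    def test_half_mismatch_gives_poisson_ln2(self):
        row_a = "A" * 100
        row_b = "A" * 50 + "C" * 50
        dm = protein_distance(_msa([row_a, row_b]))
        assert dm.values[0, 1] == pytest.approx(np.log(2.0))

    def test_gapped_columns_excluded(self):
        dm = protein_distance(_msa(["MK-H", "MKV-"]))
        # only the two shared ungapped columns count, both identical
        assert dm.values[0, 1] == 0.0

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(ValueError, match="share"):
            protein_distance(_msa(["MK--", "--VH"]))

    def test_saturation_capped(self):
        dm = protein_distance(_msa(["AAAA", "CCCC"]), max_distance=5.0)
        assert dm.values[0, 1] == 5.0

    def test_poisson_simulation_recovers_planted_rate(self):
        # substitute each site with probability p = 1 - exp(-d): the
        # corrected estimate must land within 10% of the planted distance
        rng = np.random.default_rng(3)
        length, d_true = 1000, 0.4
        p = 1 - np.exp(-d_true)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        a = rng.choice(alphabet, length)
        b = a.copy()
        hit = rng.random(length) < p
        b[hit] = rng.choice(alphabet, int(hit.sum()))
        # a fraction of substitutions land on the original letter; correct
        # the planted expectation accordingly
        p_eff = p * (1 - 1 / 20)
        d_eff = -np.log(1 - p_eff)
        dm = protein_distance(_msa(["".join(a), "".join(b)]))
        assert dm.values[0, 1] == pytest.approx(d_eff, rel=0.10)


class TestDistanceMatrixInvariants:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.5 * (5 + 9 - 10))
        assert lengths["B"] == pytest.approx(0.5 * (5 + 10 - 9))
        assert lengths["C"] == pytest.approx(0.5 * (9 + 10 - 5))

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        rng = np.random.default_rng(11)
        labels = [f"T{i}" for i in range(5)]
        edges, n_nodes = random_additive_tree(rng, labels)
        d = path_distance_matrix(edges, 5, n_nodes)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert newick_splits(tree, labels) == tree_splits(edges, 5, n_nodes)
        # exact branch lengths: tree path distances equal the input matrix
        dists = tree.tip_tip_distances()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert dists[a, b] == pytest.approx(d[i, j])

    def test_six_taxon_topology_matches_least_squares_search(self):
        rng = np.random.default_rng(29)
        labels = [f"T{i}" for i in range(6)]
        for _ in range(5):
            edges, n_nodes = random_additive_tree(rng, labels)
            d = path_distance_matrix(edges, 6, n_nodes)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert newick_splits(tree, labels) == \
                least_squares_topology(d, 6)

    def test_leaf_set_preserved(self):
        rng = np.random.default_rng(4)
        labels = [f"L{i}" for i in range(7)]
        edges, n_nodes = random_additive_tree(rng, labels)
        d = path_distance_matrix(edges, 7, n_nodes)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert sorted(t.name for t in tree.tips()) == sorted(labels)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        labels = [f"T{i}" for i in range(6)]
        edges, n_nodes = random_additive_tree(rng, labels)
        d = path_distance_matrix(edges, 6, n_nodes)
        perm = rng.permutation(6)
        tree_a = neighbor_joining(DistanceMatrix(labels, d))
        tree_b = neighbor_joining(DistanceMatrix(
            [labels[i] for i in perm], d[np.ix_(perm, perm)]))
        assert newick_splits(tree_a, labels) == newick_splits(tree_b, labels)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0, 1], [1, 0.0]])))


class TestUpgma:
    def test_identical_profiles_merge_at_zero_height(self):
        d = np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma(DistanceMatrix(["a", "b", "c"], d))
        a = tree.find("a")
        assert a.length == 0.0

    def test_four_by_four_hand_agglomeration(self):
        labels = ["a", "b", "c", "d"]
        d = np.array([
            [0, 2, 6, 10],
            [2, 0, 6, 10],
            [6, 6, 0, 8],
            [10, 10, 8, 0]], dtype=float)
        merges = manual_average_linkage(d, labels)
        # hand agglomeration: (a,b)@2, (ab,c)@6, (abc,d)@ (10+10+8)/3
        assert merges[0] == (frozenset("a"), frozenset("b"), 2)
        assert merges[1][2] == 6
        assert merges[2][2] == pytest.approx(28 / 3)
        tree = upgma(DistanceMatrix(labels, d))
        dists = tree.tip_tip_distances()
        assert dists["a", "b"] == pytest.approx(2)
        assert dists["a", "c"] == pytest.approx(6)
        assert dists["a", "d"] == pytest.approx(28 / 3)

    def test_ultrametric_input_recovered_exactly(self):
        # an ultrametric matrix is its own cophenetic matrix
        labels = ["a", "b", "c", "d"]
        d = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0]], dtype=float)
        tree = upgma(DistanceMatrix(labels, d))
        dists = tree.tip_tip_distances()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    assert dists[a, b] == pytest.approx(d[i, j])

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = 6
            pts = rng.normal(size=(n, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0)
            tree = upgma(DistanceMatrix([f"x{i}" for i in range(n)], d))
            heights = []

            def depth(node, acc):
                if node.is_tip():
                    heights.append(acc)
                for ch in node.children:
                    depth(ch, acc + (ch.length or 0))

            depth(tree, 0.0)
            assert max(heights) - min(heights) < 1e-9  # ultrametric output


class TestRooting:
    def test_outgroup_becomes_sister_of_everything_else(self):
        rng = np.random.default_rng(6)
        labels = ["ARR22", "r1", "r2", "r3", "r4"]
        edges, n_nodes = random_additive_tree(rng, labels)
        d = path_distance_matrix(edges, 5, n_nodes)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        rooted = root_on_outgroup(tree, "ARR22")
        children = rooted.children
        assert len(children) == 2
        sides = [sorted(t.name for t in ch.tips(include_self=True))
                 for ch in children]
        assert ["ARR22"] in sides

    def test_three_leaf_bipartition(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        rooted = root_on_outgroup(tree, "A")
        sides = [sorted(t.name for t in ch.tips(include_self=True))
                 for ch in rooted.children]
        assert ["A"] in sides and ["B", "C"] in sides

    def test_pendant_edge_split_at_midpoint(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        pendant = tree.find("A").length
        rooted = root_on_outgroup(tree, "A")
        assert rooted.find("A").length == pytest.approx(pendant / 2)

    def test_leaf_set_conserved(self):
        d = np.array([[0, 2, 3, 4], [2, 0, 3, 4], [3, 3, 0, 4],
                      [4, 4, 4, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        rooted = root_on_outgroup(tree, "D")
        assert sorted(t.name for t in rooted.tips()) == list("ABCD")

    def test_missing_outgroup_rejected(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        with pytest.raises(ValueError):
            root_on_outgroup(tree, "Z")


class TestVariantClade:
    def test_divergent_variant_pair_forms_one_clade(self, refs):
        # two phosphoacceptor-substituted proteins descended from a common
        # diverged ancestor must group together in the family tree, the
        # topology-level signature of a variant-specific clade
        import numpy as np

        from tcskit.align import progressive_msa
        from tcskit.seqio import ProteinRecord
        from tcskit.synthetic import generate_family

        proteins, _, _ = generate_family(6, "HPT", 0.0, divergence=0.06,
                                         seed=41)
        rng = np.random.default_rng(43)
        base = list(refs["MtHPT3_SYN"].sequence)
        aa = "ACEFGIKLMPQRSTVWY"
        for i in range(len(base)):  # common divergent ancestor
            if (i + 1) != 77 and rng.random() < 0.3:
                base[i] = aa[rng.integers(0, len(aa))]
        variants = []
        for k in range(2):
            seq = list(base)
            seq[76] = "R"  # the shared phosphoacceptor substitution
            for i in range(len(seq)):
                if (i + 1) != 77 and rng.random() < 0.03:
                    seq[i] = aa[rng.integers(0, len(aa))]
            variants.append(ProteinRecord(f"HPTX{k + 1}", "".join(seq)))
        records = proteins + variants
        msa = progressive_msa(records)
        tree = neighbor_joining(protein_distance(msa))
        rooted = root_on_outgroup(tree, records[0].id)
        variant_tips = {"HPTX1", "HPTX2"}
        clades = [set(t.name for t in node.tips())
                  for node in rooted.traverse()]
        assert variant_tips in clades
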