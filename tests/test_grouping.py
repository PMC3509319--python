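"""UPGMA clustering, robust blocks, group identity statistics, bootstrap
support, and conservation-zone segmentation."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from slacq.grouping import (
    Block,
    DistanceMatrix,
    GroupingError,
    bootstrap_support,
    conservation_zones,
    conserved_blocks,
    cut_to_clusters,
    group_identity_stats,
    identity_distance_matrix,
    upgma,
)
from slacq.sequences import MultipleAlignment, ProteinSequence
from slacq.trees import is_ultrametric, rf_distance, write_newick


def dm(ids, rows):
    return DistanceMatrix(ids=ids, matrix=np.array(rows, float))


class TestDistanceMatrix:
    def test_identical_sequences_distance_zero(self):
        aln = MultipleAlignment(records=[("a", "MKV"), ("b", "MKV")])
        D = identity_distance_matrix(aln)
        assert D.matrix[0, 1] == 0.0

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        AA = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [
            ProteinSequence(id=f"s{i}",
                            residues="".join(AA[j] for j in rng.integers(0, 20, 30)))
            for i in range(5)
        ]
        D = identity_distance_matrix(seqs)
        assert np.allclose(D.matrix, D.matrix.T)
        assert np.all(np.diag(D.matrix) == 0)

    def test_hand_counted_aligned_trio(self):
        # a vs b: 3 matches / 4 used cols; a vs c: 2/4; b vs c: 2/5 of used 4?
        aln = MultipleAlignment(records=[
            ("a", "MKV-A"),
            ("b", "MKVLA"),
            ("c", "MK-LA"),
        ])
        D = identity_distance_matrix(aln)
        # a,b: cols 1,2,3,5 match, col 4 gap-vs-L counts, used 5 -> 4/5
        assert D.matrix[0, 1] == pytest.approx(100 - 100 * 4 / 5)
        # a,c: matches M,K,A; used cols 1,2,3(V vs -),4(- vs L),5 -> 3/5
        assert D.matrix[0, 2] == pytest.approx(100 - 100 * 3 / 5)
        # b,c: matches M,K,L,A over used 5 -> 4/5
        assert D.matrix[1, 2] == pytest.approx(100 - 100 * 4 / 5)


class TestUpgma:
    def test_two_taxa_cherry_at_half_distance(self):
        tree = upgma(dm(["a", "b"], [[0, 4], [4, 0]]))
        assert tree.root.height == 2.0
        assert sorted(tree.leaf_labels()) == ["a", "b"]

    def test_hand_executed_four_taxon_recurrence(self):
        D = dm(["a", "b", "c", "d"], [
            [0, 2, 4, 6],
            [2, 0, 4, 6],
            [4, 4, 0, 6],
            [6, 6, 6, 0],
        ])
        tree = upgma(D)
        assert write_newick(tree, lengths=False) == "(((a,b),c),d);"
        heights = sorted(n.height for n in tree.internal_nodes())
        assert heights == [1.0, 2.0, 3.0]

    def test_output_ultrametric_and_recovers_generating_tree(self):
        """On distances read off a random ultrametric tree, UPGMA returns
        that tree exactly (RF = 0)."""
        from slacq.synth import simulate_species_tree

        for seed in range(4):
            true = simulate_species_tree(8, seed=seed)
            # cophenetic distances: 2 * MRCA height
            labels = true.leaf_labels()
            clades = true.clades()
            n = len(labels)
            M = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    pair = {labels[i], labels[j]}
                    h = min(
                        (node.height for node in true.postorder()
                         if pair <= clades[id(node)]),
                    )
                    M[i, j] = M[j, i] = 2 * h
            rec = upgma(DistanceMatrix(ids=labels, matrix=M))
            assert is_ultrametric(rec)
            assert rf_distance(true, rec) == 0

    def test_agrees_with_scipy_average_linkage(self):
        """Merge heights match scipy's UPGMA (cophenetic distance / 2)."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 6
            a = rng.random((n, n)) * 100
            M = (a + a.T) / 2
            np.fill_diagonal(M, 0.0)
            tree = upgma(DistanceMatrix(ids=[f"t{i}" for i in range(n)], matrix=M))
            Z = average(squareform(M, checks=False))
            ours = sorted(node.height for node in tree.internal_nodes())
            scipys = sorted(Z[:, 2] / 2)
            assert np.allclose(ours, scipys)

    def test_heights_nondecreasing_along_merges(self):
        rng = np.random.default_rng(9)
        a = rng.random((7, 7)) * 50
        M = (a + a.T) / 2
        np.fill_diagonal(M, 0)
        tree = upgma(DistanceMatrix(ids=[f"t{i}" for i in range(7)], matrix=M))
        for node in tree.internal_nodes():
            for c in node.children:
                if not c.is_leaf:
                    assert node.height >= c.height - 1e-12


class TestCutToClusters:
    def test_three_planted_tiers_recovered(self, slac_bundle):
        from sklearn.metrics import adjusted_rand_score

        tree = upgma(identity_distance_matrix(slac_bundle.alignment))
        assign = cut_to_clusters(tree, 3)
        ids = sorted(slac_bundle.groups)
        ari = adjusted_rand_score(
            [slac_bundle.groups[i] for i in ids], [assign[i] for i in ids]
        )
        assert ari == 1.0


class TestConservedBlocks:
    def test_fully_conserved_alignment_single_block(self):
        aln = MultipleAlignment(records=[(f"s{i}", "MKVLAWEP") for i in range(4)])
        assert conserved_blocks(aln) == [Block(1, 8)]

    def test_single_bad_column_splits_blocks(self):
        rows = []
        for i, mid in enumerate("ACDE"):
            rows.append((f"s{i}", "MKVLA" + mid + "WEPKR"))
        aln = MultipleAlignment(records=rows)
        blocks = conserved_blocks(aln, min_ident_frac=0.5, min_block_len=2)
        assert blocks == [Block(1, 5), Block(7, 11)]

    def test_gappy_column_never_in_block(self):
        rows = [(f"s{i}", "MK-VLA") if i < 3 else (f"s{i}", "MKCVLA")
                for i in range(4)]
        aln = MultipleAlignment(records=rows)
        for b in conserved_blocks(aln, min_block_len=1, max_gap_frac=0.5):
            assert not (b.start_col <= 3 <= b.end_col)

    def test_raising_identity_threshold_never_enlarges_blocks(self, slac_bundle):
        aln = slac_bundle.alignment
        loose = conserved_blocks(aln, min_ident_frac=0.4)
        strict = conserved_blocks(aln, min_ident_frac=0.8)
        loose_cols = {c for b in loose for c in range(b.start_col, b.end_col + 1)}
        strict_cols = {c for b in strict for c in range(b.start_col, b.end_col + 1)}
        assert strict_cols <= loose_cols


class TestGroupIdentityStats:
    def test_identical_group_mean_100_sd_0(self):
        seqs = [ProteinSequence(id=f"s{i}", residues="MKVLAWEP") for i in range(3)]
        stats = group_identity_stats(seqs, {f"s{i}": "g" for i in range(3)})
        assert stats.within["g"].mean == 100.0
        assert stats.within["g"].sd == 0.0
        assert stats.within["g"].n_pairs == 3

    def test_hand_computed_two_groups(self):
        aln = MultipleAlignment(records=[
            ("a1", "MKVL"), ("a2", "MKVA"),  # within: 3/4
            ("b1", "HHNQ"), ("b2", "HHNE"),  # within: 3/4
        ])
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        stats = group_identity_stats(aln, groups)
        assert stats.within["A"].mean == pytest.approx(75.0)
        assert stats.within["B"].mean == pytest.approx(75.0)
        assert stats.between[("A", "B")].mean == pytest.approx(0.0)
        assert stats.between[("A", "B")].n_pairs == 4

    def test_singleton_group_flagged(self):
        seqs = [ProteinSequence(id="a", residues="MKVL"),
                ProteinSequence(id="b", residues="MKVA"),
                ProteinSequence(id="c", residues="HHNQ")]
        stats = group_identity_stats(seqs, {"a": "g1", "b": "g1", "c": "solo"})
        assert stats.within["solo"] is None

    def test_invariant_under_member_reordering(self):
        aln = MultipleAlignment(records=[
            ("a1", "MKVL"), ("a2", "MKVA"), ("b1", "HHNQ"), ("b2", "HHNE"),
        ])
        g1 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        s1 = group_identity_stats(aln, g1)
        g2 = dict(reversed(list(g1.items())))
        s2 = group_identity_stats(aln, g2)
        assert s1.within["A"].mean == s2.within["A"].mean
        assert s1.between[("A", "B")].mean == s2.between[("A", "B")].mean


class TestBootstrap:
    def _two_clade_alignment(self):
        rows = []
        for i in range(4):
            rows.append((f"x{i}", "MKVLAWEPKRIL" * 3))
        for i in range(4):
            rows.append((f"y{i}", "HHNQDYGGSTNN" * 3))
        # mild within-clade variation so distances are informative
        rows[1] = ("x1", "MKVLAWEPKRIA" + "MKVLAWEPKRIL" * 2)
        rows[5] = ("y1", "HHNQDYGGSTNA" + "HHNQDYGGSTNN" * 2)
        return MultipleAlignment(records=rows)

    def test_clean_signal_gives_full_support(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=25, seed=0)
        clades = tree.clades()
        for node in tree.internal_nodes():
            if clades[id(node)] == frozenset({"x0", "x1", "x2", "x3"}):
                assert node.support == 1.0
            if clades[id(node)] == frozenset({"y0", "y1", "y2", "y3"}):
                assert node.support == 1.0

    def test_single_replicate_supports_are_binary(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=1, seed=3)
        for node in tree.internal_nodes():
            assert node.support in (0.0, 1.0)

    def test_supports_in_unit_interval_and_leaf_order_invariant(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_support(aln, n_reps=10, seed=5)
        aln_rev = MultipleAlignment(records=list(reversed(aln.records)))
        t2 = bootstrap_support(aln_rev, n_reps=10, seed=5)
        c1 = {t1.clades()[id(n)]: n.support for n in t1.internal_nodes()}
        c2 = {t2.clades()[id(n)]: n.support for n in t2.internal_nodes()}
        for clade, support in c1.items():
            assert 0.0 <= support <= 1.0
            if clade in c2:
                assert c2[clade] == support


class TestConservationZones:
    def test_uniform_conservation_single_zone(self):
        aln = MultipleAlignment(records=[(f"s{i}", "MKVLAWEP") for i in range(4)])
        zones = conservation_zones(aln, window=3, threshold=0.5)
        assert len(zones) == 1
        assert zones[0].label == "high"

    def test_planted_alternation_recovered(self):
        # 20 conserved + 20 scrambled + 20 conserved columns
        rng = np.random.default_rng(0)
        AA = "ACDEFGHIKLMNPQRSTVWY"
        cons1 = "MKVLAWEPKRILVAEQHNQD"
        cons2 = "YGGSTNNQDYMKVLAWEPKR"
        rows = []
        for i in range(6):
            noise = "".join(AA[j] for j in rng.integers(0, 20, 20))
            rows.append((f"s{i}", cons1 + noise + cons2))
        aln = MultipleAlignment(records=rows)
        zones = conservation_zones(aln, window=5, threshold=0.5)
        assert [z.label for z in zones] == ["high", "low", "high"]
        assert abs(zones[0].end_col - 20) <= 3
        assert abs(zones[1].end_col - 40) <= 3

    def test_labels_strictly_alternate(self, slac_bundle):
        zones = conservation_zones(slac_bundle.alignment, window=9, threshold=0.6)
        for a, b in zip(zones, zones[1:]):
            assert a.label != b.label
            assert b.start_col == a.end_col + 1
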