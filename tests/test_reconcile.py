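"""LCA reconciliation against a min-cost embedding dynamic program, and
duplication+loss rooting against exhaustive edge enumeration."""

import itertools

import numpy as np
import pytest

from slacq.reconcile import (
    ReconcileError,
    annotate_duplication_history,
    lca_reconcile,
    root_min_dl,
)
from slacq.synth import (
    EmptyFamilyError,
    simulate_gene_family,
    simulate_species_tree,
    true_duplication_count,
)
from slacq.trees import read_newick, write_newick

from oracles import min_dl_embedding_cost

SP_AB = read_newick("(A,B);")


class TestLcaReconcile:
    def test_congruent_tree_no_events(self):
        gene = read_newick("((A1,B1),C1);")
        species = read_newick("((A,B),C);")
        rec = lca_reconcile(gene, species, {"A1": "A", "B1": "B", "C1": "C"})
        assert rec.duplication_count == 0
        assert rec.loss_count == 0

    def test_quartet_single_root_duplication(self):
        gene = read_newick("((A1,B1),(A2,B2));")
        rec = lca_reconcile(gene, SP_AB, {"A1": "A", "B1": "B", "A2": "A", "B2": "B"})
        assert rec.duplication_count == 1
        assert rec.loss_count == 0
        assert rec.node_map[id(rec.duplication_nodes[0])] is rec.species_tree.root

    def test_triplet_duplication_with_one_loss(self):
        gene = read_newick("((A1,B1),A2);")
        rec = lca_reconcile(gene, SP_AB, {"A1": "A", "B1": "B", "A2": "A"})
        assert rec.duplication_count == 1
        assert rec.loss_count == 1

    def test_unmapped_leaf_named_in_error(self):
        gene = read_newick("(A1,B1);")
        with pytest.raises(ReconcileError, match="B1"):
            lca_reconcile(gene, SP_AB, {"A1": "A"})

    def test_polytomy_rejected(self):
        gene = read_newick("(A1,B1,A2);")
        with pytest.raises(ReconcileError, match="polytomy"):
            lca_reconcile(gene, SP_AB, {"A1": "A", "B1": "B", "A2": "A"})

    def test_cost_matches_embedding_dp_on_random_small_trees(self):
        """D+L equals the independent min-cost embedding DP for all random
        gene/species pairs with <= 6 leaves."""
        rng = np.random.default_rng(0)
        checked = 0
        for sp_seed in range(6):
            n_sp = int(rng.integers(2, 5))
            species = simulate_species_tree(n_sp, seed=sp_seed)
            for g_seed in range(8):
                try:
                    gene, _, smap = simulate_gene_family(
                        species, dup_rate=0.6, loss_rate=0.4, seed=g_seed
                    )
                except EmptyFamilyError:
                    continue
                if not (2 <= len(gene.leaves()) <= 6):
                    continue
                rec = lca_reconcile(gene, species, smap)
                oracle = min_dl_embedding_cost(gene, species, smap)
                assert rec.dl_cost == oracle, write_newick(gene)
                checked += 1
        assert checked >= 10

    def test_speciation_everywhere_iff_no_duplications(self):
        gene = read_newick("((A1,B1),C1);")
        species = read_newick("((A,B),C);")
        rec = lca_reconcile(gene, species, {"A1": "A", "B1": "B", "C1": "C"})
        # D = 0 iff the children's images are disjoint at every internal node
        for v in gene.internal_nodes():
            images = [rec.node_map[id(c)] for c in v.children]
            assert images[0] is not images[1]


class TestRootMinDl:
    def test_congruent_unrooted_tree_recovers_zero_cost_rooting(self):
        gene = read_newick("(A1,B1,C1);")
        species = read_newick("((A,B),C);")
        results = root_min_dl(gene, species, {"A1": "A", "B1": "B", "C1": "C"})
        assert min(rec.dl_cost for _, rec in results) == 0

    def test_quartet_roots_on_central_edge(self):
        gene = read_newick("(A1,B1,(A2,B2));")
        results = root_min_dl(
            gene, SP_AB, {"A1": "A", "B1": "B", "A2": "A", "B2": "B"}
        )
        topologies = {write_newick(t, lengths=False) for t, _ in results}
        assert "((A1,B1),(A2,B2));" in topologies
        assert all(rec.dl_cost == 1 for _, rec in results)

    def test_optimum_not_beaten_by_any_dendropy_rerooting(self):
        """Exhaustive check via an independent rerooting path (dendropy)."""
        import dendropy

        species = simulate_species_tree(4, seed=2)
        for seed in range(6):
            try:
                gene, _, smap = simulate_gene_family(
                    species, dup_rate=0.5, loss_rate=0.3, seed=seed
                )
            except EmptyFamilyError:
                continue
            if not (3 <= len(gene.leaves()) <= 8):
                continue
            results = root_min_dl(gene, species, smap)
            best = results[0][1].dl_cost
            dtree = dendropy.Tree.get(data=write_newick(gene), schema="newick",
                                      preserve_underscores=True)
            for edge in list(dtree.preorder_edge_iter()):
                if edge.head_node is dtree.seed_node:
                    continue
                clone = dtree.clone(depth=1)
                target = None
                for e in clone.preorder_edge_iter():
                    if e.head_node.taxon and edge.head_node.taxon and \
                            e.head_node.taxon.label == edge.head_node.taxon.label:
                        target = e
                        break
                if target is None:
                    continue
                clone.reroot_at_edge(target, update_bipartitions=False)
                rerooted = read_newick(clone.as_string(schema="newick"))
                for n in rerooted.internal_nodes():
                    if len(n.children) != 2:
                        break
                else:
                    rec = lca_reconcile(rerooted, species, smap)
                    assert rec.dl_cost >= best


class TestDuplicationHistory:
    def test_single_duplication_event_at_species_root(self):
        gene = read_newick("((A1,B1),(A2,B2));")
        rec = lca_reconcile(gene, SP_AB, {"A1": "A", "B1": "B", "A2": "A", "B2": "B"})
        events = annotate_duplication_history(rec)
        assert len(events) == 1
        assert events[0].species_node == "lca(A,B)"
        assert {events[0].side_a, events[0].side_b} == {("A1", "B1"), ("A2", "B2")}

    def test_zero_duplication_gives_empty_table(self):
        gene = read_newick("((A1,B1),C1);")
        species = read_newick("((A,B),C);")
        rec = lca_reconcile(gene, species, {"A1": "A", "B1": "B", "C1": "C"})
        assert annotate_duplication_history(rec) == []

    def test_invariant_to_gene_child_order(self):
        g1 = read_newick("((A1,B1),(A2,B2));")
        g2 = read_newick("((A2,B2),(A1,B1));")
        smap = {"A1": "A", "B1": "B", "A2": "A", "B2": "B"}
        e1 = annotate_duplication_history(lca_reconcile(g1, SP_AB, smap))
        e2 = annotate_duplication_history(lca_reconcile(g2, SP_AB, smap))
        assert e1 == e2


class TestSimulatedFamilies:
    def test_loss_free_duplication_count_recovered_exactly(self):
        species = simulate_species_tree(8, seed=3)
        checked = 0
        for seed in range(8):
            try:
                gene, events, smap = simulate_gene_family(
                    species, dup_rate=0.3, loss_rate=0.0, seed=seed
                )
            except EmptyFamilyError:
                continue
            rec = lca_reconcile(gene, species, smap)
            assert rec.duplication_count == true_duplication_count(events)
            assert rec.loss_count == 0
            checked += 1
        assert checked >= 5

    def test_with_losses_inferred_never_exceeds_truth(self):
        species = simulate_species_tree(8, seed=3)
        for seed in range(12):
            try:
                gene, events, smap = simulate_gene_family(
                    species, dup_rate=0.4, loss_rate=0.3, seed=seed
                )
            except EmptyFamilyError:
                continue
            if len(gene.leaves()) < 2:
                continue
            rec = lca_reconcile(gene, species, smap)
            assert rec.duplication_count <= true_duplication_count(events)
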