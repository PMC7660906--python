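import itertools

import numpy as np
import pytest

from verticality import (
    GeneTree,
    TaxonMap,
    VerticalityRecord,
    aggregate_verticality,
    count_rooted_tree_topologies,
    distribution_correlation,
    gene_verticality,
    mad_root,
    mean_branch_length,
    score_tree,
    taxon_split_status,
    weighted_gene_verticality,
)
from verticality._unrooted import UnrootedView

from conftest import random_taxon_tree, random_tree
from oracles import oracle_is_monophyletic


def tm(assignments, totals=None):
    return TaxonMap(assignments=assignments, totals=totals or {})


class TestTaxonSplitStatus:
    def test_clean_split_both_monophyletic(self):
        gt = GeneTree.from_newick("((X1|a:1,X2|b:1):1,(Y1|c:1,Y2|d:1):1);")
        m = tm({"X1": "X", "X2": "X", "Y1": "Y", "Y2": "Y"})
        rep = taxon_split_status(gt, m)
        assert rep.statuses["X"].is_monophyletic
        assert rep.statuses["Y"].is_monophyletic
        assert rep.statuses["X"].n_subgroups == 1

    def test_interleaved_taxa_score_zero(self):
        gt = GeneTree.from_newick("((X1|a:1,Y1|c:1):1,(X2|b:1,Y2|d:1):1);")
        m = tm({"X1": "X", "X2": "X", "Y1": "Y", "Y2": "Y"})
        rep = taxon_split_status(gt, m)
        for taxon in "XY":
            assert not rep.statuses[taxon].is_monophyletic
            assert rep.statuses[taxon].n_subgroups == 2
            assert rep.statuses[taxon].score == 0.0

    def test_singleton_is_a_clade(self):
        gt = GeneTree.from_newick("((X1|a:1,X2|b:1):1,Y1|c:1);")
        m = tm({"X1": "X", "X2": "X", "Y1": "Y"}, {"X": 2, "Y": 4})
        rep = taxon_split_status(gt, m)
        assert rep.statuses["Y"].is_monophyletic
        assert rep.statuses["Y"].score == pytest.approx(1 / 4)

    def test_singleton_scoring_can_be_disabled(self):
        gt = GeneTree.from_newick("((X1|a:1,X2|b:1):1,Y1|c:1);")
        m = tm({"X1": "X", "X2": "X", "Y1": "Y"})
        rep = taxon_split_status(gt, m, score_singletons=False)
        assert rep.statuses["Y"].is_monophyletic
        assert rep.statuses["Y"].score == 0.0

    def test_unmapped_genome_is_an_error(self):
        gt = GeneTree.from_newick("((X1|a:1,X2|b:1):1,Z9|c:1);")
        with pytest.raises(KeyError, match="Z9"):
            taxon_split_status(gt, tm({"X1": "X", "X2": "X"}))

    def test_monophyly_at_sequence_level(self):
        """All sequences of a multi-copy taxon must fall on one side."""
        gt = GeneTree.from_newick(
            "((X1|a:1,(Y1|c:1,X1|b:1):1):1,Y2|d:1);"
        )
        m = tm({"X1": "X", "Y1": "Y", "Y2": "Y"})
        rep = taxon_split_status(gt, m)
        assert not rep.statuses["X"].is_monophyletic
        assert rep.statuses["X"].n_genomes == 1
        assert rep.statuses["X"].n_sequences == 2

    def test_oracle_agreement_on_random_trees(self, rng):
        """Monophyly equals the dendropy bipartition-enumeration oracle on
        200 random 30-leaf, 4-taxon trees."""
        for _ in range(200):
            gt, m, taxa = random_taxon_tree(rng, 30, 4)
            rep = taxon_split_status(gt, m)
            view = UnrootedView(gt)
            for taxon in taxa:
                leaves = frozenset(
                    l
                    for l in gt.leaf_labels()
                    if m.taxon_of(gt.genome_of_leaf(l)) == taxon
                )
                assert rep.statuses[taxon].is_monophyletic == \
                    oracle_is_monophyletic(gt, leaves), (gt.as_newick(), taxon)


class TestGeneVerticality:
    def test_formula_evaluation(self):
        gt = GeneTree.from_newick("((A1|a:1,A2|b:1):1,(B1|c:1,B2|d:1):1);")
        m = tm({"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
               {"A": 4, "B": 2})
        rec = gene_verticality(gt, m)
        assert rec.v_g == pytest.approx(2 / 4 + 2 / 2)

    def test_saturation_at_taxon_count(self):
        """k fully sampled monophyletic taxa give V_g = k, the maximum."""
        gt = GeneTree.from_newick(
            "(((A1|a:1,A2|b:1):1,(B1|c:1,B2|d:1):1):1,(C1|e:1,C2|f:1):1);"
        )
        m = tm({f"{t}{i}": t for t in "ABC" for i in (1, 2)})
        rec = gene_verticality(gt, m)
        assert rec.v_g == pytest.approx(3.0)
        assert rec.v_g <= rec.n_taxa_present

    def test_single_taxon_tree_flagged_excluded(self):
        gt = GeneTree.from_newick("((A1|a:1,A2|b:1):1,A3|c:1);")
        m = tm({"A1": "A", "A2": "A", "A3": "A"})
        rec = gene_verticality(gt, m)
        assert rec.excluded

    def test_vg_in_range_and_split_oracle(self, rng):
        """V_g equals an independent recomputation from oracle-tested
        splits, and stays within [0, taxa present]."""
        for _ in range(50):
            gt, m, taxa = random_taxon_tree(rng, 16, 3)
            rec = gene_verticality(gt, m, min_genomes=0, min_taxa=0)
            expected = 0.0
            for taxon in taxa:
                leaves = frozenset(
                    l
                    for l in gt.leaf_labels()
                    if m.taxon_of(gt.genome_of_leaf(l)) == taxon
                )
                if oracle_is_monophyletic(gt, leaves):
                    genomes = {gt.genome_of_leaf(l) for l in leaves}
                    expected += len(genomes) / m.totals[taxon]
            assert rec.v_g == pytest.approx(expected)
            assert 0 <= rec.v_g <= rec.n_taxa_present

    def test_invariant_under_rerooting(self, rng):
        """V_g is an unrooted-split property: rerooting cannot change it."""
        gt, m, _ = random_taxon_tree(rng, 12, 3)
        base = gene_verticality(gt, m, min_genomes=0, min_taxa=0).v_g
        for edge in list(gt.tree.preorder_edge_iter()):
            if edge.tail_node is None or edge.head_node.is_leaf():
                continue
            clone = gt.clone()
            target = [
                e for e in clone.tree.preorder_edge_iter()
                if e.tail_node is not None and not e.head_node.is_leaf()
            ][0]
            clone.tree.reroot_at_edge(target, length1=target.length / 2,
                                      length2=target.length / 2)
            assert gene_verticality(clone, m, min_genomes=0,
                                    min_taxa=0).v_g == pytest.approx(base)
            break


class TestWeightedVerticality:
    def test_m_times_depth(self):
        gt = GeneTree.from_newick(
            "((A1|a:0.25,A2|b:0.25):0.25,(B1|c:0.25,B2|d:0.25):0.25);"
        )
        m = tm({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        res = mad_root(gt)
        # 2 monophyletic taxa, clock depth 0.5
        assert weighted_gene_verticality(res.rooted_tree, m) == \
            pytest.approx(2 * 0.5)

    def test_no_monophyletic_taxon_gives_zero(self):
        gt = GeneTree.from_newick(
            "((A1|a:1,B1|c:1):1,(A2|b:1,B2|d:1):1);"
        )
        m = tm({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        res = mad_root(gt)
        assert weighted_gene_verticality(res.rooted_tree, m) == 0.0

    def test_unrooted_input_rejected(self):
        gt = GeneTree.from_newick("((A1|a:1,A2|b:1):1,B1|c:1);")
        m = tm({"A1": "A", "A2": "A", "B1": "B"})
        with pytest.raises(ValueError, match="rooted"):
            weighted_gene_verticality(gt, m)

    def test_equals_product_of_independent_parts(self, rng):
        from oracles import oracle_root_to_tip_mean

        for _ in range(20):
            gt, m, taxa = random_taxon_tree(rng, 10, 3)
            res = mad_root(gt)
            rep = taxon_split_status(gt, m)
            mcount = sum(
                1 for s in rep.statuses.values() if s.is_monophyletic
            )
            expected = mcount * oracle_root_to_tip_mean(res.rooted_tree)
            assert weighted_gene_verticality(res.rooted_tree, m) == \
                pytest.approx(expected, rel=1e-9)


class TestAggregation:
    def _scores(self):
        m = tm({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        g1 = GeneTree.from_newick(
            "((A1|a:1,A2|b:1):1,(B1|c:1,B2|d:1):1);", tree_id="t1")
        g2 = GeneTree.from_newick(
            "((A1|a:1,B1|c:1):1,(A2|b:1,B2|d:1):1);", tree_id="t2")
        return [score_tree(g, m, min_genomes=0, min_taxa=0) for g in (g1, g2)], m

    def test_p_mono_counts_trees(self):
        scores, m = self._scores()
        taxa, _ = aggregate_verticality(scores, m)
        by = {t.taxon: t for t in taxa}
        assert by["A"].p_mono == pytest.approx(0.5)  # mono in t1 only
        assert by["B"].p_mono == pytest.approx(0.5)
        assert by["A"].n_trees == 2

    def test_genome_average(self):
        scores, m = self._scores()
        _, genomes = aggregate_verticality(scores, m)
        by = {g.genome: g for g in genomes}
        v1 = scores[0].record.v_g
        v2 = scores[1].record.v_g
        assert by["A1"].v_g_avg == pytest.approx((v1 + v2) / 2)
        assert by["A1"].n_clusters == 2

    def test_signed_weighted_mean(self):
        m = tm({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        g1 = GeneTree.from_newick(
            "((A1|a:1,A2|b:1):1,(B1|c:1,B2|d:1):1);", tree_id="t1")
        g2 = GeneTree.from_newick(
            "((A1|a:1,B1|c:1):1,(A2|b:1,B2|d:1):1);", tree_id="t2")
        scores = []
        for g in (g1, g2):
            cs = score_tree(g, m, rooted=mad_root(g).rooted_tree,
                            min_genomes=0, min_taxa=0)
            scores.append(cs)
        taxa, _ = aggregate_verticality(scores, m)
        by = {t.taxon: t for t in taxa}
        vw1, vw2 = scores[0].record.v_w, scores[1].record.v_w
        assert by["A"].v_weighted == pytest.approx((vw1 - vw2) / 2)


class TestMeanBranchLength:
    def test_boundary_is_conserved(self):
        gt = GeneTree.from_newick("(A:0.1,B:0.1);")
        mean, conserved = mean_branch_length(gt)
        assert mean == pytest.approx(0.1)
        assert conserved

    def test_fast_tree_not_conserved(self):
        gt = GeneTree.from_newick("(A:0.2,B:0.4);")
        mean, conserved = mean_branch_length(gt)
        assert mean == pytest.approx(0.3)
        assert not conserved

    def test_matches_edge_sum_oracle(self, rng):
        for _ in range(20):
            gt = random_tree(rng, [f"L{i}" for i in range(8)])
            lengths = []
            for e in gt.tree.preorder_edge_iter():
                if e.tail_node is not None:
                    lengths.append(e.length or 0.0)
            mean, _ = mean_branch_length(gt)
            assert mean == pytest.approx(sum(lengths) / len(lengths))


class TestTopologyCount:
    def test_small_values(self):
        assert count_rooted_tree_topologies(2) == 1
        assert count_rooted_tree_topologies(3) == 3

    def test_n4_matches_exhaustive_enumeration(self):
        """Enumerate all distinct labelled rooted binary shapes on 4
        leaves by recursive construction."""

        def shapes(labels):
            if len(labels) == 1:
                return {labels[0]}
            out = set()
            labels = sorted(labels)
            first = labels[0]
            for r in range(1, len(labels)):
                for left in itertools.combinations(labels[1:], r - 1):
                    lset = sorted((first,) + left)
                    rset = sorted(set(labels) - set(lset))
                    if not rset:
                        continue
                    for a in shapes(lset):
                        for b in shapes(rset):
                            out.add("(" + ",".join(sorted((a, b))) + ")")
            return out

        assert len(shapes(["a", "b", "c", "d"])) == 15
        assert count_rooted_tree_topologies(4) == 15

    def test_52_leaves_rounds_to_3e80(self):
        v = count_rooted_tree_topologies(52)
        exponent = len(str(v)) - 1
        assert exponent == 80
        assert round(v / 10**exponent) == 3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            count_rooted_tree_topologies(1)


class TestDistributionCorrelation:
    @staticmethod
    def _records(vs, ns):
        return [
            VerticalityRecord(
                cluster_id=f"c{i}", v_g=v, n_genomes=n, n_taxa_present=2,
                mean_branch_length=0.1, conserved=True,
            )
            for i, (v, n) in enumerate(zip(vs, ns))
        ]

    def test_perfect_line(self):
        recs = self._records([1, 2, 3, 4], [10, 20, 30, 40])
        r, r2, p = distribution_correlation(recs)
        assert r2 == pytest.approx(1.0)

    def test_anti_linear_is_negative(self):
        recs = self._records([4, 3, 2, 1], [10, 20, 30, 40])
        r, _, _ = distribution_correlation(recs)
        assert r < 0

    def test_zero_variance_rejected(self):
        recs = self._records([1, 1, 1], [10, 20, 30])
        with pytest.raises(ValueError, match="variance"):
            distribution_correlation(recs)
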