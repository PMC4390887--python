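"""Monophyly, rank collapsing, convergence statistics, lineage rules."""

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from cvtree import (
    InputError,
    ModificationRule,
    UsageError,
    apply_modification,
    collapse,
    convergence_report,
    is_monophyletic,
    rf_distance,
)
from cvtree.simulate import (
    inject_unclassified,
    lineages_from_tree,
    random_tree,
)

from .conftest import make_lineage


def tree_ab_cd():
    return TreeNode.read(["((A:1.0,B:1.0):0.5,(C:1.0,D:1.0):0.5);"])


class TestMonophyly:
    def test_bipartition_side_is_monophyletic(self):
        assert is_monophyletic(tree_ab_cd(), {"A", "B"})

    def test_crossing_set_is_not(self):
        assert not is_monophyletic(tree_ab_cd(), {"A", "C"})

    def test_singletons_and_full_set_trivially_monophyletic(self):
        t = tree_ab_cd()
        assert is_monophyletic(t, {"C"})
        assert is_monophyletic(t, {"A", "B", "C", "D"})

    def test_unknown_leaf_rejected(self):
        with pytest.raises(UsageError):
            is_monophyletic(tree_ab_cd(), {"A", "Z"})

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("n", [6, 9])
    def test_agrees_with_edge_enumeration_on_all_subsets(self, n, seed):
        """Exhaustive check against a direct per-edge oracle."""
        tree = random_tree(n, seed)
        leaves = sorted(t.name for t in tree.tips())
        # oracle: a set is monophyletic iff it is a side of some edge,
        # computed by enumerating every edge's two sides explicitly
        edge_sides = set()
        full = frozenset(leaves)
        for node in tree.traverse(include_self=False):
            if node.is_tip():
                s = frozenset([node.name])
            else:
                s = frozenset(t.name for t in node.tips())
            edge_sides.add(s)
            edge_sides.add(full - s)
        for r in range(1, n + 1):
            for subset in itertools.combinations(leaves, r):
                fs = frozenset(subset)
                expect = len(fs) == 1 or fs == full or fs in edge_sides
                assert is_monophyletic(tree, set(fs)) == expect


class TestCollapse:
    def lineages_xxyy(self, x2_class="X"):
        return {
            "x1": make_lineage(C="X", S="s1"),
            "x2": make_lineage(C=x2_class, S="s2"),
            "y1": make_lineage(C="Y", S="s3"),
            "y2": make_lineage(C="Y", S="s4"),
        }

    def test_two_clean_classes_collapse_to_two_leaves(self):
        t = TreeNode.read(["((x1:1.0,x2:1.0):0.5,(y1:1.0,y2:1.0):0.5);"])
        ctree, recs = collapse(t, self.lineages_xxyy(), "C")
        labels = sorted(r.label() for r in recs)
        assert labels == ["<C>X{2}", "<C>Y{2}"]
        assert ctree.count(tips=True) == 2

    def test_nested_unclassified_absorbed_with_m_plus_n(self):
        t = TreeNode.read(["((x1:1.0,x2:1.0):0.5,(y1:1.0,y2:1.0):0.5);"])
        lin = self.lineages_xxyy(x2_class="Unclassified")
        # x2 must be fully incomplete for {m+n} bookkeeping
        lin["x2"] = make_lineage(C="Unclassified", G="Unclassified", S="Unclassified")
        ctree, recs = collapse(t, lin, "C")
        labels = sorted(r.label() for r in recs)
        assert "<C>X{1+1}" in labels

    def test_paraphyletic_taxon_yields_split_parts(self):
        t = TreeNode.read(["((x1:1.0,y1:1.0):0.5,(x2:1.0,y2:1.0):0.5);"])
        lin = {
            "x1": make_lineage(C="X", S="s1"),
            "x2": make_lineage(C="X", S="s2"),
            "y1": make_lineage(C="Y", S="s3"),
            "y2": make_lineage(C="Y", S="s4"),
        }
        _, recs = collapse(t, lin, "C")
        assert sorted(r.label() for r in recs) == [
            "<C>X{1/2}", "<C>X{1/2}", "<C>Y{1/2}", "<C>Y{1/2}",
        ]

    def test_all_unclassified_branch_falls_back_to_shared_parent_rank(self):
        # two classified classes keep the root unmergeable, so the
        # all-unclassified cluster stands alone and is labeled at the
        # deepest shared classified rank (here the phylum)
        t = TreeNode.read(
            ["((u1:1.0,u2:1.0):0.5,((y1:1.0,y2:1.0):0.5,(z1:1.0,z2:1.0):0.5):0.2);"]
        )
        lin = {
            "u1": make_lineage(P="Eury", C="Unclassified", S="Unclassified"),
            "u2": make_lineage(P="Eury", C="Unclassified", G="Unclassified",
                               S="Unclassified"),
            "y1": make_lineage(P="Eury", C="Y", S="s3"),
            "y2": make_lineage(P="Eury", C="Y", S="s4"),
            "z1": make_lineage(P="Eury", C="Z", S="s5"),
            "z2": make_lineage(P="Eury", C="Z", S="s6"),
        }
        _, recs = collapse(t, lin, "C")
        labels = sorted(r.label() for r in recs)
        assert labels == ["<C>Y{2}", "<C>Z{2}", "<P>Eury{0+2}"]

    def test_missing_lineage_is_error(self):
        t = tree_ab_cd()
        with pytest.raises(InputError):
            collapse(t, {"A": make_lineage()}, "C")

    @pytest.mark.parametrize("frac", [0.0, 0.3, 1.0])
    @pytest.mark.parametrize("seed", [3, 4])
    def test_leaf_accounting_conserved(self, seed, frac):
        """Sum of branch sizes (k or m, plus n) equals the leaf count."""
        tree = random_tree(10, seed)
        lin = lineages_from_tree(tree)
        lin = inject_unclassified(lin, frac, seed)
        for rank in "DPCOFG":
            _, recs = collapse(tree, lin, rank)
            covered = sum((r.k if r.k is not None else r.m) + r.n for r in recs)
            assert covered == 10

    def test_collapse_at_domain_of_uniform_tree_is_single_leaf(self):
        tree = random_tree(6, 0)
        lin = lineages_from_tree(tree)
        ctree, recs = collapse(tree, lin, "D")
        assert len(recs) == 1
        assert recs[0].label() == "<D>SimDomain{6}"
        assert ctree.is_tip() and ctree.name == "<D>SimDomain{6}"


class TestConvergenceReport:
    def test_flags_match_direct_monophyly_calls(self):
        tree5 = random_tree(10, 5)
        tree6 = random_tree(10, 6)  # different topology
        lin = lineages_from_tree(tree5)
        rep = convergence_report({5: tree5, 6: tree6}, lin)
        for row in rep.rows:
            members = {
                g for g, l in lin.items()
                if l.complete and l.name_at(row.rank_code) == row.taxon_name
            }
            assert row.size == len(members)
            assert row.flags[5] == is_monophyletic(tree5, members)
            assert row.flags[6] == is_monophyletic(tree6, members)

    def test_truth_lineages_fully_monophyletic_on_truth_tree(self):
        tree = random_tree(8, 2)
        rep = convergence_report({5: tree, 6: tree}, lineages_from_tree(tree))
        assert rep.rows, "report should not be empty"
        for row in rep.rows:
            assert all(row.flags.values())

    def test_rendered_line_format(self):
        tree = random_tree(5, 1)
        lin = lineages_from_tree(tree)
        rep = convergence_report({K: tree for K in range(3, 8)}, lin)
        line = rep.row("D", "SimDomain").render()
        assert line == "<D>SimDomain{5} K3 K4 K5 K6 K7"

    def test_incomplete_lineages_excluded_from_sizes(self):
        tree = random_tree(8, 3)
        lin = inject_unclassified(lineages_from_tree(tree), 1.0, 1)
        rep = convergence_report({5: tree}, lin)
        assert rep.rows == []

    def test_leaf_order_permutation_invariance(self):
        tree = random_tree(9, 4)
        lin = lineages_from_tree(tree)
        shuffled = tree.copy()
        for node in shuffled.non_tips(include_self=True):
            node.children.reverse()
        r1 = convergence_report({5: tree}, lin)
        r2 = convergence_report({5: shuffled}, lin)
        assert r1.render() == r2.render()

    def test_leafset_mismatch_rejected(self):
        t1, t2 = random_tree(6, 1), random_tree(7, 1)
        with pytest.raises(UsageError):
            convergence_report({5: t1, 6: t2}, lineages_from_tree(t1))


class TestModification:
    def lineages(self):
        return {
            "cald": make_lineage(P="Thaumarchaeota", G="Caldiarchaeum", S="cs"),
            "thaum1": make_lineage(P="Thaumarchaeota", G="Nitrosopumilus", S="np"),
            "thaum2": make_lineage(P="Thaumarchaeota", G="Cenarchaeum", S="ce"),
        }

    def test_reassignment_restores_monophyly(self):
        # caldiarchaeum is the outlier inside an otherwise clean phylum;
        # two outgroup leaves keep its set from being a trivial complement
        tree = TreeNode.read(
            ["((thaum1:1.0,thaum2:1.0):0.5,"
             "((cald:1.0,other1:1.0):0.5,other2:1.0):0.5);"]
        )
        lin = self.lineages()
        lin["other1"] = make_lineage(P="Crenarchaeota", S="o1")
        lin["other2"] = make_lineage(P="Crenarchaeota", S="o2")
        members = lambda l, name: {
            g for g, x in l.items() if x.name_at("P") == name
        }
        assert not is_monophyletic(tree, members(lin, "Thaumarchaeota"))
        rule = ModificationRule.parse(
            "<P>Thaumarchaeota<G>Caldiarchaeum <P>Aigarchaeota<G>Caldiarchaeum"
        )
        new, changed = apply_modification(lin, rule)
        assert changed == 1
        assert new["cald"].name_at("P") == "Aigarchaeota"
        assert is_monophyletic(tree, members(new, "Thaumarchaeota"))
        assert is_monophyletic(tree, members(new, "Aigarchaeota"))

    def test_zero_matches_is_error(self):
        rule = ModificationRule.parse("<P>Nope<G>Caldiarchaeum <P>X<G>Caldiarchaeum")
        with pytest.raises(InputError, match="not recognizable"):
            apply_modification(self.lineages(), rule)

    def test_rule_then_inverse_is_identity(self):
        lin = self.lineages()
        rule = ModificationRule.parse(
            "<P>Thaumarchaeota<G>Caldiarchaeum <P>Aigarchaeota<G>Caldiarchaeum"
        )
        once, _ = apply_modification(lin, rule)
        back, _ = apply_modification(once, rule.inverse())
        assert back == lin

    def test_mismatched_rank_sets_rejected(self):
        with pytest.raises(UsageError):
            ModificationRule.parse("<P>A<G>B <C>X<G>B")

    def test_modification_never_touches_tree_topology(self):
        tree = random_tree(8, 9)
        lin = lineages_from_tree(tree)
        some_phylum = lin[next(iter(lin))].name_at("P")
        rule = ModificationRule.parse(f"<P>{some_phylum} <P>Renamed")
        new, changed = apply_modification(lin, rule)
        assert changed >= 1
        assert rf_distance(tree, tree.copy()) == 0  # tree untouched by design
        # re-collapse uses the same topology, only labels change
        _, recs_old = collapse(tree, lin, "P")
        _, recs_new = collapse(tree, new, "P")
        assert len(recs_old) == len(recs_new)
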