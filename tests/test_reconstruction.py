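import numpy as np
import pandas as pd
import pytest

from cade import (
    CodedMatrix,
    Tree,
    acctran_assignment,
    change_summary,
    changes_of,
    deltran_assignment,
    fitch_steps,
    mpr_state_sets,
    tree_length,
)
from cade.reconstruction import strict_unambiguous_changes

from conftest import (
    oracle_assignment_cost,
    oracle_mprs,
    random_coded_matrix,
    random_rooted_tree,
)


def _char(tree, present):
    return {lab: int(lab in present) for lab in tree.leaf_labels()}


def _named_changes(changes):
    return sorted(("+".join(sorted(n.leaf_labels())), d) for n, d in changes)


class TestMprStateSets:
    def test_clean_clade_all_singletons(self, five_leaf_tree):
        sets = mpr_state_sets(five_leaf_tree, _char(five_leaf_tree, {"A", "B"}))
        assert all(len(s) == 1 for s in sets.values())

    def test_all_zero_character(self, five_leaf_tree):
        sets = mpr_state_sets(five_leaf_tree, _char(five_leaf_tree, set()))
        assert all(s == frozenset([0]) for s in sets.values())

    def test_scattered_character_unique_mpr(self, five_leaf_tree):
        # oracle: the {A, D} character has a single MPR assigning 0 everywhere
        char = _char(five_leaf_tree, {"A", "D"})
        best, mprs = oracle_mprs(five_leaf_tree, char)
        assert best == 2 and len(mprs) == 1
        sets = mpr_state_sets(five_leaf_tree, char)
        for node in five_leaf_tree.internal_nodes():
            assert sets[node] == frozenset([0])

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 11))
            tree = random_rooted_tree([f"A{i}" for i in range(n - 1)] + ["ROOT"], rng)
            tree = tree.rerooted_on_leaf("ROOT")
            present = {f"A{i}" for i in range(n - 1) if rng.random() < 0.4}
            char = _char(tree, present)
            _, mprs = oracle_mprs(tree, char)
            expected = {
                node: frozenset(a[node] for a in mprs)
                for node in tree.internal_nodes()
            }
            got = mpr_state_sets(tree, char)
            for node in tree.internal_nodes():
                assert got[node] == expected[node]


class TestAcctranDeltran:
    def test_both_are_true_mprs_realizing_s(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 10))
            tree = random_rooted_tree([f"A{i}" for i in range(n - 1)] + ["ROOT"], rng)
            tree = tree.rerooted_on_leaf("ROOT")
            present = {f"A{i}" for i in range(n - 1) if rng.random() < 0.4}
            char = _char(tree, present)
            s, mprs = oracle_mprs(tree, char)
            for assign in (acctran_assignment(tree, char), deltran_assignment(tree, char)):
                assert oracle_assignment_cost(tree, assign) == s
                assert any(assign == m for m in mprs)
                assert len(changes_of(assign, tree)) == s

    def test_deltran_never_fewer_gains(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 10))
            tree = random_rooted_tree([f"A{i}" for i in range(n - 1)] + ["ROOT"], rng)
            tree = tree.rerooted_on_leaf("ROOT")
            present = {f"A{i}" for i in range(n - 1) if rng.random() < 0.5}
            char = _char(tree, present)
            acc_gains = sum(d == "gain" for _, d in changes_of(acctran_assignment(tree, char), tree))
            dlt_gains = sum(d == "gain" for _, d in changes_of(deltran_assignment(tree, char), tree))
            assert dlt_gains >= acc_gains

    def test_known_divergent_example(self):
        # single origin + reversal (ACCTRAN) vs two parallel gains (DELTRAN);
        # branch placements frozen from the oracle MPR enumeration
        tree = Tree.from_newick("((((A,B),C),D),ROOT);")
        char = _char(tree, {"A", "C"})
        acc = _named_changes(changes_of(acctran_assignment(tree, char), tree))
        dlt = _named_changes(changes_of(deltran_assignment(tree, char), tree))
        assert acc == [("A+B+C", "gain"), ("B", "loss")]
        assert dlt == [("A", "gain"), ("C", "gain")]

    def test_clean_clade_identical_reconstructions(self, five_leaf_tree):
        char = _char(five_leaf_tree, {"D", "E"})
        assert acctran_assignment(five_leaf_tree, char) == deltran_assignment(
            five_leaf_tree, char
        )

    def test_everywhere_but_root_single_gain_on_root_edge(self):
        tree = Tree.from_newick("(ROOT,((A,B),(C,D)));")
        char = _char(tree, {"A", "B", "C", "D"})
        for assign in (acctran_assignment(tree, char), deltran_assignment(tree, char)):
            changes = _named_changes(changes_of(assign, tree))
            assert changes == [("A+B+C+D", "gain")]


class TestChangeSummary:
    def test_totals_equal_tree_length(self, rng):
        m = random_coded_matrix(rng, n_areas=6, n_taxa=12)
        tree = random_rooted_tree(m.area_labels, rng).rerooted_on_leaf("ROOT")
        summary = change_summary(tree, m)
        length = tree_length(tree, m)
        assert summary.acctran_total == length
        assert summary.deltran_total == length

    def test_clean_matrix_no_ambiguity(self):
        df = pd.DataFrame(
            {"A": [1, 1], "B": [1, 1], "C": [0, 1], "D": [0, 0], "ROOT": [0, 0]},
            index=["cAB", "cABC"],
        )
        m = CodedMatrix(df, root_area="ROOT")
        tree = Tree.from_newick("((((A,B),C),D),ROOT);")
        summary = change_summary(tree, m)
        assert summary.unambiguous_gains == 2
        assert summary.unambiguous_losses == 0
        assert summary.acctran_ambiguous_gains == 0
        assert summary.deltran_ambiguous_gains == 0

    def test_branch_names_use_postorder_numbers(self):
        df = pd.DataFrame(
            {"A": [1], "B": [1], "C": [0], "D": [0], "ROOT": [0]}, index=["cAB"]
        )
        m = CodedMatrix(df, root_area="ROOT")
        tree = Tree.from_newick("((((A,B),C),D),ROOT);")
        summary = change_summary(tree, m)
        (record,) = summary.records
        assert "node" in record.branch and "->" in record.branch


def test_strict_unambiguous_subset_of_both(rng, five_leaf_tree):
    char = _char(five_leaf_tree, {"A", "B", "D"})
    strict = strict_unambiguous_changes(five_leaf_tree, char)
    acc = changes_of(acctran_assignment(five_leaf_tree, char), five_leaf_tree)
    dlt = changes_of(deltran_assignment(five_leaf_tree, char), five_leaf_tree)
    assert strict <= acc and strict <= dlt
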