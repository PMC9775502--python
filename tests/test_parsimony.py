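import numpy as np
import pandas as pd
import pytest

from cade import (
    CodedMatrix,
    Tree,
    ValidationError,
    branch_and_bound,
    enumerate_unrooted_topologies,
    exhaustive_search,
    fitch_steps,
    fitch_steps_per_character,
    n_unrooted_topologies,
    tree_length,
)

from conftest import oracle_steps, random_coded_matrix, random_rooted_tree


def _char(tree, present):
    return {lab: int(lab in present) for lab in tree.leaf_labels()}


class TestFitchSteps:
    def test_constant_character_is_free(self, five_leaf_tree):
        assert fitch_steps(five_leaf_tree, _char(five_leaf_tree, set())) == 0

    def test_single_origin(self, five_leaf_tree):
        assert fitch_steps(five_leaf_tree, _char(five_leaf_tree, {"A"})) == 1

    def test_two_disjoint_occurrences(self, five_leaf_tree):
        # frozen value computed with the exhaustive-assignment oracle
        char = _char(five_leaf_tree, {"A", "D"})
        assert oracle_steps(five_leaf_tree, char) == 2
        assert fitch_steps(five_leaf_tree, char) == 2

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 9))
            tree = random_rooted_tree([f"A{i}" for i in range(n)], rng)
            present = {f"A{i}" for i in range(n) if rng.random() < 0.4}
            char = _char(tree, present)
            assert fitch_steps(tree, char) == oracle_steps(tree, char)

    def test_invariant_under_rerooting(self, rng):
        labels = [f"A{i}" for i in range(7)]
        tree = random_rooted_tree(labels, rng)
        char = _char(tree, {"A0", "A3", "A5"})
        expected = fitch_steps(tree, char)
        for lab in labels:
            assert fitch_steps(tree.rerooted_on_leaf(lab), char) == expected

    def test_missing_leaf_state_rejected(self, five_leaf_tree):
        with pytest.raises(ValidationError):
            fitch_steps(five_leaf_tree, {"A": 1})


class TestTreeLength:
    def test_single_area_endemics_cost_their_count(self, rng):
        m = CodedMatrix(
            pd.DataFrame(np.eye(4, dtype=int), index=list("wxyz"), columns=list("ABCD"))
        )
        for _ in range(5):
            tree = random_rooted_tree(list("ABCD"), rng)
            assert tree_length(tree, m) == 4

    def test_equals_sum_of_per_character_oracle(self, rng):
        for _ in range(5):
            m = random_coded_matrix(rng, n_areas=6, n_taxa=8)
            tree = random_rooted_tree(m.area_labels, rng)
            per_char = fitch_steps_per_character(tree, m)
            expected = [
                oracle_steps(tree, {a: int(v) for a, v in zip(m.area_labels, m.row(t))})
                for t in m.taxon_labels
            ]
            assert list(per_char) == expected
            assert tree_length(tree, m) == sum(expected)

    def test_duplicate_character_adds_linearly(self, rng):
        m = random_coded_matrix(rng, n_areas=6, n_taxa=6)
        tree = random_rooted_tree(m.area_labels, rng)
        steps = fitch_steps_per_character(tree, m)
        df = pd.concat([m.data, m.data.iloc[[2]].set_axis(["dup"])])
        m2 = CodedMatrix(df, root_area=m.root_area)
        assert tree_length(tree, m2) == tree_length(tree, m) + int(steps[2])


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_topology_counts(self, n, count):
        trees = list(enumerate_unrooted_topologies(n))
        assert len(trees) == count
        # all distinct by bipartition set
        assert len({frozenset(t.bipartitions()) for t in trees}) == count

    def test_double_factorial_closed_form(self):
        assert n_unrooted_topologies(10) == 2_027_025

    def test_cap_refused(self):
        with pytest.raises(ValidationError, match="cap"):
            list(enumerate_unrooted_topologies(12))


class TestSearch:
    def test_perfectly_nested_matrix_recovers_its_tree(self):
        # characters = clades of ((((A,B),C),D),ROOT)
        df = pd.DataFrame(
            {
                "A": [1, 1, 1], "B": [1, 1, 1], "C": [0, 1, 1],
                "D": [0, 0, 1], "ROOT": [0, 0, 0],
            },
            index=["cAB", "cABC", "cABCD"],
        )
        m = CodedMatrix(df, root_area="ROOT")
        res = exhaustive_search(m)
        assert res.best_score == 3
        assert res.n_optimal == 1
        truth = Tree.from_newick("((((A,B),C),D),ROOT);")
        assert res.trees[0].same_topology(truth)

    def test_single_uninformative_character_all_topologies_tie(self):
        # a single-area endemic costs 1 step on every topology, so the search
        # must report the complete topology set as optimal
        df = pd.DataFrame(
            {"A": [1], "B": [0], "C": [0], "D": [0], "ROOT": [0]}, index=["c1"]
        )
        m = CodedMatrix(df, root_area="ROOT")
        res = exhaustive_search(m)
        assert res.best_score == 1
        assert res.n_optimal == n_unrooted_topologies(5)

    def test_branch_and_bound_matches_exhaustive(self, rng):
        for _ in range(30):
            m = random_coded_matrix(rng, n_areas=5, n_taxa=int(rng.integers(4, 12)))
            exh = exhaustive_search(m)
            bnb = branch_and_bound(m)
            assert bnb.best_score == exh.best_score
            assert {frozenset(t.bipartitions()) for t in bnb.trees} == {
                frozenset(t.bipartitions()) for t in exh.trees
            }

    def test_addition_order_does_not_change_result(self, rng):
        m = random_coded_matrix(rng, n_areas=6, n_taxa=10)
        a = branch_and_bound(m, addition_order="furthest")
        b = branch_and_bound(m, addition_order="as-is")
        assert a.best_score == b.best_score
        assert {frozenset(t.bipartitions()) for t in a.trees} == {
            frozenset(t.bipartitions()) for t in b.trees
        }

    def test_optimal_trees_are_rooted_on_hypothetical_area(self, rng):
        m = random_coded_matrix(rng, n_areas=5, n_taxa=8)
        res = branch_and_bound(m)
        for tree in res.trees:
            assert tree.is_binary
            assert "ROOT" in [c.label for c in tree.root.children if c.is_leaf]

    def test_score_at_least_number_of_variable_characters(self, rng):
        m = random_coded_matrix(rng, n_areas=6, n_taxa=12)
        n_variable = sum(1 for t in m.taxon_labels if 0 < m.row(t).sum() < m.n_areas)
        assert branch_and_bound(m).best_score >= n_variable
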