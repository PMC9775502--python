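import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from cade import (
    AreaTaxonMatrix,
    CodedMatrix,
    DissimilarityMatrix,
    ValidationError,
    beta_sim,
    beta_sor,
    cluster_bootstrap,
    dissimilarity_matrix,
    node_strength,
    upgma,
)
from cade.clustering import consensus_clades

from conftest import random_coded_matrix


def _matrix_from_sets(rows: dict, areas) -> AreaTaxonMatrix:
    areas = list(areas)
    df = pd.DataFrame(
        {a: [int(a in m) for m in rows.values()] for a in areas}, index=list(rows)
    )
    return AreaTaxonMatrix(df)


def _dist(values: dict, areas) -> DissimilarityMatrix:
    df = pd.DataFrame(0.0, index=areas, columns=areas)
    for (x, y), v in values.items():
        df.at[x, y] = df.at[y, x] = v
    return DissimilarityMatrix(df, "sor")


class TestCoefficients:
    def test_identical_composition_zero(self):
        m = _matrix_from_sets({"t1": "XY", "t2": "XY"}, "XY")
        assert beta_sor(m, "X", "Y") == 0
        assert beta_sim(m, "X", "Y") == 0

    def test_disjoint_composition_sor_one(self):
        m = _matrix_from_sets({"t1": "X", "t2": "Y"}, "XY")
        assert beta_sor(m, "X", "Y") == 1

    def test_sor_worked_example(self):
        # a=2 shared, b=1 only-X, c=1 only-Y -> (1+1)/(4+1+1) = 1/3
        m = _matrix_from_sets({"s1": "XY", "s2": "XY", "bx": "X", "cy": "Y"}, "XY")
        assert beta_sor(m, "X", "Y") == pytest.approx(1 / 3)

    def test_sim_nested_composition_zero(self):
        m = _matrix_from_sets({"t1": "XY", "t2": "XY", "t3": "Y"}, "XY")
        assert beta_sim(m, "X", "Y") == 0

    def test_sim_worked_example(self):
        # a=2, b=1, c=3 -> min(b,c)/(a+min) = 1/3
        rows = {"s1": "XY", "s2": "XY", "bx": "X", "c1": "Y", "c2": "Y", "c3": "Y"}
        m = _matrix_from_sets(rows, "XY")
        assert beta_sim(m, "X", "Y") == pytest.approx(1 / 3)

    def test_sim_le_sor_randomized(self, rng):
        for _ in range(50):
            m = random_coded_matrix(rng, n_areas=4, n_taxa=10, root=False)
            a1, a2 = rng.choice(m.area_labels, size=2, replace=False)
            assert beta_sim(m, a1, a2) <= beta_sor(m, a1, a2) + 1e-12

    def test_pairwise_locality(self, rng):
        # the dissimilarity of X and Y ignores what happens in other areas
        m = random_coded_matrix(rng, n_areas=5, n_taxa=12, root=False)
        sub = AreaTaxonMatrix(m.data[["A1", "A2"]][m.data[["A1", "A2"]].sum(axis=1) > 0])
        assert beta_sor(m, "A1", "A2") == pytest.approx(beta_sor(sub, "A1", "A2"))
        assert beta_sim(m, "A1", "A2") == pytest.approx(beta_sim(sub, "A1", "A2"))

    def test_coded_rows_excluded_by_default(self):
        df = pd.DataFrame(
            {"X": [1, 0, 1], "Y": [0, 1, 1]}, index=["t1", "t2", "fam"]
        )
        m = CodedMatrix(df, taxon_level={"fam": "coded-higher-clade"})
        # with the coded row, a would gain a shared pseudo-taxon
        assert beta_sor(m, "X", "Y") == 1
        assert beta_sor(m, "X", "Y", terminals_only=False) == pytest.approx(0.5)

    def test_both_empty_pair_rejected(self):
        m = _matrix_from_sets({"t1": "Z"}, "XYZ")
        with pytest.raises(ValidationError):
            beta_sor(m, "X", "Y")


class TestUpgma:
    def test_three_point_worked_example(self):
        d = _dist({("A", "B"): 0.2, ("A", "C"): 0.6, ("B", "C"): 0.4}, list("ABC"))
        den = upgma(d)
        heights = den.heights()
        assert heights[frozenset("AB")] == pytest.approx(0.1)
        # C joins at mean(0.6, 0.4)/2 = 0.25
        assert heights[frozenset("ABC")] == pytest.approx(0.25)

    def test_matches_scipy_average_linkage_when_tie_free(self, rng):
        for _ in range(10):
            m = random_coded_matrix(rng, n_areas=6, n_taxa=25, root=False)
            dist = dissimilarity_matrix(m, "sor")
            cond = dist.condensed()
            if len(np.unique(np.round(cond, 12))) < len(cond):
                continue  # ties: order-dependent by design
            Z = average(cond)
            ours = upgma(dist)
            coph = squareform(cophenet(Z))
            labels = dist.area_labels
            got = ours.cophenetic().data
            for i, x in enumerate(labels):
                for j, y in enumerate(labels):
                    if i < j:
                        assert got.at[x, y] == pytest.approx(coph[i, j])

    def test_ultrametric_fixed_point(self):
        # cophenetic distances of an ultrametric input reproduce it exactly
        d = _dist(
            {("A", "B"): 0.2, ("A", "C"): 0.6, ("B", "C"): 0.6, ("A", "D"): 0.8,
             ("B", "D"): 0.8, ("C", "D"): 0.8},
            list("ABCD"),
        )
        den = upgma(d)
        coph = den.cophenetic().data
        for x, y in [("A", "B"), ("A", "C"), ("B", "C"), ("A", "D")]:
            assert coph.at[x, y] == pytest.approx(d.value(x, y))

    def test_order_invariant_without_ties(self, rng):
        d = _dist({("A", "B"): 0.2, ("A", "C"): 0.6, ("B", "C"): 0.4}, list("ABC"))
        base = upgma(d)
        for order in (["C", "A", "B"], ["B", "C", "A"]):
            den = upgma(d.reordered(order))
            assert den.clades(trivial=True) == base.clades(trivial=True)
            assert den.heights() == pytest.approx(base.heights())

    def test_tie_resolution_depends_on_order(self):
        # exact tie on the first merge: (A,B) and (C,D) both at 0.1
        d = _dist(
            {("A", "B"): 0.1, ("C", "D"): 0.1, ("A", "C"): 0.9, ("A", "D"): 0.8,
             ("B", "C"): 0.7, ("B", "D"): 0.9},
            list("ABCD"),
        )
        first = upgma(d)
        second = upgma(d.reordered(["C", "D", "A", "B"]))
        assert first.ties >= 1
        h1 = sorted(first.heights().values())[0]
        h2 = sorted(second.heights().values())[0]
        assert h1 == h2 == pytest.approx(0.05)


class TestNodeStrength:
    def test_tie_free_matrix_full_strength(self):
        m = _matrix_from_sets(
            {"t1": "XY", "t2": "XY", "t3": "XYZ", "t4": "Z", "t5": "ZW", "t6": "W"},
            "XYZW",
        )
        den = node_strength(m, "sor", n_trees=50, seed=1)
        assert den.ties == 0
        assert all(v == 100.0 for v in den.node_strength.values())

    def test_strengths_are_multiples_of_one_sixth(self, rng):
        m = random_coded_matrix(rng, n_areas=6, n_taxa=12, root=False)
        den = node_strength(m, "sim", n_trees=60, seed=2)
        for v in den.node_strength.values():
            assert v * 6 / 100 == pytest.approx(round(v * 6 / 100))

    def test_engineered_tie_weakens_node(self):
        # two equal first merges that lead to different topologies by order
        df = pd.DataFrame(
            {
                "A": [1, 1, 0, 0, 1, 0],
                "B": [1, 0, 1, 0, 0, 1],
                "C": [0, 1, 1, 1, 0, 0],
                "D": [0, 0, 0, 1, 1, 1],
            },
            index=[f"t{i}" for i in range(6)],
        )
        m = AreaTaxonMatrix(df)
        dist = dissimilarity_matrix(m, "sor")
        cond = dist.condensed()
        assert len(np.unique(cond)) < len(cond)  # the tie is real
        den = node_strength(m, "sor", n_trees=200, seed=3)
        assert min(den.node_strength.values()) <= 50.0


class TestClusterBootstrap:
    def test_fixed_seed_reproducible(self, rng):
        m = random_coded_matrix(rng, n_areas=5, n_taxa=12, root=False)
        a = cluster_bootstrap(m, "sor", n_trees=20, n_boot=30, seed=4)
        b = cluster_bootstrap(m, "sor", n_trees=20, n_boot=30, seed=4)
        assert a == b

    def test_supports_bounded_and_trivial_clade_full(self, rng):
        m = random_coded_matrix(rng, n_areas=5, n_taxa=12, root=False)
        sup = cluster_bootstrap(m, "sim", n_trees=20, n_boot=30, seed=5)
        assert all(0 <= v <= 100 for v in sup.values())
        assert sup[frozenset(m.area_labels)] == 100.0

    def test_block_structure_strongly_supported(self):
        rows = {}
        for k in range(6):
            rows[f"w{k}"] = "XY"
            rows[f"v{k}"] = "ZW"
        rows["x"] = "X"
        rows["z"] = "Z"
        m = _matrix_from_sets(rows, "XYZW")
        sup = cluster_bootstrap(m, "sor", n_trees=30, n_boot=60, seed=6)
        assert sup.get(frozenset("XY"), 0) >= 90
        assert sup.get(frozenset("ZW"), 0) >= 90


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    st.lists(
        st.tuples(st.booleans(), st.booleans()).filter(any),
        min_size=1,
        max_size=25,
    )
)
def test_turnover_coefficient_invariants(cells):
    """For any two-area composition: both coefficients lie in [0,1] and
    Simpson turnover never exceeds Sørensen dissimilarity."""
    rows = {f"t{i}": {a for a, p in zip("XY", c) if p} for i, c in enumerate(cells)}
    m = _matrix_from_sets(rows, "XY")
    sor = beta_sor(m, "X", "Y")
    sim = beta_sim(m, "X", "Y")
    assert 0.0 <= sim <= sor <= 1.0


def test_consensus_rule_thresholds():
    sets = [{frozenset("AB")}, {frozenset("AB")}, {frozenset("AC")}]
    assert frozenset("AB") in consensus_clades(sets, 0.5)
    assert frozenset("AB") not in consensus_clades(sets, 0.8)
    assert frozenset("AC") not in consensus_clades(sets, 0.5)
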