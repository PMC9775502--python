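"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive quantities by exhaustive enumeration (all internal
state assignments, all topologies) and never call the algorithms they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cade import AreaTaxonMatrix, CodedMatrix, Node, Tree


# ----------------------------------------------------------------- oracles
def oracle_assignment_cost(tree: Tree, assignment: dict) -> int:
    cost = 0
    for node in tree.preorder():
        if node.parent is not None and assignment[node] != assignment[node.parent]:
            cost += 1
    return cost


def oracle_mprs(tree: Tree, character: dict):
    """(min steps, list of optimal full assignments) by enumerating every
    internal-node state combination."""
    internals = tree.internal_nodes()
    leaf_states = {leaf: int(character[leaf.label]) for leaf in tree.leaves()}
    best, optima = None, []
    for states in itertools.product((0, 1), repeat=len(internals)):
        assignment = dict(leaf_states)
        assignment.update(zip(internals, states))
        cost = oracle_assignment_cost(tree, assignment)
        if best is None or cost < best:
            best, optima = cost, [assignment]
        elif cost == best:
            optima.append(assignment)
    return best, optima


def oracle_steps(tree: Tree, character: dict) -> int:
    return oracle_mprs(tree, character)[0]


# ------------------------------------------------------------- generators
def random_rooted_tree(labels, rng) -> Tree:
    """Random binary tree by joining two uniformly chosen subtrees until one
    remains (independent of the package's own simulators)."""
    nodes = [Node(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return Tree(nodes[0])


def random_coded_matrix(
    rng, n_areas: int, n_taxa: int, root: bool = True
) -> CodedMatrix:
    """Random binary matrix with no constant-zero rows; optional all-zero
    root area appended under the label 'ROOT'."""
    areas = [f"A{i + 1}" for i in range(n_areas)]
    rows = {}
    for t in range(n_taxa):
        row = (rng.random(n_areas) < rng.uniform(0.2, 0.8)).astype(int)
        if row.sum() == 0:
            row[rng.integers(0, n_areas)] = 1
        rows[f"T{t + 1}"] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=areas)
    for col in areas:  # keep every real area occupied
        if df[col].sum() == 0:
            df.iloc[int(rng.integers(0, n_taxa)), df.columns.get_loc(col)] = 1
    if root:
        df["ROOT"] = 0
        return CodedMatrix(df, root_area="ROOT")
    return CodedMatrix(df)


# -------------------------------------------------------------- fixtures
@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def five_leaf_tree() -> Tree:
    """(((A,B),C),((D,E),ROOT)) — the worked example used across modules."""
    return Tree.from_newick("(((A,B),C),((D,E),ROOT));")


@pytest.fixture
def small_matrix() -> AreaTaxonMatrix:
    df = pd.DataFrame(
        {
            "AF": [1, 0, 1, 0],
            "MD": [0, 1, 1, 0],
            "SE": [0, 0, 0, 1],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    return AreaTaxonMatrix(df)
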