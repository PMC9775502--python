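"""Fitch parsimony scoring and exact tree search over area cladograms.

Characters are the (binary) taxon rows of a coded matrix; terminals are the
areas plus the all-zero hypothetical rooting area. Search is exact: either
plain exhaustive enumeration of unrooted topologies or branch-and-bound by
stepwise addition, pruning a partial tree as soon as its Fitch length exceeds
the best complete length seen (partial length never decreases when leaves are
added). All optimal trees are retained ("MulTrees" semantics).

Scoring packs all characters of a matrix into Python integers, two bitmasks
per node (one per state), so one intersection/union Fitch step over every
character is a handful of bitwise operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .matrix import CodedMatrix, ValidationError
from .tree import Node, Tree, TreeError

#: refuse exhaustive enumeration above this many leaves (default cap)
DEFAULT_LEAF_CAP = 11


@dataclass
class SearchResult:
    """Outcome of an exact search: the optimum and every tree attaining it."""

    best_score: int
    trees: list[Tree]
    stats: dict = field(default_factory=dict)

    @property
    def n_optimal(self) -> int:
        return len(self.trees)


# ----------------------------------------------------------------- scoring
def _leaf_masks(matrix: CodedMatrix) -> dict[str, tuple[int, int]]:
    """Per area: (mask0, mask1) over characters, bit c set iff character c has
    that state in the area."""
    chars = matrix.characters()  # (n_taxa, n_areas)
    masks = {}
    for j, area in enumerate(matrix.area_labels):
        m1 = 0
        for c in range(matrix.n_taxa):
            if chars[c, j]:
                m1 |= 1 << c
        full = (1 << matrix.n_taxa) - 1
        masks[area] = (full & ~m1, m1)
    return masks


def _combine(a: tuple[int, int], b: tuple[int, int], full: int) -> tuple[tuple[int, int], int]:
    """One Fitch down-pass step over all packed characters; returns the
    resulting state-set masks and the number of characters that took a step."""
    i0 = a[0] & b[0]
    i1 = a[1] & b[1]
    empty = full & ~(i0 | i1)
    r0 = i0 | (empty & (a[0] | b[0]))
    r1 = i1 | (empty & (a[1] | b[1]))
    return (r0, r1), empty.bit_count()


class _Scorer:
    """Fitch length of the nested-list tree encoding used by the search.

    A tree is either an int (leaf index) or a list of subtrees; the top-level
    list may have three children (the unrooted trifurcation), all other
    internal nodes have two.
    """

    def __init__(self, masks: Sequence[tuple[int, int]], n_chars: int):
        self.masks = masks
        self.full = (1 << n_chars) - 1

    def score(self, node) -> int:
        sets, steps = self._down(node)
        return steps

    def _down(self, node):
        if isinstance(node, int):
            return self.masks[node], 0
        acc, steps = self._down(node[0])
        for child in node[1:]:
            cset, csteps = self._down(child)
            acc, extra = _combine(acc, cset, self.full)
            steps += csteps + extra
        return acc, steps


def fitch_steps(tree: Tree, character: Mapping[str, int]) -> int:
    """Minimum number of changes of one binary character on a (binary) tree.

    `character` maps every leaf label (including the root area) to 0 or 1.
    """
    if not tree.is_binary:
        raise TreeError("Fitch scoring requires a binary tree")
    steps = 0

    def down(node: Node) -> frozenset:
        nonlocal steps
        if node.is_leaf:
            if node.label not in character:
                raise ValidationError(f"leaf {node.label!r} has no character state")
            state = character[node.label]
            if state not in (0, 1):
                raise ValidationError(f"state for {node.label!r} must be 0/1")
            return frozenset([state])
        left = down(node.children[0])
        right = down(node.children[1])
        inter = left & right
        if inter:
            return inter
        steps += 1
        return left | right

    down(tree.root)
    return steps


def fitch_steps_per_character(tree: Tree, matrix: CodedMatrix) -> np.ndarray:
    """Vector of Fitch lengths, one per character (matrix row), on `tree`."""
    leaf_labels = tree.leaf_labels()
    if set(leaf_labels) != set(matrix.area_labels):
        raise ValidationError("tree leaves must equal the matrix areas")
    masks = _leaf_masks(matrix)
    full = (1 << matrix.n_taxa) - 1
    per_char_steps = [0] * matrix.n_taxa

    def down2(node: Node) -> tuple[int, int]:
        if node.is_leaf:
            return masks[node.label]
        if len(node.children) != 2:
            raise TreeError("Fitch scoring requires a binary tree")
        a = down2(node.children[0])
        b = down2(node.children[1])
        i0, i1 = a[0] & b[0], a[1] & b[1]
        empty = full & ~(i0 | i1)
        e = empty
        while e:
            c = (e & -e).bit_length() - 1
            per_char_steps[c] += 1
            e &= e - 1
        return (i0 | (empty & (a[0] | b[0])), i1 | (empty & (a[1] | b[1])))

    down2(tree.root)
    return np.array(per_char_steps, dtype=int)


def tree_length(tree: Tree, matrix: CodedMatrix) -> int:
    """Total Fitch length: sum of per-character minimum changes."""
    return int(fitch_steps_per_character(tree, matrix).sum())


# ------------------------------------------------------------- enumeration
def n_unrooted_topologies(n_leaves: int) -> int:
    """(2n-5)!! — the number of unrooted binary topologies on n labelled leaves."""
    if n_leaves < 3:
        return 1
    return math.prod(range(2 * n_leaves - 5, 0, -2))


def _iter_structures(n_leaves: int) -> Iterator:
    """Yield every unrooted binary topology on leaf indices 0..n-1 exactly once,
    as nested lists with a top-level trifurcation (leaves 0,1,2 seed the star)."""
    base = [0, 1, 2]

    def edges(node, parent, idx, out):
        out.append((parent, idx, node))
        if isinstance(node, list):
            for i, child in enumerate(node):
                edges(child, node, i, out)

    def rec(tree, next_leaf):
        if next_leaf == n_leaves:
            yield tree
            return
        pos: list = []
        for i, child in enumerate(tree):
            edges(child, tree, i, pos)
        for parent, idx, old in pos:
            parent[idx] = [old, next_leaf]
            yield from rec(tree, next_leaf + 1)
            parent[idx] = old

    if n_leaves == 3:
        yield base
        return
    yield from rec(base, 3)


def enumerate_unrooted_topologies(
    n_leaves: int, cap: int = DEFAULT_LEAF_CAP
) -> Iterator[Tree]:
    """Stream all unrooted binary topologies on leaves L1..Ln (as trees whose
    root carries the unrooted trifurcation)."""
    if n_leaves < 3:
        raise ValidationError("need at least 3 leaves")
    if n_leaves > cap:
        raise ValidationError(
            f"{n_leaves} leaves exceeds the enumeration cap of {cap} "
            f"({n_unrooted_topologies(n_leaves)} topologies)"
        )
    labels = [f"L{i + 1}" for i in range(n_leaves)]
    for structure in _iter_structures(n_leaves):
        yield _structure_to_tree(structure, labels)


def _structure_to_tree(structure, labels: Sequence[str]) -> Tree:
    def build(node) -> Node:
        if isinstance(node, int):
            return Node(label=labels[node])
        out = Node()
        for child in node:
            out.add_child(build(child))
        return out

    return Tree(build(structure))


# ------------------------------------------------------------------ search
def _addition_order(matrix: CodedMatrix, mode: str) -> list[int]:
    """Leaf insertion order (area indices). 'as-is' keeps column order;
    'furthest' starts from the most mutually distant pair plus the root area,
    then repeatedly adds the area with the largest total Hamming distance to
    the already-placed set (ties broken lexicographically by label)."""
    areas = matrix.area_labels
    n = len(areas)
    if mode == "as-is":
        return list(range(n))
    if mode != "furthest":
        raise ValidationError(f"unknown addition order {mode!r}")
    cols = matrix.characters().T  # (n_areas, n_taxa)
    dist = np.array(
        [[int(np.sum(cols[i] != cols[j])) for j in range(n)] for i in range(n)]
    )
    # most mutually distant pair, ties lexicographic by label pair
    best_pair = min(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda p: (-dist[p[0], p[1]], areas[p[0]], areas[p[1]]),
    )
    order = list(best_pair)
    root_idx = areas.index(matrix.root_area) if matrix.root_area else None
    if root_idx is not None and root_idx not in order:
        order.append(root_idx)
    while len(order) < n:
        remaining = [i for i in range(n) if i not in order]
        nxt = min(remaining, key=lambda i: (-int(dist[i, order].sum()), areas[i]))
        order.append(nxt)
    return order


def _search(
    matrix: CodedMatrix,
    order: Sequence[int],
    prune: bool,
    cap: int,
) -> SearchResult:
    areas = matrix.area_labels
    n = len(areas)
    if n < 3:
        raise ValidationError("search needs at least 3 areas including the root")
    if n > cap:
        raise ValidationError(
            f"{n} areas exceeds the search cap of {cap}; raise `cap` explicitly"
        )
    masks_by_label = _leaf_masks(matrix)
    masks = [masks_by_label[areas[i]] for i in range(n)]
    scorer = _Scorer([masks[i] for i in order], matrix.n_taxa)
    # NB: scorer indexes leaves by *position in the addition order*
    stats = {"trees_examined": 0, "trees_pruned": 0, "complete_trees": 0}
    best = math.inf
    optima: list = []

    base = [0, 1, 2]
    if n == 3:
        best = scorer.score(base)
        optima = [[0, 1, 2]]
        stats["complete_trees"] = 1
        stats["trees_examined"] = 1
    else:

        def edges(node, parent, idx, out):
            out.append((parent, idx, node))
            if isinstance(node, list):
                for i, child in enumerate(node):
                    edges(child, node, i, out)

        def copy_structure(node):
            if isinstance(node, int):
                return node
            return [copy_structure(c) for c in node]

        def rec(tree, next_leaf):
            nonlocal best, optima
            pos: list = []
            for i, child in enumerate(tree):
                edges(child, tree, i, pos)
            for parent, idx, old in pos:
                parent[idx] = [old, next_leaf]
                stats["trees_examined"] += 1
                score = scorer.score(tree)
                if prune and score > best:
                    stats["trees_pruned"] += 1
                elif next_leaf + 1 == n:
                    stats["complete_trees"] += 1
                    if score < best:
                        best = score
                        optima = [copy_structure(tree)]
                    elif score == best:
                        optima.append(copy_structure(tree))
                else:
                    rec(tree, next_leaf + 1)
                parent[idx] = old

        rec(base, 3)

    # convert structures (leaf = position in addition order) to rooted trees
    labels = [areas[i] for i in order]
    trees = []
    seen = set()
    for structure in optima:
        tree = _structure_to_tree(structure, labels)
        if matrix.root_area is not None:
            tree = tree.rerooted_on_leaf(matrix.root_area)
        tree.canonicalize()
        key = frozenset(tree.bipartitions())
        if key in seen:
            continue
        seen.add(key)
        trees.append(tree)
    return SearchResult(best_score=int(best), trees=trees, stats=stats)


def exhaustive_search(matrix: CodedMatrix, cap: int = DEFAULT_LEAF_CAP) -> SearchResult:
    """Score every unrooted topology; the oracle for branch_and_bound."""
    return _search(matrix, list(range(matrix.n_areas)), prune=False, cap=cap)


def branch_and_bound(
    matrix: CodedMatrix,
    addition_order: str = "furthest",
    cap: int = DEFAULT_LEAF_CAP,
) -> SearchResult:
    """Provably optimal search with stepwise addition and length-bound pruning;
    retains every optimal tree, rooted on the hypothetical area's edge."""
    if matrix.root_area is None:
        raise ValidationError(
            "branch_and_bound expects a coded matrix with the root area added"
        )
    order = _addition_order(matrix, addition_order)
    return _search(matrix, order, prune=True, cap=cap)
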