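"""Character bootstrap with per-replicate tree search and split supports.

Characters (matrix rows) are resampled with replacement; each replicate is
analysed by an exact branch-and-bound search by default — the area problems
here are small enough that exactness is cheaper than worrying about search
failure — or by the classic stepwise-addition + tree-bisection-reconnection
(TBR) heuristic for protocol fidelity with standard parsimony software.

Within a replicate, multiple optimal trees are reduced to their strict
consensus before crediting splits: a split counts once per replicate iff it
occurs in every optimal tree of that replicate (conservative and
deterministic). Supports are percentages of replicates crediting the split.
Replicate r of a run with seed s draws from the derived stream (s, r), so
results are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .matrix import CodedMatrix, ValidationError
from .parsimony import SearchResult, _leaf_masks, branch_and_bound
from .tree import Node, Tree


@dataclass
class BootstrapResult:
    n_replicates: int
    supports: dict            # frozenset (canonical split) -> percentage
    seed: int
    scores: list = field(default_factory=list)  # per-replicate best score
    search: str = "branch_and_bound"

    def annotate(self, tree: Tree) -> Tree:
        """Attach integer-rounded support percentages to the matching internal
        nodes of `tree` (annotation key 'bootstrap')."""
        all_leaves = tree.root.leaf_labels()
        ref = min(all_leaves)
        for node in tree.internal_nodes():
            side = node.leaf_labels()
            if ref in side:
                side = all_leaves - side
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                pct = self.supports.get(side)
                if pct is not None:
                    node.annotations["bootstrap"] = int(round(pct))
        return tree


def resample_characters(
    matrix: CodedMatrix, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> CodedMatrix:
    """Draw n characters (rows) with replacement; area columns are untouched.
    Repeated draws get a '.k' label suffix to keep row labels unique."""
    if matrix.n_taxa < 1:
        raise ValidationError("need at least one character to resample")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, matrix.n_taxa, size=matrix.n_taxa)
    counts: dict[str, int] = {}
    labels = []
    for i in idx:
        orig = matrix.taxon_labels[int(i)]
        counts[orig] = counts.get(orig, 0) + 1
        labels.append(orig if counts[orig] == 1 else f"{orig}.{counts[orig]}")
    data = matrix.data.iloc[idx].copy()
    data.index = labels
    levels = {
        lab: matrix.taxon_level[matrix.taxon_labels[int(i)]]
        for lab, i in zip(labels, idx)
    }
    return CodedMatrix(
        data, taxon_level=levels, provenance=matrix.provenance, root_area=matrix.root_area
    )


def strict_consensus_splits(trees: list[Tree]) -> set:
    """Splits present in every tree (canonical bipartition encoding)."""
    out = trees[0].bipartitions()
    for t in trees[1:]:
        out &= t.bipartitions()
    return out


def bootstrap(
    matrix: CodedMatrix,
    n_reps: int,
    seed: int,
    search: str = "branch_and_bound",
) -> BootstrapResult:
    """Nonparametric character bootstrap; see module docstring for crediting."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if matrix.root_area is None:
        raise ValidationError("bootstrap expects a matrix with the root area added")
    if search not in ("branch_and_bound", "addition_tbr"):
        raise ValidationError(f"unknown search {search!r}")
    counts: dict = {}
    scores = []
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        resampled = resample_characters(matrix, rng=rng)
        if search == "branch_and_bound":
            result = branch_and_bound(resampled, addition_order="as-is")
        else:
            result = addition_tbr_search(resampled)
        scores.append(result.best_score)
        for split in strict_consensus_splits(result.trees):
            counts[split] = counts.get(split, 0) + 1
    supports = {split: 100.0 * c / n_reps for split, c in counts.items()}
    return BootstrapResult(
        n_replicates=n_reps, supports=supports, seed=seed, scores=scores, search=search
    )


# ----------------------------------------------------- heuristic search
# Unrooted trees as adjacency maps {node_id: [neighbours]}; leaf ids are the
# area positions 0..n-1, internal ids count up from n. Kept private to the
# bootstrap: the main search is exact.


class _GraphScorer:
    def __init__(self, matrix: CodedMatrix):
        masks = _leaf_masks(matrix)
        self.leaf_masks = [masks[a] for a in matrix.area_labels]
        self.full = (1 << matrix.n_taxa) - 1
        self.n_leaves = matrix.n_areas

    def score(self, adj: dict) -> int:
        start = next(i for i in adj if i >= self.n_leaves)
        steps = 0

        def down(node: int, parent: int):
            nonlocal steps
            if node < self.n_leaves:
                return self.leaf_masks[node]
            acc = None
            for nb in adj[node]:
                if nb == parent:
                    continue
                cset = down(nb, node)
                if acc is None:
                    acc = cset
                    continue
                i0, i1 = acc[0] & cset[0], acc[1] & cset[1]
                empty = self.full & ~(i0 | i1)
                steps += empty.bit_count()
                acc = (
                    i0 | (empty & (acc[0] | cset[0])),
                    i1 | (empty & (acc[1] | cset[1])),
                )
            return acc

        down(start, -1)
        return steps


def _graph_splits(adj: dict, n_leaves: int) -> frozenset:
    """Canonical nontrivial splits of an adjacency tree (leaf-index sets on
    the side not containing leaf 0)."""
    all_leaves = frozenset(range(n_leaves))
    splits = set()

    def below(node: int, parent: int) -> frozenset:
        if node < n_leaves:
            return frozenset([node])
        out: set = set()
        for nb in adj[node]:
            if nb != parent:
                out |= below(nb, node)
        side = frozenset(out)
        canon = side if 0 not in side else all_leaves - side
        if 2 <= len(canon) <= n_leaves - 2:
            splits.add(canon)
        return side

    start = next(i for i in adj if i >= n_leaves)
    below(start, -1)
    return frozenset(splits)


def _stepwise_addition(matrix: CodedMatrix, scorer: _GraphScorer) -> dict:
    """Simple addition sequence: leaves in column order, each attached at the
    currently best edge (first such edge on ties); one tree held per step."""
    n = matrix.n_areas
    center = n  # first internal id
    adj = {center: [0, 1, 2], 0: [center], 1: [center], 2: [center]}
    next_id = n + 1
    for leaf in range(3, n):
        best_edge = None
        best_score = None
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for u, v in edges:
            new = next_id
            _attach(adj, u, v, new, leaf)
            sc = scorer.score(adj)
            _detach(adj, u, v, new, leaf)
            if best_score is None or sc < best_score:
                best_score, best_edge = sc, (u, v)
        u, v = best_edge
        _attach(adj, u, v, next_id, leaf)
        next_id += 1
    return adj


def _attach(adj: dict, u: int, v: int, new: int, leaf: int) -> None:
    adj[u][adj[u].index(v)] = new
    adj[v][adj[v].index(u)] = new
    adj[new] = [u, v, leaf]
    adj[leaf] = [new]


def _detach(adj: dict, u: int, v: int, new: int, leaf: int) -> None:
    adj[u][adj[u].index(new)] = v
    adj[v][adj[v].index(new)] = u
    del adj[new]
    del adj[leaf]


def _copy_adj(adj: dict) -> dict:
    return {k: list(v) for k, v in adj.items()}


def _tbr_neighbours(adj: dict, n_leaves: int):
    """Yield every tree one TBR move away: cut an edge, then reconnect any
    edge of one component to any edge of the other."""
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    for cut_u, cut_v in edges:
        for comp_adj, roots in _bisect(adj, cut_u, cut_v, n_leaves):
            yield comp_adj


def _component(adj: dict, start: int, banned: int) -> set:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb != banned and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _bisect(adj: dict, cut_u: int, cut_v: int, n_leaves: int):
    """All reconnections of the two components created by cutting (u, v)."""
    comp_u = _component(adj, cut_u, cut_v)
    comp_v = _component(adj, cut_v, cut_u)

    def extract(nodes: set, cut_end: int) -> dict:
        sub = {k: [x for x in adj[k] if x in nodes] for k in nodes}
        # suppress the degree-2 node left at the cut end (if internal)
        if cut_end >= n_leaves and len(sub[cut_end]) == 2:
            a, b = sub[cut_end]
            sub[a][sub[a].index(cut_end)] = b
            sub[b][sub[b].index(cut_end)] = a
            del sub[cut_end]
        return sub

    sub_u = extract(comp_u, cut_u)
    sub_v = extract(comp_v, cut_v)
    fresh = max(adj) + 1

    def attach_points(sub: dict):
        if len(sub) == 1:  # single leaf: the attachment is the leaf itself
            (leaf,) = sub
            return [None], leaf
        return [(a, b) for a in sub for b in sub[a] if a < b], None

    pts_u, lone_u = attach_points(sub_u)
    pts_v, lone_v = attach_points(sub_v)
    for eu in pts_u:
        for ev in pts_v:
            new = {k: list(v) for k, v in sub_u.items()}
            new.update({k: list(v) for k, v in sub_v.items()})
            nid = fresh
            if eu is None:
                end_u = lone_u
            else:
                a, b = eu
                new[a][new[a].index(b)] = nid
                new[b][new[b].index(a)] = nid
                new[nid] = [a, b]
                end_u = nid
                nid += 1
            if ev is None:
                end_v = lone_v
            else:
                a, b = ev
                new[a][new[a].index(b)] = nid
                new[b][new[b].index(a)] = nid
                new[nid] = [a, b]
                end_v = nid
                nid += 1
            new[end_u].append(end_v)
            new[end_v].append(end_u)
            yield new, (end_u, end_v)


def _adj_to_tree(adj: dict, matrix: CodedMatrix) -> Tree:
    labels = matrix.area_labels
    n = matrix.n_areas
    start = next(i for i in adj if i >= n)

    def build(node: int, parent: int) -> Node:
        if node < n:
            return Node(label=labels[node])
        out = Node()
        for nb in adj[node]:
            if nb != parent:
                out.add_child(build(nb, node))
        return out

    tree = Tree(build(start, -1))
    if matrix.root_area is not None:
        tree = tree.rerooted_on_leaf(matrix.root_area)
    tree.canonicalize()
    return tree


def addition_tbr_search(matrix: CodedMatrix, max_rounds: int = 50) -> SearchResult:
    """Stepwise addition then TBR to (local) optimality, holding every
    equally good tree found ('MulTrees'); not guaranteed globally optimal."""
    scorer = _GraphScorer(matrix)
    n = matrix.n_areas
    current = _stepwise_addition(matrix, scorer)
    best = scorer.score(current)
    optima = {_graph_splits(current, n): current}
    examined = 0
    for _ in range(max_rounds):
        improved = False
        frontier = list(optima.values())
        for adj in frontier:
            for nbr in _tbr_neighbours(adj, n):
                examined += 1
                sc = scorer.score(nbr)
                if sc < best:
                    best = sc
                    optima = {_graph_splits(nbr, n): _copy_adj(nbr)}
                    improved = True
                    break
                if sc == best:
                    key = _graph_splits(nbr, n)
                    if key not in optima:
                        optima[key] = _copy_adj(nbr)
                        improved = True
            if improved:
                break
        if not improved:
            break
    trees = [_adj_to_tree(adj, matrix) for adj in optima.values()]
    return SearchResult(
        best_score=int(best),
        trees=trees,
        stats={"trees_examined": examined, "search": "addition_tbr"},
    )
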