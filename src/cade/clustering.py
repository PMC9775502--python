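"""Turnover-based area clustering: βsor/βsim, UPGMA, order-resampling consensus.

The phenetic counterpart to the parsimony track. Pairwise dissimilarities
between areas use the Dice-Sørensen coefficient

    βsor = (b + c) / (2a + b + c)

(overall compositional dissimilarity, richness differences included) and the
Simpson coefficient

    βsim = min(b, c) / (a + min(b, c))

(pure spatial turnover, insensitive to richness gradients), where a is the
number of taxa shared by the two areas and b, c the numbers exclusive to each.
Both are computed on terminal taxa by default: coded higher-clade rows would
double-count lineages in a, b, c (a config switch allows the expanded matrix
to be explored).

UPGMA here is deliberately order-sensitive: when two merge candidates tie, the
pair encountered first in the current input order wins, exactly the behaviour
that makes dendrogram topology depend on the order of areas when distances
tie. The node-strength and bootstrap procedures quantify that instability by
re-sampling the area order (and, for the bootstrap, the taxa) and counting how
often each node of a reference tree survives consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import AreaTaxonMatrix, DissimilarityMatrix, ValidationError
from .tree import Node, Tree

_TIE_TOL = 1e-12


# ------------------------------------------------------------ coefficients
def _shared_counts(
    matrix: AreaTaxonMatrix, area_x: str, area_y: str, terminals_only: bool
) -> tuple[int, int, int]:
    taxa = matrix.terminal_taxa() if terminals_only else matrix.taxon_labels
    sub = matrix.data.loc[taxa]
    x = sub[area_x].to_numpy().astype(bool)
    y = sub[area_y].to_numpy().astype(bool)
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    if a + b + c == 0:
        raise ValidationError(
            f"dissimilarity undefined: areas {area_x!r} and {area_y!r} are both empty"
        )
    return a, b, c


def beta_sor(
    matrix: AreaTaxonMatrix, area_x: str, area_y: str, terminals_only: bool = True
) -> float:
    """Dice-Sørensen dissimilarity (b + c)/(2a + b + c)."""
    a, b, c = _shared_counts(matrix, area_x, area_y, terminals_only)
    return (b + c) / (2 * a + b + c)


def beta_sim(
    matrix: AreaTaxonMatrix, area_x: str, area_y: str, terminals_only: bool = True
) -> float:
    """Simpson turnover min(b, c)/(a + min(b, c)); 0 for nested compositions."""
    a, b, c = _shared_counts(matrix, area_x, area_y, terminals_only)
    mbc = min(b, c)
    if mbc == 0:
        return 0.0
    return mbc / (a + mbc)


def dissimilarity_matrix(
    matrix: AreaTaxonMatrix, coefficient: str, terminals_only: bool = True
) -> DissimilarityMatrix:
    fn = {"sor": beta_sor, "sim": beta_sim}.get(coefficient)
    if fn is None:
        raise ValidationError(f"unknown coefficient {coefficient!r}")
    areas = matrix.area_labels
    vals = pd.DataFrame(0.0, index=areas, columns=areas)
    for i, x in enumerate(areas):
        for y in areas[i + 1 :]:
            d = fn(matrix, x, y, terminals_only)
            vals.at[x, y] = d
            vals.at[y, x] = d
    return DissimilarityMatrix(vals, coefficient)


# ------------------------------------------------------------------- UPGMA
@dataclass
class Dendrogram:
    """Ultrametric UPGMA tree over areas; node heights (cophenetic level / 2)
    live in node.annotations['height']."""

    tree: Tree
    coefficient: str
    ties: int = 0  # number of tied merge decisions encountered
    node_strength: dict = field(default_factory=dict)   # clade -> percentage
    bootstrap: dict = field(default_factory=dict)       # clade -> percentage

    def clades(self, trivial: bool = False) -> set:
        return self.tree.clade_sets(trivial=trivial)

    def heights(self) -> dict:
        return {
            node.leaf_labels(): node.annotations["height"]
            for node in self.tree.internal_nodes()
        }

    def cophenetic(self) -> DissimilarityMatrix:
        """Pairwise cophenetic dissimilarities (2 x merge height)."""
        areas = self.tree.leaf_labels()
        vals = pd.DataFrame(0.0, index=areas, columns=areas)

        def walk(node: Node):
            if node.is_leaf:
                return [node.label]
            sides = [walk(c) for c in node.children]
            h = node.annotations["height"]
            for i in range(len(sides)):
                for j in range(i + 1, len(sides)):
                    for x in sides[i]:
                        for y in sides[j]:
                            vals.at[x, y] = 2 * h
                            vals.at[y, x] = 2 * h
            return [x for side in sides for x in side]

        walk(self.tree.root)
        return DissimilarityMatrix(vals.loc[sorted(areas), sorted(areas)], self.coefficient)

    def to_newick(self) -> str:
        def set_lengths(node: Node, parent_height: float):
            h = 0.0 if node.is_leaf else node.annotations["height"]
            node.length = parent_height - h
            for c in node.children:
                set_lengths(c, h)

        tree = self.tree.copy()
        root_h = tree.root.annotations["height"]
        set_lengths(tree.root, root_h)
        tree.root.length = None
        return tree.to_newick(include_lengths=True)


def upgma(dist: DissimilarityMatrix) -> Dendrogram:
    """Unweighted pair-group agglomeration: merge the closest pair of clusters
    (first pair in current order on ties), inter-cluster distance = arithmetic
    mean over all cross pairs, merge height = distance / 2."""
    labels = dist.area_labels
    if len(labels) < 2:
        raise ValidationError("UPGMA needs at least 2 areas")
    nodes: list[Node] = []
    sizes: list[int] = []
    for lab in labels:
        nodes.append(Node(label=lab))
        sizes.append(1)
    d = dist.data.to_numpy(dtype=float).copy()
    active = list(range(len(labels)))
    ties = 0
    while len(active) > 1:
        best = None
        best_pair = None
        tied = False
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                val = d[active[ii], active[jj]]
                if best is None or val < best - _TIE_TOL:
                    best = val
                    best_pair = (ii, jj)
                    tied = False
                elif abs(val - best) <= _TIE_TOL:
                    tied = True
        if tied:
            ties += 1
        ii, jj = best_pair
        i, j = active[ii], active[jj]
        parent = Node()
        parent.annotations["height"] = best / 2.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # unweighted average: weights by cluster sizes
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
        nodes[i] = parent
        sizes[i] = ni + nj
        active.pop(jj)
    root = nodes[active[0]]
    return Dendrogram(tree=Tree(root), coefficient=dist.coefficient, ties=ties)


# --------------------------------------------------------------- consensus
def clade_frequencies(clade_sets: Sequence[set]) -> dict:
    counts: dict = {}
    for cs in clade_sets:
        for clade in cs:
            counts[clade] = counts.get(clade, 0) + 1
    return {clade: c / len(clade_sets) for clade, c in counts.items()}


def consensus_clades(clade_sets: Sequence[set], rule: float) -> set:
    """Clades present in at least `rule` fraction of the trees."""
    freqs = clade_frequencies(clade_sets)
    return {clade for clade, f in freqs.items() if f >= rule - _TIE_TOL}


def _reordered_clade_sets(
    dist: DissimilarityMatrix, n_trees: int, rng: np.random.Generator
) -> list[set]:
    areas = dist.area_labels
    out = []
    for _ in range(n_trees):
        order = [areas[i] for i in rng.permutation(len(areas))]
        out.append(upgma(dist.reordered(order)).clades())
    return out


DEFAULT_RULES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def node_strength(
    matrix: AreaTaxonMatrix,
    coefficient: str,
    n_trees: int = 1000,
    rules: Sequence[float] = DEFAULT_RULES,
    seed: int = 0,
    terminals_only: bool = True,
) -> Dendrogram:
    """Initial-order UPGMA tree annotated with node strengths: the percentage
    of consensus rules under which each node survives consensus over `n_trees`
    trees built from uniformly re-ordered areas."""
    dist = dissimilarity_matrix(matrix, coefficient, terminals_only)
    initial = upgma(dist)
    rng = np.random.default_rng(seed)
    clade_sets = _reordered_clade_sets(dist, n_trees, rng)
    freqs = clade_frequencies(clade_sets)
    strengths = {}
    for clade in initial.clades():
        f = freqs.get(clade, 0.0)
        score = sum(1 for q in rules if f >= q - _TIE_TOL)
        strengths[clade] = 100.0 * score / len(rules)
    initial.node_strength = strengths
    for node in initial.tree.internal_nodes():
        clade = node.leaf_labels()
        if clade in strengths:
            node.annotations["strength"] = strengths[clade]
    return initial


def consensus_reference_clades(
    matrix: AreaTaxonMatrix,
    coefficient: str,
    n_trees: int,
    rng: np.random.Generator,
    rule: float = 0.5,
    terminals_only: bool = True,
) -> set:
    dist = dissimilarity_matrix(matrix, coefficient, terminals_only)
    return consensus_clades(_reordered_clade_sets(dist, n_trees, rng), rule)


def cluster_bootstrap(
    matrix: AreaTaxonMatrix,
    coefficient: str,
    n_trees: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    rule: float = 0.5,
    terminals_only: bool = True,
) -> dict:
    """Taxon bootstrap of the order-resampling consensus.

    The reference tree is the `rule`-consensus of `n_trees` reordered UPGMA
    trees on the original matrix. Each replicate resamples taxa (rows) with
    replacement at the original richness, rebuilds the reordered consensus the
    same way, and each reference clade is credited when it reappears. Returns
    clade -> support percentage (the trivial all-areas clade is reported at
    100)."""
    rng = np.random.default_rng(seed)
    reference = consensus_reference_clades(
        matrix, coefficient, n_trees, rng, rule, terminals_only
    )
    counts = {clade: 0 for clade in reference}
    taxa = matrix.terminal_taxa() if terminals_only else matrix.taxon_labels
    for _ in range(n_boot):
        idx = rng.integers(0, len(taxa), size=len(taxa))
        rows = [taxa[int(i)] for i in idx]
        data = matrix.data.loc[rows].copy()
        data.index = [f"t{k}" for k in range(len(rows))]
        resampled = AreaTaxonMatrix(data)
        # a resample can empty an area; such replicates still count in the
        # denominator but credit no clade involving the undefined pairs
        try:
            rep_clades = consensus_reference_clades(
                resampled, coefficient, n_trees, rng, rule, terminals_only=False
            )
        except ValidationError:
            continue
        for clade in reference:
            if clade in rep_clades:
                counts[clade] += 1
    supports = {clade: 100.0 * c / n_boot for clade, c in counts.items()}
    supports[frozenset(matrix.area_labels)] = 100.0
    return supports
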