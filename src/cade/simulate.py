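"""Vicariance/dispersal simulator: incidence matrices with known ground truth.

The forward model mirrors how a vicariant history writes itself into a
taxon x area incidence matrix. A rooted binary "area tree" stands for the
fragmentation history of a landmass. Each taxon originates on a uniformly
chosen branch and initially occupies exactly the areas descending from it
(pure vicariant inheritance). Two perturbations then act:

* dispersal — with probability p_dispersal the taxon gains one uniformly
  chosen area outside its range (at most one gain per taxon, so each
  dispersal maps to a single potential homoplasy);
* extinction — each occupied area is lost independently with probability
  p_extinction, but never the taxon's last area.

With both probabilities at zero every character is a clade of the area tree,
the data are perfectly compatible, and the CADE pipeline must recover the
true tree exactly — the calibration point for the recovery experiment.

Defaults (9 areas, 66 taxa, p_dispersal=0.1, p_extinction=0.05) match the
scale of a global analysis of major clades across zoogeographic regions with
a modest dispersal footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .coding import code_matrix
from .diagnostics import ensemble_fit
from .matrix import AreaTaxonMatrix, CladeHierarchy, ValidationError
from .parsimony import branch_and_bound
from .tree import Node, Tree


@dataclass
class SimulationConfig:
    n_areas: int = 9
    n_taxa: int = 66
    p_dispersal: float = 0.1
    p_extinction: float = 0.05
    hierarchy_depth: Optional[int] = None  # None = emit every eligible level
    seed: int = 0
    #: seed the first taxa one per internal branch so that every clade of the
    #: true tree is witnessed by at least one informative character
    ensure_coverage: bool = False

    def __post_init__(self):
        if self.n_areas < 3:
            raise ValidationError("n_areas must be >= 3")
        if self.n_taxa < 1:
            raise ValidationError("n_taxa must be >= 1")
        for p in (self.p_dispersal, self.p_extinction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class TaxonEvents:
    taxon: str
    origin: frozenset          # leaf set of the origin branch
    dispersals: list = field(default_factory=list)   # areas gained
    extinctions: list = field(default_factory=list)  # areas lost


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    area_tree: Tree
    matrix: AreaTaxonMatrix
    hierarchy: Optional[CladeHierarchy]
    events: list  # one TaxonEvents per taxon


def simulate_area_tree(
    n_areas: int, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> Tree:
    """Uniformly random rooted binary topology over A1..An by sequential
    addition: each new leaf attaches to a uniformly chosen branch, the branch
    above the root included (2k-1 choices at k leaves, giving (2n-3)!! equal
    weight overall)."""
    if n_areas < 2:
        raise ValidationError("need at least 2 areas for a tree")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = [f"A{i + 1}" for i in range(n_areas)]
    root = Node()
    root.add_child(Node(label=labels[0]))
    root.add_child(Node(label=labels[1]))
    tree = Tree(root)
    for label in labels[2:]:
        nodes = [n for n in tree.postorder()]  # non-root nodes = their stem edges
        nodes.remove(tree.root)
        choice = int(rng.integers(0, len(nodes) + 1))
        leaf = Node(label=label)
        if choice == len(nodes):  # above the root
            new_root = Node()
            new_root.add_child(tree.root)
            new_root.add_child(leaf)
            tree = Tree(new_root)
        else:
            target = nodes[choice]
            parent = target.parent
            idx = parent.children.index(target)
            joint = Node()
            joint.add_child(target)
            joint.add_child(leaf)
            joint.parent = parent
            parent.children[idx] = joint
    tree.canonicalize()
    return tree


def _branch_nodes(tree: Tree) -> list[Node]:
    """Every node, each standing for its stem branch (the root's stem is the
    branch on which a taxon occupies all areas)."""
    return list(tree.postorder())


def simulate_matrix(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full dataset (matrix, hierarchy, events) from the forward model."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_area_tree(config.n_areas, rng=rng)
    areas = sorted(tree.leaf_labels())
    branches = _branch_nodes(tree)
    width = len(str(config.n_taxa))
    taxa = [f"T{str(i + 1).zfill(width)}" for i in range(config.n_taxa)]

    origins: list[Node] = []
    if config.ensure_coverage:
        internal = [
            n for n in branches
            if not n.is_leaf and n.parent is not None
        ]
        origins.extend(internal[: config.n_taxa])
    while len(origins) < config.n_taxa:
        origins.append(branches[int(rng.integers(0, len(branches)))])

    rows = {}
    events = []
    origin_node_of = {}
    for taxon, origin in zip(taxa, origins):
        present = set(origin.leaf_labels())
        ev = TaxonEvents(taxon=taxon, origin=frozenset(present))
        if rng.random() < config.p_dispersal:
            outside = [a for a in areas if a not in present]
            if outside:
                gained = outside[int(rng.integers(0, len(outside)))]
                present.add(gained)
                ev.dispersals.append(gained)
        if config.p_extinction > 0:
            for area in sorted(present):
                if len(present) > 1 and rng.random() < config.p_extinction:
                    present.remove(area)
                    ev.extinctions.append(area)
        rows[taxon] = [1 if a in present else 0 for a in areas]
        events.append(ev)
        origin_node_of[taxon] = origin

    matrix = AreaTaxonMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=areas).astype(np.int8)
    )
    hierarchy = _build_hierarchy(tree, origin_node_of, config.hierarchy_depth)
    return SyntheticDataset(
        config=config, area_tree=tree, matrix=matrix, hierarchy=hierarchy, events=events
    )


def _build_hierarchy(
    tree: Tree, origin_node_of: dict, depth_cap: Optional[int]
) -> Optional[CladeHierarchy]:
    """Named clade per internal area-tree node whose subtree hosts the origins
    of >= 2 taxa (and that would have >= 2 children once built); taxa whose
    origins fall outside every named clade hang off the hierarchy root."""
    taxa_at: dict[Node, list[str]] = {}
    for taxon, node in origin_node_of.items():
        taxa_at.setdefault(node, []).append(taxon)

    counter = [0]

    def build(node: Node, depth: int):
        """Return the list of hierarchy children contributed by `node`."""
        own = [Node(label=t) for t in sorted(taxa_at.get(node, []))]
        below: list[Node] = list(own)
        for child in node.children:
            below.extend(build(child, depth + 1))
        emit = (
            not node.is_leaf
            and len(below) >= 2
            and (depth_cap is None or depth <= depth_cap)
            and node.parent is not None
        )
        if emit:
            counter[0] += 1
            clade = Node(label=f"C{counter[0]}")
            for h in below:
                clade.add_child(h)
            return [clade]
        return below

    children = build(tree.root, 0)
    if not children:
        return None
    root = Node()
    for h in children:
        root.add_child(h)
    if len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
    if root.is_leaf or len(root.children) < 2:
        return None
    return CladeHierarchy(Tree(root))


@dataclass
class RecoveryReplicate:
    seed: int
    n_optimal: int
    best_score: int
    true_recovered: bool       # true tree among the optima
    unique_true: bool          # single optimum and it is the true tree
    missed_bipartitions: int   # true splits absent from the closest optimum
    ci: Optional[float]        # ensemble CI excluding uninformative characters
    ri: Optional[float]        # ensemble RI excluding uninformative characters
    coverage: bool             # every internal branch hosted >= 1 origin


@dataclass
class RecoveryMetrics:
    replicates: list

    @property
    def recovery_rate(self) -> float:
        return sum(r.unique_true for r in self.replicates) / len(self.replicates)

    @property
    def mean_ci(self) -> float:
        vals = [r.ci for r in self.replicates if r.ci is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_missed(self) -> float:
        return float(np.mean([r.missed_bipartitions for r in self.replicates]))


def _true_tree_with_root(area_tree: Tree, root_label: str) -> Tree:
    out = area_tree.copy()
    new_root = Node()
    new_root.add_child(Node(label=root_label))
    new_root.add_child(out.root)
    return Tree(new_root)


def recovery_experiment(
    config: SimulationConfig, n_replicates: int, root_label: str = "ROOT"
) -> RecoveryMetrics:
    """Run the full CADE pipeline on simulated datasets and score how well the
    true area tree is recovered. Replicate r reuses `config` with seed
    (config.seed, r) via a derived stream."""
    replicates = []
    for r in range(n_replicates):
        rep_seed = int(np.random.default_rng([config.seed, r]).integers(0, 2**31 - 1))
        cfg = SimulationConfig(
            n_areas=config.n_areas,
            n_taxa=config.n_taxa,
            p_dispersal=config.p_dispersal,
            p_extinction=config.p_extinction,
            hierarchy_depth=config.hierarchy_depth,
            seed=rep_seed,
            ensure_coverage=config.ensure_coverage,
        )
        dataset = simulate_matrix(cfg)
        coded = code_matrix(dataset.matrix, dataset.hierarchy, root_label)
        result = branch_and_bound(coded)
        truth = _true_tree_with_root(dataset.area_tree, root_label)
        true_splits = truth.bipartitions()
        missed = min(
            len(true_splits - t.bipartitions()) for t in result.trees
        )
        recovered = any(t.same_topology(truth) for t in result.trees)
        try:
            ens = ensemble_fit(result.trees[0], coded, exclude_uninformative=True)
            ci, ri = ens.CI, ens.RI
        except ValidationError:
            ci = ri = None
        internal = [
            n for n in dataset.area_tree.postorder()
            if not n.is_leaf and n.parent is not None
        ]
        covered_sets = {ev.origin for ev in dataset.events}
        coverage = all(n.leaf_labels() in covered_sets for n in internal)
        replicates.append(
            RecoveryReplicate(
                seed=rep_seed,
                n_optimal=result.n_optimal,
                best_score=result.best_score,
                true_recovered=recovered,
                unique_true=recovered and result.n_optimal == 1,
                missed_bipartitions=missed,
                ci=ci,
                ri=ri,
                coverage=coverage,
            )
        )
    return RecoveryMetrics(replicates=replicates)
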