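"""Minimal rooted trees shared by the parsimony, reconstruction and clustering code.

The trees handled here are small (tens of leaves), so nodes are plain Python
objects and traversals are recursive. Newick parsing is delegated to dendropy;
writing is direct so that internal-node labels and annotation strings come out
exactly as the reports need them.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Raised for structurally invalid trees or malformed Newick input."""


class Node:
    __slots__ = ("label", "children", "parent", "length", "annotations")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length
        self.annotations: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def leaf_labels(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.label])
        out: set = set()
        for c in self.children:
            out |= c.leaf_labels()
        return frozenset(out)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Tree:
    """A rooted tree; polytomies are allowed unless a caller checks is_binary."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"invalid Newick: {exc}") from exc

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(
        self,
        include_lengths: bool = False,
        label_fn: Optional[Callable[[Node], Optional[str]]] = None,
    ) -> str:
        def fmt_label(node: Node) -> str:
            label = label_fn(node) if label_fn is not None else node.label
            if label is None:
                return ""
            label = str(label)
            if any(ch in label for ch in " ();,:[]'"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(node: Node) -> str:
            if node.is_leaf:
                s = fmt_label(node)
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")" + fmt_label(node)
            if include_lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return render(self.root) + ";"

    # ----------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            for c in node.children:
                yield from walk(c)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            yield node
            for c in node.children:
                yield from walk(c)

        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise TreeError(f"no leaf labelled {label!r}")

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            new.annotations = dict(node.annotations)
            for c in node.children:
                new.add_child(dup(c))
            return new

        return Tree(dup(self.root))

    # ---------------------------------------------------------- comparison
    def clade_sets(self, trivial: bool = False) -> set:
        """Leaf-label sets of the rooted clades.

        With trivial=False (default) singletons and the full leaf set are
        dropped, which is the convention for consensus and support counting.
        """
        all_leaves = self.root.leaf_labels()
        out = set()
        for node in self.postorder():
            clade = node.leaf_labels()
            if not trivial and (len(clade) < 2 or clade == all_leaves):
                continue
            out.add(clade)
        return out

    def bipartitions(self) -> set:
        """Canonical unrooted splits: each internal edge's leaf-set on the side
        *not* containing the lexicographically smallest leaf; both sides must
        have >= 2 leaves."""
        all_leaves = self.root.leaf_labels()
        ref = min(all_leaves)
        out = set()
        for node in self.postorder():
            side = node.leaf_labels()
            if ref in side:
                side = all_leaves - side
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                out.add(side)
        return out

    def same_topology(self, other: "Tree") -> bool:
        """Unrooted topological identity: same leaves, same bipartition set."""
        return (
            self.root.leaf_labels() == other.root.leaf_labels()
            and self.bipartitions() == other.bipartitions()
        )

    # ------------------------------------------------------------- shaping
    def canonicalize(self) -> "Tree":
        """Order children (in place) by smallest descendant leaf label; gives a
        deterministic orientation so post-order node numbering is stable."""

        def walk(node: Node) -> str:
            if node.is_leaf:
                return node.label
            keys = [walk(c) for c in node.children]
            order = sorted(range(len(keys)), key=lambda i: keys[i])
            node.children = [node.children[i] for i in order]
            return min(keys)

        walk(self.root)
        return self

    def rerooted_on_leaf(self, label: str) -> "Tree":
        """Return a copy re-rooted so that the named leaf is one of the root's
        two children (rooting on that leaf's pendant edge)."""
        tree = self.copy()
        leaf = tree.find_leaf(label)
        if leaf.parent is None:
            raise TreeError("cannot root on a single-node tree")
        # Reverse parent pointers along the path from leaf's parent to old root.
        path = []
        node = leaf.parent
        while node is not None:
            path.append(node)
            node = node.parent
        new_root = Node()
        leaf.parent.children.remove(leaf)
        new_root.add_child(leaf)
        # hang the remainder of the tree below new_root, reversing the path
        prev = new_root
        for i, node in enumerate(path):
            parent = path[i + 1] if i + 1 < len(path) else None
            if parent is not None:
                parent.children.remove(node)
            node.parent = None
            prev.add_child(node)
            prev = node
        tree2 = Tree(new_root)
        tree2._suppress_unifurcations()
        return tree2

    def _suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        idx = node.parent.children.index(node)
                        node.parent.children[idx] = child
                        child.parent = node.parent
                    changed = True

    def postorder_numbering(self) -> dict:
        """Deterministic node numbers (1-based, post-order after
        canonicalization) used in change reports, e.g. 'node 15 -> node 14'."""
        self.canonicalize()
        numbers = {}
        for i, node in enumerate(self.postorder(), start=1):
            numbers[node] = i
        return numbers

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.to_newick()})"
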