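"""Ancestral-state reconstruction: MPR state sets, ACCTRAN/DELTRAN, change lists.

All reconstructions are over binary characters on the rooted, binary area
cladogram whose terminals include the all-zero hypothetical area. The root
node is assigned state 0 whenever 0 is optimal there (it always is, since the
all-zero leaf is one of its children); changes on the root's pendant edges are
counted like any other branch.

ACCTRAN resolves ambiguity rootward (an early gain followed by reversal is
preferred over parallel gains; in area terms, vicariance plus local extinction
over repeated dispersal); DELTRAN is the opposite extreme. Both are computed
by the classic two-pass algorithms: ACCTRAN assigns, in preorder, the parent's
state whenever it belongs to the child's Fitch down-pass set; DELTRAN does the
same against the child's MPR (final) set. A change is reported as
"unambiguous" when it appears on the same branch with the same direction in
both reconstructions; the stricter all-MPRs criterion is available separately
for diagnostics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .matrix import CodedMatrix, ValidationError
from .tree import Node, Tree, TreeError

GAIN = "gain"   # 0 -> 1
LOSS = "loss"   # 1 -> 0


@dataclass(frozen=True)
class ChangeRecord:
    character: str
    level: str
    branch: str        # e.g. "node 15 -> node 14" or "node 12 -> AF"
    direction: str     # gain | loss
    ambiguity: str     # unambiguous | ambiguous
    optimization: str  # acctran | deltran | both


@dataclass
class ChangeSummary:
    unambiguous_gains: int = 0
    unambiguous_losses: int = 0
    acctran_ambiguous_gains: int = 0
    acctran_ambiguous_losses: int = 0
    deltran_ambiguous_gains: int = 0
    deltran_ambiguous_losses: int = 0
    records: list = field(default_factory=list)

    @property
    def acctran_total(self) -> int:
        return (
            self.unambiguous_gains
            + self.unambiguous_losses
            + self.acctran_ambiguous_gains
            + self.acctran_ambiguous_losses
        )

    @property
    def deltran_total(self) -> int:
        return (
            self.unambiguous_gains
            + self.unambiguous_losses
            + self.deltran_ambiguous_gains
            + self.deltran_ambiguous_losses
        )


def _leaf_states(tree: Tree, character: Mapping[str, int]) -> dict[Node, frozenset]:
    out = {}
    for leaf in tree.leaves():
        if leaf.label not in character:
            raise ValidationError(f"leaf {leaf.label!r} has no character state")
        out[leaf] = frozenset([int(character[leaf.label])])
    return out


def _downpass(tree: Tree, character: Mapping[str, int]) -> dict[Node, frozenset]:
    if not tree.is_binary:
        raise TreeError("reconstruction requires a binary tree")
    sets = _leaf_states(tree, character)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        left, right = (sets[c] for c in node.children)
        inter = left & right
        sets[node] = inter if inter else (left | right)
    return sets


def mpr_state_sets(tree: Tree, character: Mapping[str, int]) -> dict[Node, frozenset]:
    """For every node, the exact set of states it takes in at least one
    most-parsimonious reconstruction (Fitch down-pass + final-pass)."""
    down = _downpass(tree, character)
    final: dict[Node, frozenset] = {}
    for node in tree.preorder():
        if node.parent is None:
            final[node] = down[node]
            continue
        if node.is_leaf:
            final[node] = down[node]
            continue
        fu = final[node.parent]
        dv = down[node]
        left, right = (down[c] for c in node.children)
        if fu <= dv:
            final[node] = fu
        elif left & right:
            final[node] = dv | (fu & (left | right))
        else:
            final[node] = dv | fu
    return final


def _resolve_root(down_root: frozenset) -> int:
    # the all-zero outgroup leaf hangs off the root, so 0 is always optimal
    return 0 if 0 in down_root else 1


def acctran_assignment(tree: Tree, character: Mapping[str, int]) -> dict[Node, int]:
    """The accelerated-transformation MPR: preorder against down-pass sets."""
    down = _downpass(tree, character)
    return _preorder_resolve(tree, character, down)


def deltran_assignment(tree: Tree, character: Mapping[str, int]) -> dict[Node, int]:
    """The delayed-transformation MPR: preorder against MPR (final) sets."""
    final = mpr_state_sets(tree, character)
    return _preorder_resolve(tree, character, final)


def _preorder_resolve(
    tree: Tree, character: Mapping[str, int], sets: dict[Node, frozenset]
) -> dict[Node, int]:
    state: dict[Node, int] = {}
    for node in tree.preorder():
        if node.is_leaf:
            state[node] = int(character[node.label])
        elif node.parent is None:
            state[node] = _resolve_root(sets[node])
        else:
            parent_state = state[node.parent]
            if parent_state in sets[node]:
                state[node] = parent_state
            else:
                (only,) = set(sets[node]) - {parent_state}
                state[node] = only
    return state


def changes_of(assignment: dict[Node, int], tree: Tree) -> set:
    """Branch changes implied by a full node-state assignment, as
    (child-node, direction) pairs; the branch is the edge above the child."""
    out = set()
    for node in tree.preorder():
        if node.parent is None:
            continue
        a, b = assignment[node.parent], assignment[node]
        if a != b:
            out.add((node, GAIN if b == 1 else LOSS))
    return out


def branch_name(node: Node, numbers: dict[Node, int]) -> str:
    parent = f"node {numbers[node.parent]}"
    child = node.label if node.is_leaf else f"node {numbers[node]}"
    return f"{parent} -> {child}"


def change_summary(tree: Tree, matrix: CodedMatrix) -> ChangeSummary:
    """Aggregate ACCTRAN/DELTRAN change counts over all characters.

    Per character, both reconstructions realize exactly the character's Fitch
    length; a change is unambiguous iff identical (branch and direction) in
    both. The remaining changes of each reconstruction are that
    optimization's ambiguous changes.
    """
    numbers = tree.postorder_numbering()
    summary = ChangeSummary()
    for taxon in matrix.taxon_labels:
        character = dict(zip(matrix.area_labels, matrix.row(taxon)))
        acc = changes_of(acctran_assignment(tree, character), tree)
        dlt = changes_of(deltran_assignment(tree, character), tree)
        common = acc & dlt
        level = matrix.taxon_level[taxon]
        for node, direction in sorted(
            common, key=lambda cd: (numbers[cd[0]], cd[1])
        ):
            summary.records.append(
                ChangeRecord(
                    taxon, level, branch_name(node, numbers), direction,
                    "unambiguous", "both",
                )
            )
            if direction == GAIN:
                summary.unambiguous_gains += 1
            else:
                summary.unambiguous_losses += 1
        for label, changes in (("acctran", acc - common), ("deltran", dlt - common)):
            for node, direction in sorted(
                changes, key=lambda cd: (numbers[cd[0]], cd[1])
            ):
                summary.records.append(
                    ChangeRecord(
                        taxon, level, branch_name(node, numbers), direction,
                        "ambiguous", label,
                    )
                )
                if label == "acctran":
                    if direction == GAIN:
                        summary.acctran_ambiguous_gains += 1
                    else:
                        summary.acctran_ambiguous_losses += 1
                else:
                    if direction == GAIN:
                        summary.deltran_ambiguous_gains += 1
                    else:
                        summary.deltran_ambiguous_losses += 1
    return summary


def enumerate_mprs(tree: Tree, character: Mapping[str, int], cap: int = 20):
    """All most-parsimonious full assignments, by exhaustive enumeration over
    internal-node states (strict-criterion diagnostics; small trees only)."""
    internals = tree.internal_nodes()
    if len(internals) > cap:
        raise ValidationError(f"too many internal nodes for enumeration ({len(internals)})")
    leaf_state = {leaf: int(character[leaf.label]) for leaf in tree.leaves()}
    best = None
    mprs = []
    for states in itertools.product((0, 1), repeat=len(internals)):
        assignment = dict(leaf_state)
        assignment.update(dict(zip(internals, states)))
        cost = sum(
            1
            for node in tree.preorder()
            if node.parent is not None and assignment[node] != assignment[node.parent]
        )
        if best is None or cost < best:
            best = cost
            mprs = [assignment]
        elif cost == best:
            mprs.append(assignment)
    return best, mprs


def strict_unambiguous_changes(tree: Tree, character: Mapping[str, int]) -> set:
    """Changes present in *every* MPR (all-reconstructions criterion); logged
    as a diagnostic alongside the ACCTRAN-vs-DELTRAN classification."""
    _, mprs = enumerate_mprs(tree, character)
    change_sets = [changes_of(a, tree) for a in mprs]
    out = change_sets[0]
    for cs in change_sets[1:]:
        out = out & cs
    return out


def write_change_table(summary: ChangeSummary, path) -> None:
    lines = ["character\tlevel\tbranch\tdirection\tambiguity\toptimization"]
    for r in summary.records:
        lines.append(
            f"{r.character}\t{r.level}\t{r.branch}\t{r.direction}\t{r.ambiguity}\t{r.optimization}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
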