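"""Core domain types: presence/absence matrices, clade hierarchies, dissimilarities.

The central object is the binary taxon x area incidence matrix: rows are taxa
(used as cladistic characters), columns are areas of endemism (used as
cladistic terminals). A CodedMatrix is the CADE expansion of such a matrix:
extra rows for named higher clades plus, eventually, the all-zero hypothetical
area used to root the area cladogram.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .tree import Tree

TERMINAL = "terminal"
CODED = "coded-higher-clade"

#: default label for the all-zero hypothetical rooting area
ROOT_AREA_LABEL = "ROOT"


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


def _check_unique(labels: Sequence[str], axis: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {axis} label: {lab!r}")
        seen.add(lab)


class AreaTaxonMatrix:
    """Binary incidence of taxa (rows) across areas of endemism (columns).

    Parameters
    ----------
    data:
        DataFrame with taxon labels as index, area labels as columns, and
        cells that are exactly 0 or 1 (no missing values).
    taxon_level:
        Optional mapping taxon -> {"terminal", "coded-higher-clade"}; taxa
        absent from the mapping are terminals.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        taxon_level: Optional[Mapping[str, str]] = None,
    ):
        _check_unique(list(data.index), "taxon")
        _check_unique(list(data.columns), "area")
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValidationError(
                f"need at least 1 taxon and 2 areas, got {data.shape[0]}x{data.shape[1]}"
            )
        values = data.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-binary cell at taxon {data.index[i]!r}, area {data.columns[j]!r}: "
                f"{data.iat[i, j]!r}"
            )
        self.data = data.astype(np.int8)
        self.taxon_level = {
            t: (taxon_level.get(t, TERMINAL) if taxon_level else TERMINAL)
            for t in data.index
        }

    # ------------------------------------------------------------ accessors
    @property
    def taxon_labels(self) -> list[str]:
        return list(self.data.index)

    @property
    def area_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_areas(self) -> int:
        return self.data.shape[1]

    def terminal_taxa(self) -> list[str]:
        return [t for t in self.taxon_labels if self.taxon_level[t] == TERMINAL]

    def row(self, taxon: str) -> np.ndarray:
        return self.data.loc[taxon].to_numpy()

    def column(self, area: str) -> np.ndarray:
        return self.data[area].to_numpy()

    def characters(self) -> np.ndarray:
        """Matrix as (n_taxa, n_areas) int array; each row is one character
        over the area terminals."""
        return self.data.to_numpy()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AreaTaxonMatrix)
            and self.taxon_labels == other.taxon_labels
            and self.area_labels == other.area_labels
            and np.array_equal(self.characters(), other.characters())
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}({self.n_taxa} taxa x {self.n_areas} areas)"


class CodedMatrix(AreaTaxonMatrix):
    """A CADE-expanded matrix: terminal rows plus one row per named clade.

    provenance maps each coded row label to the hierarchy node it came from;
    root_area is the label of the all-zero hypothetical area once appended
    (None before add_root_area).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        taxon_level: Optional[Mapping[str, str]] = None,
        provenance: Optional[Mapping[str, str]] = None,
        root_area: Optional[str] = None,
    ):
        super().__init__(data, taxon_level)
        self.provenance = dict(provenance or {})
        self.root_area = root_area
        if root_area is not None:
            if root_area not in self.data.columns:
                raise ValidationError(f"root area {root_area!r} not a column")
            if self.data[root_area].any():
                raise ValidationError("root area column must be all zeros")


class CladeHierarchy:
    """Rooted, possibly polytomous tree of named clades over terminal taxa.

    Leaves are terminal taxon labels; internal nodes carry unique clade names
    (the root itself may be unnamed). Taxa of uncertain affinity may hang
    directly off the root ("unplaced"), mirroring groups left out of a
    phylogenetic backbone.
    """

    def __init__(self, tree: Tree):
        names = []
        for node in tree.internal_nodes():
            if len(node.children) < 2:
                raise ValidationError(
                    f"internal node {node.label!r} has fewer than 2 children"
                )
            if node is not tree.root and node.label is None:
                raise ValidationError(
                    "unnamed internal node: clade names are required for coding"
                )
            if node.label is not None:
                names.append(node.label)
        _check_unique(names, "clade")
        leaf_labels = tree.leaf_labels()
        _check_unique(leaf_labels, "hierarchy leaf")
        self.tree = tree

    @property
    def terminal_taxa(self) -> list[str]:
        return self.tree.leaf_labels()

    @property
    def clade_names(self) -> list[str]:
        return [n.label for n in self.tree.internal_nodes() if n.label is not None]

    def clade_members(self) -> dict[str, frozenset]:
        """Map each named clade to the set of terminal taxa it contains."""
        return {
            n.label: n.leaf_labels()
            for n in self.tree.internal_nodes()
            if n.label is not None
        }

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CladeHierarchy({len(self.terminal_taxa)} terminals, "
            f"{len(self.clade_names)} named clades)"
        )


class DissimilarityMatrix:
    """Symmetric pairwise area dissimilarities in [0, 1] with a coefficient tag."""

    def __init__(self, data: pd.DataFrame, coefficient: str):
        if coefficient not in ("sor", "sim"):
            raise ValidationError(f"unknown coefficient tag {coefficient!r}")
        if list(data.index) != list(data.columns):
            raise ValidationError("index and columns must list the same areas")
        values = data.to_numpy(dtype=float)
        if not np.allclose(values, values.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValidationError("diagonal must be zero")
        if values.min() < 0 or values.max() > 1:
            raise ValidationError("dissimilarities must lie in [0, 1]")
        self.data = data.astype(float)
        self.coefficient = coefficient

    @property
    def area_labels(self) -> list[str]:
        return list(self.data.columns)

    def value(self, a: str, b: str) -> float:
        return float(self.data.at[a, b])

    def reordered(self, order: Sequence[str]) -> "DissimilarityMatrix":
        if sorted(order) != sorted(self.area_labels):
            raise ValidationError("reorder must permute the existing areas")
        return DissimilarityMatrix(self.data.loc[order, order], self.coefficient)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy 'condensed' order."""
        vals = self.data.to_numpy(dtype=float)
        n = len(vals)
        return vals[np.triu_indices(n, k=1)]

    def __repr__(self) -> str:  # pragma: no cover
        return f"DissimilarityMatrix({self.coefficient}, {len(self.area_labels)} areas)"
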