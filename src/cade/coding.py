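"""CADE coding: expand a terminal-taxon matrix with higher-clade rows.

This is the step that separates CADE from plain PAE: for every named internal
node of the clade hierarchy a row is added whose distribution is the logical
OR (set union) of its descendant terminals' rows, injecting shared-ancestry
signal into the area analysis. Identical rows are deliberately *not*
de-duplicated: repeated distributions legitimately reinforce the signal of the
clades that produce them.

After expansion, add_root_area appends the all-zero hypothetical area used to
root the area cladogram.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import (
    CODED,
    ROOT_AREA_LABEL,
    AreaTaxonMatrix,
    CladeHierarchy,
    CodedMatrix,
    ValidationError,
)


def expand_with_hierarchy(
    matrix: AreaTaxonMatrix, hierarchy: CladeHierarchy
) -> CodedMatrix:
    """Append one row per named clade: the union of its terminals' rows.

    Hierarchy leaves must all be taxa of the matrix. Matrix taxa missing from
    the hierarchy ("unplaced", e.g. groups of uncertain affinity) keep their
    terminal rows and simply contribute to no coded ancestor.
    """
    unknown = set(hierarchy.terminal_taxa) - set(matrix.taxon_labels)
    if unknown:
        raise ValidationError(
            f"hierarchy references taxa absent from the matrix: {sorted(unknown)}"
        )
    members = hierarchy.clade_members()
    collisions = set(members) & set(matrix.taxon_labels)
    if collisions:
        raise ValidationError(
            f"clade names collide with taxon labels: {sorted(collisions)}"
        )

    coded_rows = {}
    for clade in members:  # internal nodes in post-order: stable, nested first
        terminals = sorted(members[clade])
        union = matrix.data.loc[terminals].to_numpy().max(axis=0)
        coded_rows[clade] = union

    data = pd.concat(
        [
            matrix.data,
            pd.DataFrame(coded_rows, index=matrix.area_labels).T.astype(np.int8),
        ]
    )
    levels = dict(matrix.taxon_level)
    levels.update({clade: CODED for clade in coded_rows})
    provenance = {clade: clade for clade in coded_rows}
    return CodedMatrix(data, taxon_level=levels, provenance=provenance)


def add_root_area(matrix: CodedMatrix, label: str = ROOT_AREA_LABEL) -> CodedMatrix:
    """Append the all-zero hypothetical area that roots the cladogram."""
    if matrix.root_area is not None:
        raise ValidationError(
            f"matrix already has a root area ({matrix.root_area!r})"
        )
    if label in matrix.area_labels:
        raise ValidationError(f"root label {label!r} collides with an area label")
    data = matrix.data.copy()
    data[label] = np.int8(0)
    return CodedMatrix(
        data,
        taxon_level=matrix.taxon_level,
        provenance=matrix.provenance,
        root_area=label,
    )


def code_matrix(
    matrix: AreaTaxonMatrix,
    hierarchy: CladeHierarchy | None = None,
    root_label: str = ROOT_AREA_LABEL,
) -> CodedMatrix:
    """Convenience: hierarchy expansion (if any) followed by root-area addition."""
    if hierarchy is not None:
        coded = expand_with_hierarchy(matrix, hierarchy)
    else:
        coded = CodedMatrix(matrix.data.copy(), taxon_level=matrix.taxon_level)
    return add_root_area(coded, root_label)
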