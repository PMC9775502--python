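"""Readers and writers: CSV and NEXUS matrices, Newick trees, hierarchy outlines.

Orientation conventions
-----------------------
In memory, rows are taxa and columns are areas. The NEXUS emission transposes:
areas become NEXUS "taxa" and matrix taxa become characters, which is the
PAE/CADE convention expected by parsimony programs. Character (taxon) names
are written as CHARLABELS; readers must preserve file order on both axes
because bootstrap resampling and reports are index-based.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Union

import dendropy
import pandas as pd

from .matrix import AreaTaxonMatrix, CladeHierarchy, ValidationError
from .tree import Node, Tree, TreeError

PathLike = Union[str, Path]


# --------------------------------------------------------------------- CSV
def read_matrix_csv(path: PathLike) -> AreaTaxonMatrix:
    """CSV with header row of area labels and first column of taxon labels."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"empty matrix file: {path}")
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AreaTaxonMatrix(df)


def write_matrix_csv(matrix: AreaTaxonMatrix, path: PathLike) -> None:
    matrix.data.to_csv(Path(path), index_label="taxon")


# ------------------------------------------------------------------- NEXUS
def _nexus_quote(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(matrix: AreaTaxonMatrix, path: PathLike) -> None:
    """Write the matrix transposed (areas as NEXUS taxa, taxa as characters)."""
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_areas} NCHAR={matrix.n_taxa};",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? INTERLEAVE=NO;',
        "  CHARLABELS " + " ".join(_nexus_quote(t) for t in matrix.taxon_labels) + ";",
        "  MATRIX",
    ]
    width = max(len(_nexus_quote(a)) for a in matrix.area_labels)
    for area in matrix.area_labels:
        states = "".join(str(int(v)) for v in matrix.column(area))
        lines.append(f"    {_nexus_quote(area):<{width}} {states}")
    lines += ["  ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def _read_charlabels(text: str) -> list[str]:
    m = re.search(r"CHARLABELS\s+(.*?);", text, flags=re.IGNORECASE | re.DOTALL)
    if not m:
        return []
    body = m.group(1)
    labels = []
    for tok in re.finditer(r"'((?:[^']|'')*)'|(\S+)", body):
        if tok.group(1) is not None:
            labels.append(tok.group(1).replace("''", "'"))
        else:
            labels.append(tok.group(2))
    return labels


def read_matrix_nexus(path: PathLike) -> AreaTaxonMatrix:
    """Read a DATA/CHARACTERS block with SYMBOLS "01"; the NEXUS taxa are the
    areas, the characters are the matrix taxa (CHARLABELS, else c1, c2, ...)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"empty matrix file: {path}")
    try:
        cm = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise ValidationError(f"cannot parse NEXUS matrix: {exc}") from exc
    areas = [t.label for t in cm.taxon_namespace]
    rows = {}
    nchar = None
    for taxon in cm.taxon_namespace:
        symbols = cm[taxon].symbols_as_string()
        if any(s not in "01" for s in symbols):
            bad = next(s for s in symbols if s not in "01")
            raise ValidationError(
                f"non-binary state {bad!r} in NEXUS row for area {taxon.label!r}"
            )
        rows[taxon.label] = [int(s) for s in symbols]
        nchar = len(symbols)
    taxa = _read_charlabels(text)
    if taxa and len(taxa) != nchar:
        raise ValidationError(
            f"CHARLABELS lists {len(taxa)} names but matrix has {nchar} characters"
        )
    if not taxa:
        taxa = [f"c{i + 1}" for i in range(nchar)]
    df = pd.DataFrame(
        {area: rows[area] for area in areas}, index=taxa, columns=areas
    )
    return AreaTaxonMatrix(df)


def read_matrix(path: PathLike, format: str = "csv") -> AreaTaxonMatrix:
    if format == "csv":
        return read_matrix_csv(path)
    if format == "nexus":
        return read_matrix_nexus(path)
    raise ValidationError(f"unknown matrix format {format!r}")


# ------------------------------------------------------------------ Newick
def read_newick(path: PathLike) -> Tree:
    text = Path(path).read_text().strip()
    if not text:
        raise TreeError(f"empty tree file: {path}")
    return Tree.from_newick(text)


def write_newick(tree: Tree, path: PathLike, include_lengths: bool = False) -> None:
    Path(path).write_text(tree.to_newick(include_lengths=include_lengths) + "\n")


# --------------------------------------------------------------- hierarchy
def read_hierarchy(path: PathLike) -> CladeHierarchy:
    """Read a clade hierarchy from Newick (named internal nodes) or from an
    indented text outline; the format is sniffed from the content."""
    text = Path(path).read_text()
    if not text.strip():
        raise ValidationError(f"empty hierarchy file: {path}")
    if "(" in text:
        return CladeHierarchy(Tree.from_newick(text.strip()))
    return parse_indented_hierarchy(text)


def parse_indented_hierarchy(text: str) -> CladeHierarchy:
    """Outline format: one label per line; children are indented more deeply
    than their parent; lines with children are named clades, leaf lines are
    terminal taxa; top-level lines hang off an implicit unnamed root."""
    root = Node()
    stack: list[tuple[int, Node]] = [(-1, root)]
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        indent = len(raw) - len(raw.lstrip())
        label = raw.strip()
        while stack and stack[-1][0] >= indent:
            stack.pop()
        if not stack:
            raise ValidationError(f"bad indentation at line {lineno}: {raw!r}")
        node = Node(label=label)
        stack[-1][1].add_child(node)
        stack.append((indent, node))
    if not root.children:
        raise ValidationError("hierarchy outline contains no entries")
    return CladeHierarchy(Tree(root))
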