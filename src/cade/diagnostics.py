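"""Character-fit indices: ci, ri, rc, hi per character and CI/RI/RC ensembles.

For a binary character on a tree whose terminals include the all-zero rooting
area: m is the minimum conceivable number of steps (0 for a constant
character, otherwise 1), s the observed Fitch length on the evaluated tree,
and g the maximum conceivable number of steps, i.e. the length on a star
tree, which for a binary character is the count of the minority state over
all terminals. Then

    ci = m/s        (consistency; 1 = homoplasy-free)
    ri = (g-s)/(g-m) (retention; 1 = maximal, 0 = fits as poorly as possible)
    rc = ci * ri     hi = 1 - ci

ci/ri are undefined for constant characters (s = 0) and ri also when g = m
(single-area endemics). A character is parsimony-informative iff each state
occurs in at least two terminals. Ensemble indices use summed m, s, g:
CI = Σm/Σs, RI = (Σg-Σs)/(Σg-Σm), RC = CI·RI; "excluding uninformative"
removes uninformative characters from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .matrix import CodedMatrix, ValidationError
from .parsimony import fitch_steps_per_character
from .tree import Tree


@dataclass
class CharacterFit:
    taxon: str
    level: str
    m: int
    s: int
    g: int
    ci: Optional[float]
    ri: Optional[float]
    rc: Optional[float]
    hi: Optional[float]
    informative: bool

    @property
    def homoplasy_free(self) -> bool:
        return self.s == self.m


@dataclass
class EnsembleFit:
    CI: float
    RI: float
    RC: float
    n_characters: int
    excluded_uninformative: bool


def _is_informative(row: np.ndarray) -> bool:
    ones = int(row.sum())
    return ones >= 2 and (len(row) - ones) >= 2


def count_informative(matrix: CodedMatrix) -> int:
    """Number of parsimony-informative characters (each state in >= 2 terminals),
    counted on the analysis matrix, i.e. including the all-zero root column if
    it has been added."""
    return sum(_is_informative(row) for row in matrix.characters())


def count_informative_by_level(matrix: CodedMatrix) -> dict[str, int]:
    out: dict[str, int] = {}
    for taxon, row in zip(matrix.taxon_labels, matrix.characters()):
        if _is_informative(row):
            level = matrix.taxon_level[taxon]
            out[level] = out.get(level, 0) + 1
    return out


def _fit_from_counts(taxon: str, level: str, row: np.ndarray, s: int) -> CharacterFit:
    ones = int(row.sum())
    zeros = len(row) - ones
    m = 0 if ones == 0 or zeros == 0 else 1
    g = min(ones, zeros)
    ci = m / s if s > 0 else None
    ri = (g - s) / (g - m) if g > m else None
    rc = ci * ri if ci is not None and ri is not None else None
    hi = 1 - ci if ci is not None else None
    return CharacterFit(
        taxon=taxon,
        level=level,
        m=m,
        s=s,
        g=g,
        ci=ci,
        ri=ri,
        rc=rc,
        hi=hi,
        informative=_is_informative(row),
    )


def char_fit(tree: Tree, matrix: CodedMatrix, taxon: str) -> CharacterFit:
    """Fit of a single character (matrix row) on the evaluated tree."""
    steps = fitch_steps_per_character(tree, matrix)
    idx = matrix.taxon_labels.index(taxon)
    return _fit_from_counts(
        taxon, matrix.taxon_level[taxon], matrix.row(taxon), int(steps[idx])
    )


def all_char_fits(tree: Tree, matrix: CodedMatrix) -> list[CharacterFit]:
    steps = fitch_steps_per_character(tree, matrix)
    return [
        _fit_from_counts(t, matrix.taxon_level[t], matrix.row(t), int(s))
        for t, s in zip(matrix.taxon_labels, steps)
    ]


def ensemble_fit(
    tree: Tree, matrix: CodedMatrix, exclude_uninformative: bool = False
) -> EnsembleFit:
    """CI = Σm/Σs, RI = (Σg-Σs)/(Σg-Σm), RC = CI·RI over the selected characters."""
    fits = all_char_fits(tree, matrix)
    if exclude_uninformative:
        fits = [f for f in fits if f.informative]
    sm = sum(f.m for f in fits)
    ss = sum(f.s for f in fits)
    sg = sum(f.g for f in fits)
    if ss == 0:
        raise ValidationError(
            "ensemble indices undefined: no steps on the selected characters"
        )
    if sg == sm:
        raise ValidationError("ensemble RI undefined: Σg equals Σm")
    CI = sm / ss
    RI = (sg - ss) / (sg - sm)
    return EnsembleFit(
        CI=CI,
        RI=RI,
        RC=CI * RI,
        n_characters=len(fits),
        excluded_uninformative=exclude_uninformative,
    )


def write_fit_table(fits: list[CharacterFit], path) -> None:
    """Per-character fit table as TSV."""

    def fmt(x: Optional[float]) -> str:
        return "NA" if x is None else f"{x:.4f}"

    lines = ["taxon\tlevel\tm\ts\tg\tci\tri\trc\thi\tinformative"]
    for f in fits:
        lines.append(
            f"{f.taxon}\t{f.level}\t{f.m}\t{f.s}\t{f.g}\t{fmt(f.ci)}\t{fmt(f.ri)}"
            f"\t{fmt(f.rc)}\t{fmt(f.hi)}\t{int(f.informative)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
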