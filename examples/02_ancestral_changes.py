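"""Where did each taxon appear and disappear? ACCTRAN vs DELTRAN.

Reconstructs per-branch gains (0->1, colonization of the subtended areas) and
losses (1->0, local disappearance) for every character on the optimal area
cladogram, under both extreme resolutions of ambiguity: ACCTRAN (changes
pulled rootward: vicariance-leaning) and DELTRAN (changes pushed tipward:
dispersal-leaning).
"""

import pandas as pd

from cade import CodedMatrix, Tree, change_summary, tree_length

# a character present in two areas that are not sisters on the cladogram
# cannot be explained by a single origin without a loss
matrix = CodedMatrix(
    pd.DataFrame(
        {
            "AF": [1, 1, 1], "MD": [1, 1, 0], "IN": [0, 1, 1],
            "SE": [0, 0, 0], "ROOT": [0, 0, 0],
        },
        index=["cladeAFMD", "wide", "disjunct"],
    ),
    root_area="ROOT",
)
tree = Tree.from_newick("(((AF,MD),(IN,SE)),ROOT);")

summary = change_summary(tree, matrix)
print(f"tree length: {tree_length(tree, matrix)} steps")
print(
    f"unambiguous: {summary.unambiguous_gains} gains, "
    f"{summary.unambiguous_losses} losses"
)
print(
    f"ACCTRAN-only: {summary.acctran_ambiguous_gains} gains, "
    f"{summary.acctran_ambiguous_losses} losses"
)
print(
    f"DELTRAN-only: {summary.deltran_ambiguous_gains} gains, "
    f"{summary.deltran_ambiguous_losses} losses"
)
print()
for rec in summary.records:
    print(f"  {rec.character:>10}  {rec.branch:<22} {rec.direction:<5} "
          f"{rec.ambiguity:<12} [{rec.optimization}]")
print(
    "\nUnambiguous changes sit on the same branch in every most-parsimonious\n"
    "reconstruction; ambiguous ones move between an early-gain+reversal story\n"
    "(ACCTRAN) and a parallel-gains story (DELTRAN)."
)
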