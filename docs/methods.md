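# Methods

## Data model

The analysis object is a binary taxon × area incidence matrix. Rows are taxa
assumed monophyletic (mixed ranks are fine: what matters is monophyly, not
rank); columns are a priori areas of endemism. Cells are strictly 0/1 — no
missing values — and validation rejects anything else, naming the offending
row and column. Row and column order are significant throughout: bootstrap
resampling, reports and the order-sensitive clustering all refer to file
order, so readers preserve it.

A clade hierarchy (rooted, possibly polytomous, internal nodes named) groups
terminals into nested monophyletic sets. Taxa of uncertain affinity may hang
directly off the (unnamed) hierarchy root: they keep their terminal rows and
simply contribute to no coded ancestor. CADE coding appends one row per
named clade — the element-wise OR of its descendants' rows. Identical coded
rows are deliberately not de-duplicated: repeated distributions are repeated
evidence, and character-indexed reports would break under row merging.

The all-zero hypothetical rooting area is never stored in input matrices; it
is appended at analysis time under a reserved label (default `ROOT`,
collision with a real area is an error, adding it twice is an error).

## Parsimony engine

Characters are unordered, unweighted and binary. Fitch scoring packs all
characters into two Python-integer bitmasks per node (one bit per character
and state), so one down-pass step over every character is a handful of
bitwise operations; per-character step counts are recovered from the
disagreement mask. Search is over unrooted topologies on areas + `ROOT`:

* exhaustive enumeration by stepwise insertion yields each of the (2n−5)!!
  topologies exactly once (refused above a configurable cap, default 11
  leaves ≈ 2 × 10⁶ topologies);
* branch-and-bound inserts leaves in "furthest" order (seed pair = maximum
  Hamming distance between area columns plus the root area; thereafter the
  area with the largest summed distance to the placed set; ties broken
  lexicographically by label) and prunes a partial tree as soon as its
  length exceeds the best complete length — partial Fitch length is
  monotone under leaf addition, so pruning is safe and the optimum is exact.
  The addition order affects traversal only, never the reported optimum;
  both tracks retain *all* optimal trees ("MulTrees") and results are
  de-duplicated by canonical bipartition sets.

Returned cladograms are rooted on the hypothetical area's pendant edge with
the `ROOT` leaf retained, so reconstructions have an explicit all-zero
outgroup. Node numbering in reports is post-order after a canonical
orientation (children sorted by smallest descendant label), hence stable
across runs.

## Character fit

For a binary character: `m` = 0 (constant) or 1; `s` = Fitch length on the
evaluated tree; `g` = minority-state count over **all** terminals including
the root area (the root is a terminal of the analysis matrix). Homoplasy-free
characters have `ci = 1` (the standard consistency index of unity for a
perfectly fitting character); `ci`/`ri` are reported as undefined for
constant characters and `ri` also when `g = m` (single-area endemics).
Informativeness requires each state in ≥ 2 terminals; the all-zero root can
supply the second zero for near-ubiquitous characters, which is the intended
behaviour of the rooting convention. Ensembles sum `m`, `s`, `g` over the
selected characters; "excluding uninformative" removes those characters from
numerator and denominator alike — the convention under which the excluded CI
can differ from (and never exceeds) the all-character CI.

## Ancestral states and change classification

`mpr_state_sets` computes, per node, the exact set of states realized in at
least one most-parsimonious reconstruction, by the Fitch down-pass plus the
standard three-case final pass; it is verified against exhaustive enumeration
of internal assignments in the tests. The root node takes state 0 whenever 0
is optimal there — always true, since the all-zero leaf is one of its
children.

ACCTRAN resolves each node, in preorder, to the parent's state whenever that
state is in the node's *down-pass* set (changes surface as high as possible:
early gain, later reversal). DELTRAN applies the same rule against the *MPR*
set (changes deferred: parallel gains). For binary characters both rules are
deterministic and each realizes exactly `s` changes.

A change (branch, direction) is classified **unambiguous** iff it appears
identically in both reconstructions; the remaining changes of each
reconstruction are that optimization's ambiguous changes. This pairwise
criterion is the one summarized in reports because it is what the
ACCTRAN/DELTRAN comparison measures; the stricter all-MPRs criterion
(`strict_unambiguous_changes`, by enumeration) is available for diagnostics.
Changes on the root's pendant edges count like any other branch.

## Bootstrap

Characters are resampled with replacement; each replicate is searched
exactly by branch-and-bound by default. The area problems in scope are small
enough that exactness is cheaper than worrying about heuristic failure; the
classic stepwise-addition + TBR heuristic is provided for protocol fidelity
with standard parsimony software and agrees with the exact search on the
tested instances (differences are possible only through replicate-level
multiple optima). Within a replicate, splits are credited through the strict
consensus of that replicate's optimal trees — conservative and
deterministic. Replicate r of a run with seed s draws from the derived
stream (s, r), so runs are reproducible and trivially parallelizable. The
trivial root-adjacent split is excluded from reports.

## Turnover clustering

βsor and βsim are computed on terminal taxa only by default: coded
higher-clade rows would double-count lineages in the shared/exclusive counts
a, b, c (a `terminals_only=False` switch exposes the expanded variant). A
pair of empty areas has no defined dissimilarity and raises; βsim of a
nested pair is 0.

UPGMA is implemented directly rather than through a library call because the
procedure must be *order-sensitive*: when two merge candidates tie (within
1e−12), the pair encountered first in the current input order wins, and tied
merges are counted on the result. This is exactly the behaviour that makes
dendrogram topology depend on the area order when distances tie, which the
consensus machinery is designed to quantify; a deterministic label-based
tie-break would make re-ordering a no-op and the node-strength statistic
vacuous. On tie-free inputs the implementation is order-invariant and is
cross-checked against scipy's average-linkage in the tests. Merge height is
dissimilarity/2 (cophenetic convention; the cophenetic distance of a pair is
twice their merge height and reproduces ultrametric inputs exactly).

Node strength: build n trees (default 1000) from uniformly random area
orders; for each consensus rule q ∈ {0.5, 0.6, …, 1.0} a node of the
initial-order tree scores 1 if its clade reaches frequency ≥ q among those
trees; strength = 100 × score/6, hence quantized to multiples of 100/6.
The cluster bootstrap resamples taxa with replacement at original richness
(level 1), rebuilds the re-ordered 0.5-consensus per replicate, and reports
the percentage of replicates containing each node of the reference
(original-matrix 0.5-consensus) tree; replicates that empty an area keep
their place in the denominator but credit nothing.

## Simulator

`simulate_area_tree` draws uniformly from rooted binary topologies by
sequential random addition (the branch above the root included: 2k−1
attachment points at k leaves). Each taxon originates on a uniformly chosen
branch (the root branch yields a cosmopolitan taxon) and occupies that
branch's descendant leaves; with probability `p_dispersal` it gains one
uniform outside area (at most one gain per taxon, so each dispersal maps to
one potential homoplasy and the forward model stays identifiable); each
occupied area is then lost with probability `p_extinction`, never the last
one. The hierarchy emits one named clade per internal area-tree node whose
subtree hosts ≥ 2 hierarchy children (taxa originating there plus nested
clades); the root-level clade of everything is not emitted — it would add an
invariant-by-construction row. The event log records origin, gains and
losses per taxon, and with both probabilities at zero every row equals its
origin branch's leaf set exactly.

Defaults — 9 areas, 66 taxa, `p_dispersal = 0.1`, `p_extinction = 0.05` —
mirror the scale of a global compilation of major clades over zoogeographic
regions with a modest dispersal footprint. `ensure_coverage` seeds the first
taxa one per internal branch before uniform assignment; this generates the
premise of the perfect-recovery calibration (every internal branch witnessed
by an informative character), which uniform assignment alone misses in a
noticeable fraction of replicates at this scale.

`recovery_experiment` runs the full chain (coding → rooting →
branch-and-bound → diagnostics) per replicate and reports whether the true
tree is the unique optimum, the number of true splits missed by the closest
optimum, and the ensemble CI/RI.

What the simulator does *not* emulate: real compilations have phylogenetically
autocorrelated range sizes, uneven taxon sampling across clades, correlated
(route-constrained) dispersal, and areas of wildly different richness.
Passing the recovery battery therefore shows the machinery is correct and
calibrated on its own model, not that any empirical dataset satisfies that
model.

## Numerical and scale choices

Exact searches are capped at 11 leaves by default (the intended problem
size — a handful of zoogeographic regions — is far below combinatorial
trouble; the cap is an explicit argument). Verification batteries use
problem sizes chosen to keep the whole suite in a few minutes on one CPU
while leaving the checks sharp: 200 random instances for search exactness
(≤ 8 terminals, where exhaustive enumeration is still instant), 60 instances
each for the Fitch and reconstruction oracles (trees to 12 leaves ≈ 2¹¹
assignments), 100 replicates for pure-vicariance recovery at the default
9 × 66 scale, 1000 pairs for the turnover inequality, and 10,000 bootstrap
replicates for the two-seed stability check on a 6-area dataset. All
stochastic components consume numpy `default_rng` streams derived from a
single user seed.

## Known limitations

* Binary characters only; no multistate, ordered, Dollo or weighted variants.
* No heuristic search for the main analysis (by design — exact search is
  feasible at the intended scale); TBR exists only inside bootstrap
  replicates.
* The ACCTRAN/DELTRAN ambiguity classification is the two-extremes
  criterion, not the full-MPR one (available separately).
* The simulator's dispersal is single-step per taxon; multi-area dispersal
  chains are out of scope.
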