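"""How robust is the area cladogram to the particular taxa sampled?

Resamples the characters (taxon rows) with replacement, re-runs the exact
search per replicate, and reports for each split of the area set the
percentage of replicates whose optimal trees all contain it.
"""

from cade import SimulationConfig, bootstrap, branch_and_bound, code_matrix, simulate_matrix

dataset = simulate_matrix(
    SimulationConfig(n_areas=6, n_taxa=40, p_dispersal=0.1, p_extinction=0.05, seed=42)
)
coded = code_matrix(dataset.matrix, dataset.hierarchy)

result = branch_and_bound(coded)
boot = bootstrap(coded, n_reps=500, seed=42)
tree = boot.annotate(result.trees[0])

print("optimal area cladogram with bootstrap percentages as node labels:")
print(
    tree.to_newick(
        label_fn=lambda n: str(n.annotations.get("bootstrap", "")) if not n.is_leaf else n.label
    )
)
print("\nper-split supports (500 replicates):")
for split, pct in sorted(boot.supports.items(), key=lambda kv: -kv[1]):
    print(f"  {'+'.join(sorted(split)):<24} {pct:5.1f}%")
print(
    "\nSplits backed by several congruent characters approach 100%; splits\n"
    "resting on one or two characters crumble when resampling drops them."
)
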