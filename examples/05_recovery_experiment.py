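"""Ground-truth validation: can the pipeline recover a known area history?

Simulates datasets under vicariant inheritance on a random area tree, with
tunable dispersal noise, runs the full CADE chain on each, and reports how
often the true tree is the unique optimum.
"""

from cade import SimulationConfig, recovery_experiment

for p_disp in (0.0, 0.1, 0.3):
    cfg = SimulationConfig(
        n_areas=6, n_taxa=40, p_dispersal=p_disp, p_extinction=0.0,
        seed=1, ensure_coverage=True,
    )
    metrics = recovery_experiment(cfg, n_replicates=20)
    print(
        f"p_dispersal={p_disp:.1f}: unique recovery "
        f"{100 * metrics.recovery_rate:5.1f}%  mean CI={metrics.mean_ci:.3f}  "
        f"mean missed splits={metrics.mean_missed:.2f}"
    )
print(
    "\nWith no dispersal and every branch witnessed, recovery is exact and\n"
    "CI = 1; dispersal introduces homoplasy, lowering CI and recovery."
)
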