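"""End-to-end runs: coding -> search -> diagnostics -> bootstrap, and clustering.

Each run_* function takes a RunConfig, executes one track of the workflow and
writes a plain-text report bundle into the output directory. Every file
records the seed and options it came from, so a bundle is reproducible from
(inputs, config, seed) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .bootstrap import bootstrap
from .coding import code_matrix
from .clustering import (
    cluster_bootstrap,
    dissimilarity_matrix,
    node_strength,
    upgma,
)
from .diagnostics import (
    all_char_fits,
    count_informative,
    count_informative_by_level,
    ensemble_fit,
    write_fit_table,
)
from .io import read_hierarchy, read_matrix, write_matrix_csv, write_newick, write_nexus
from .matrix import ROOT_AREA_LABEL, ValidationError
from .parsimony import branch_and_bound
from .reconstruction import change_summary, write_change_table
from .simulate import SimulationConfig, simulate_matrix
from .tree import Tree

log = logging.getLogger("cade")


@dataclass
class RunConfig:
    matrix_path: Optional[Path] = None
    hierarchy_path: Optional[Path] = None
    matrix_format: str = "csv"
    root_label: str = ROOT_AREA_LABEL
    addition_order: str = "furthest"
    bootstrap_reps: int = 0
    seed: int = 0
    coefficients: tuple = ("sor", "sim")
    cluster_trees: int = 1000
    cluster_boot: int = 0
    consensus_rule: float = 0.5
    outdir: Path = Path("cade_out")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate_inputs(self) -> None:
        for path in (self.matrix_path, self.hierarchy_path):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input file not found: {path}")


def _load(config: RunConfig):
    config.validate_inputs()
    if config.matrix_path is None:
        raise ValidationError("a matrix file is required")
    matrix = read_matrix(config.matrix_path, config.matrix_format)
    hierarchy = (
        read_hierarchy(config.hierarchy_path) if config.hierarchy_path else None
    )
    return matrix, hierarchy


def _header(config: RunConfig) -> list[str]:
    return [f"# cade {__version__}", f"# seed: {config.seed}"]


def run_cade(config: RunConfig) -> dict:
    """Parsimony track: coded NEXUS, optimal trees, fit and change tables."""
    matrix, hierarchy = _load(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    coded = code_matrix(matrix, hierarchy, config.root_label)
    write_nexus(coded, outdir / "coded.nex")
    log.info(
        "coded matrix: %d characters (%d terminal) x %d areas",
        coded.n_taxa, len(coded.terminal_taxa()), coded.n_areas,
    )

    result = branch_and_bound(coded, addition_order=config.addition_order)
    log.info(
        "branch-and-bound: %d optimal tree(s), %d steps (%d trees examined)",
        result.n_optimal, result.best_score, result.stats["trees_examined"],
    )

    boot = None
    if config.bootstrap_reps > 0:
        boot = bootstrap(coded, config.bootstrap_reps, config.seed)
        for tree in result.trees:
            boot.annotate(tree)

    with open(outdir / "trees.nwk", "w") as fh:
        for tree in result.trees:
            fh.write(
                tree.to_newick(
                    label_fn=lambda n: (
                        str(n.annotations["bootstrap"])
                        if "bootstrap" in n.annotations
                        else n.label
                    )
                )
                + "\n"
            )

    best = result.trees[0]
    fits = all_char_fits(best, coded)
    write_fit_table(fits, outdir / "character_fit.tsv")
    summary = change_summary(best, coded)
    write_change_table(summary, outdir / "changes.tsv")

    report = dict(
        n_characters=coded.n_taxa,
        n_areas=coded.n_areas,
        best_score=result.best_score,
        n_optimal_trees=result.n_optimal,
        n_informative=count_informative(coded),
        informative_by_level=count_informative_by_level(coded),
        n_perfect_fit=sum(
            1 for f in fits if f.informative and f.ci == 1.0 and f.ri == 1.0
        ),
        unambiguous_gains=summary.unambiguous_gains,
        unambiguous_losses=summary.unambiguous_losses,
        acctran_ambiguous_gains=summary.acctran_ambiguous_gains,
        acctran_ambiguous_losses=summary.acctran_ambiguous_losses,
        deltran_ambiguous_gains=summary.deltran_ambiguous_gains,
        deltran_ambiguous_losses=summary.deltran_ambiguous_losses,
    )
    try:
        ens_all = ensemble_fit(best, coded, exclude_uninformative=False)
        ens_inf = ensemble_fit(best, coded, exclude_uninformative=True)
        report.update(
            CI=ens_all.CI, RI=ens_all.RI, RC=ens_all.RC,
            CI_excl_uninformative=ens_inf.CI,
            RI_excl_uninformative=ens_inf.RI,
            RC_excl_uninformative=ens_inf.RC,
        )
    except ValidationError as exc:
        log.info("ensemble indices unavailable: %s", exc)

    lines = _header(config) + [f"{k}: {v}" for k, v in report.items()]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report


def run_cluster(config: RunConfig) -> dict:
    """Phenetic track: dissimilarities, annotated dendrograms, support tables."""
    matrix, _ = _load(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {}
    for coeff in config.coefficients:
        dist = dissimilarity_matrix(matrix, coeff)
        dist.data.to_csv(outdir / f"dissimilarity_{coeff}.tsv", sep="\t")
        dendro = node_strength(
            matrix, coeff, n_trees=config.cluster_trees, seed=config.seed
        )
        supports = {}
        if config.cluster_boot > 0:
            supports = cluster_bootstrap(
                matrix, coeff,
                n_trees=config.cluster_trees,
                n_boot=config.cluster_boot,
                seed=config.seed,
                rule=config.consensus_rule,
            )
        annotated = dendro.tree.copy()
        def _label(node):
            if node.is_leaf:
                return node.label
            clade = node.leaf_labels()
            s = dendro.node_strength.get(clade)
            b = supports.get(clade)
            parts = []
            if s is not None:
                parts.append(f"{s:.0f}")
            if b is not None:
                parts.append(f"{b:.0f}")
            return "/".join(parts) if parts else None
        (outdir / f"dendrogram_{coeff}.nwk").write_text(
            annotated.to_newick(label_fn=_label) + "\n"
        )
        table = [_hdr for _hdr in _header(config)] + [
            "clade\tstrength\tbootstrap"
        ]
        for clade in sorted(dendro.node_strength, key=lambda c: (len(c), sorted(c))):
            s = dendro.node_strength[clade]
            b = supports.get(clade, "")
            table.append(f"{'+'.join(sorted(clade))}\t{s:.1f}\t{b}")
        (outdir / f"supports_{coeff}.tsv").write_text("\n".join(table) + "\n")
        report[coeff] = dict(
            ties=dendro.ties,
            newick=dendro.to_newick(),
            node_strength={
                "+".join(sorted(c)): v for c, v in dendro.node_strength.items()
            },
        )
        log.info("%s dendrogram: %d tied merges", coeff, dendro.ties)
    return report


def run_simulate(config: RunConfig) -> dict:
    """Write a simulated dataset in the same formats the pipeline consumes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = simulate_matrix(config.simulation)
    write_matrix_csv(dataset.matrix, outdir / "matrix.csv")
    write_newick(dataset.area_tree, outdir / "true_tree.nwk")
    if dataset.hierarchy is not None:
        write_newick(dataset.hierarchy.tree, outdir / "hierarchy.nwk")
    lines = ["taxon\torigin\tdispersals\textinctions"]
    for ev in dataset.events:
        lines.append(
            f"{ev.taxon}\t{'+'.join(sorted(ev.origin))}"
            f"\t{'+'.join(ev.dispersals)}\t{'+'.join(ev.extinctions)}"
        )
    (outdir / "events.tsv").write_text("\n".join(lines) + "\n")
    cfg = dataset.config
    (outdir / "simulation.cfg").write_text(
        "\n".join(
            [
                f"n_areas={cfg.n_areas}",
                f"n_taxa={cfg.n_taxa}",
                f"p_dispersal={cfg.p_dispersal}",
                f"p_extinction={cfg.p_extinction}",
                f"seed={cfg.seed}",
                f"ensure_coverage={cfg.ensure_coverage}",
            ]
        )
        + "\n"
    )
    return dict(
        n_taxa=dataset.matrix.n_taxa,
        n_areas=dataset.matrix.n_areas,
        n_clades=len(dataset.hierarchy.clade_names) if dataset.hierarchy else 0,
    )
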