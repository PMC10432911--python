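"""Orchestration: simulate -> infer -> evaluate, with file outputs.

Thin wrappers around :class:`~tophapplus.estimator.TopHapPlus` and the
simulator that handle configuration, reproducible seeding, output files and
benchmark grids.  Stages are pure functions of (input, config, seed):
rerunning with the same arguments reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import TopHapPlus
from .evaluate import (clone_tree_with_tip_clones, pair_clones, rf_with_pairing,
                       spurious_clone_count)
from .genotype_io import GenotypeMatrix, write_genotype_matrix, write_outputs
from .refine import DOUBLET, UNINFORMATIVE
from .simulate import GroundTruth, SimulationConfig, simulate_dataset
from .trees import write_newick


@dataclass
class RunConfig:
    """Configuration of one inference run."""

    vaf: str | int | float = 5
    hf: str | int | float = 5
    coi_prune: float = 0.3
    coi_attach: float = 0.4
    attach_floor: int = 2
    fisher_alpha: float = 0.01
    doublet_alpha: float | None = 0.01
    imputation: str = "none"
    impute_k: int = 20
    seed: int = 0
    outdir: str | None = None

    def make_estimator(self) -> TopHapPlus:
        return TopHapPlus(vaf=self.vaf, hf=self.hf, coi_prune=self.coi_prune,
                          coi_attach=self.coi_attach, attach_floor=self.attach_floor,
                          fisher_alpha=self.fisher_alpha, doublet_alpha=self.doublet_alpha,
                          imputation=self.imputation, impute_k=self.impute_k)


def run_pipeline(matrix: GenotypeMatrix, cfg: RunConfig) -> tuple[TopHapPlus, dict]:
    """Fit the estimator on ``matrix`` and optionally write the output bundle.

    Returns the fitted estimator and a manifest of written files (empty when
    ``cfg.outdir`` is unset).
    """
    est = cfg.make_estimator().fit(matrix)
    manifest: dict = {}
    if cfg.outdir:
        manifest = write_outputs(est.tree_, est.assignment_, est.error_rates_,
                                 cfg.outdir, report=est.report_)
    return est, manifest


def write_simulation(observed: GenotypeMatrix, gt: GroundTruth,
                     config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Write a simulated dataset bundle (matrix, truth tree, tables, config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    p = outdir / "observed_matrix.tsv"
    write_genotype_matrix(observed, p)
    manifest["matrix"] = str(p)
    p = outdir / "true_tree.nwk"
    p.write_text(write_newick(gt.true_tree) + "\n")
    manifest["true_tree"] = str(p)
    p = outdir / "cell_to_clone.tsv"
    pd.Series(gt.cell_to_clone, name="clone").rename_axis("cell").to_csv(p, sep="\t")
    manifest["cell_to_clone"] = str(p)
    p = outdir / "doublets.tsv"
    rows = [{"cell": c, "clone_a": a, "clone_b": b} for c, (a, b) in gt.doublet_cells.items()]
    pd.DataFrame(rows, columns=["cell", "clone_a", "clone_b"]).to_csv(p, sep="\t", index=False)
    manifest["doublets"] = str(p)
    p = outdir / "sim_config.json"
    p.write_text(json.dumps(dataclasses.asdict(config), indent=2) + "\n")
    manifest["config"] = str(p)
    return manifest


def evaluate_run(est: TopHapPlus, gt: GroundTruth) -> dict:
    """Paired-RF metrics of a fitted estimator against the simulated truth.

    Doublet cells are excluded from the truth side (their identity is a
    mixture); DOUBLET/UNINFORMATIVE cells are excluded from the inferred
    assignment, as in the reference evaluation protocol.
    """
    true_assign = {c: cl for c, cl in gt.cell_to_clone.items()
                   if c not in gt.doublet_cells}
    inf_assign = {
        r["cell"]: r["clone"] for _, r in est.assignment_.iterrows()
        if r["clone"] not in (DOUBLET, UNINFORMATIVE)
    }
    pairing = pair_clones(true_assign, inf_assign)
    true_clone_ids = set(gt.clone_ids)
    true_tips = clone_tree_with_tip_clones(gt.true_tree, true_clone_ids)
    inferred_clone_ids = {c for c, n in est.clone_counts_.items() if n > 0}
    inf_tips = clone_tree_with_tip_clones(est.tree_, inferred_clone_ids)
    metrics = rf_with_pairing(true_tips, inf_tips, pairing,
                              n_inferred_clones=len(inferred_clone_ids))
    return {
        "rf_distance": metrics.rf_distance,
        "n_true_partitions": metrics.n_true_partitions,
        "n_inferred_partitions": metrics.n_inferred_partitions,
        "unpaired_true_clones": metrics.unpaired_true_clones,
        "clone_count_error": len(inferred_clone_ids) - len(true_clone_ids),
        "spurious_clones": spurious_clone_count(true_assign, inf_assign),
        "n_inferred_clones": len(inferred_clone_ids),
        "n_true_clones": len(true_clone_ids),
        "degenerate": metrics.degenerate,
    }


def run_benchmark(clone_counts: list[int], cell_counts: list[int], n_replicates: int,
                  seed: int = 0, run_cfg: RunConfig | None = None,
                  sim_kwargs: dict | None = None) -> pd.DataFrame:
    """Replicated simulation grid; per-replicate metrics plus config columns."""
    rows = []
    base = run_cfg or RunConfig()
    for k in clone_counts:
        for n in cell_counts:
            for r in range(n_replicates):
                s = int((seed * 1_000_003 + k * 7919 + n * 104729 + r) % (2**31 - 1))
                cfg = SimulationConfig(n_clones=k, n_cells=n, seed=s,
                                       **(sim_kwargs or {}))
                observed, gt = simulate_dataset(cfg)
                est = base.make_estimator().fit(observed)
                m = evaluate_run(est, gt)
                m.update({"n_clones_sim": k, "n_cells": n, "replicate": r, "seed": s,
                          "estimated_fnr": est.error_rates_.fnr,
                          "estimated_fpr": est.error_rates_.fpr})
                rows.append(m)
    return pd.DataFrame(rows)


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of RF and clone-count error per grid condition."""
    return df.groupby(["n_clones_sim", "n_cells"]).agg(
        rf_mean=("rf_distance", "mean"), rf_sd=("rf_distance", "std"),
        cce_mean=("clone_count_error", "mean"), cce_sd=("clone_count_error", "std"),
        spurious_mean=("spurious_clones", "mean"),
    ).reset_index()
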