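"""Simulation-study harness: architecture grids, detection classification,
and power/false-positive summary tables.

A causal marker whose compressed-scan p-value misses the threshold is a
false negative.  A non-causal marker significant under BOTH the compressed
and the multi-locus scan is a false positive — the dual-evidence rule
mirrors how real scans combine statistical significance with the stepwise
model's LD pruning.  For linearly distributed effects, false-negative
fractions are additionally reported restricted to the strongest quartile
(and three quartiles) of effects; these restrictions are undefined for
uniform effects and reported as NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, resolve_heterozygotes
from .mlm_core import CompressionSweep, ScanResult, scan_cmlm
from .mlmm import StepwisePath, dual_model_report, mlmm_scan
from .popstruct import KinshipMatrix, cluster_lines, kinship, pca
from .synthetic_data import (ArchitectureSpec, QTLAssignment, effect_sizes,
                             draw_qtl, simulate_phenotype)

DEFAULT_THRESHOLDS = (1e-5, 1e-4)


@dataclass
class EvalTable:
    """Replicate-averaged false-negative / false-positive summaries."""

    table: pd.DataFrame  # long format: one row per (condition, threshold)
    replicates: pd.DataFrame  # raw per-replicate records

    def wide(self) -> pd.DataFrame:
        """Conditions as columns, metric rows — the printed-table layout."""
        t = self.table.copy()
        t["condition"] = (t["n_qtl"].astype(str) + "QTL/"
                          + t["distribution"] + "/h2=" + t["h2"].astype(str)
                          + "/p<" + t["threshold"].map("{:g}".format))
        metrics = ["fn_total", "fn_top_quartile", "fn_top_three_quartiles",
                   "fp_rate"]
        return t.set_index("condition")[metrics].T


def classify(assignment: QTLAssignment, cmlm: ScanResult,
             path: StepwisePath, threshold: float
             ) -> tuple[set, set, int]:
    """Split markers into false negatives / false positives at a threshold.

    FN: causal markers not significant in the compressed scan.
    FP: non-causal markers significant in BOTH scans.
    Returns (fn marker names, fp marker names, number of markers tested).
    """
    tab = cmlm.table
    names = tab["marker"].to_numpy()
    p_cmlm = tab["p_value"].to_numpy()
    p_mlmm = path.selected_pvalues.reindex(names).to_numpy()
    causal = set(names[assignment.qtl_markers])
    is_causal = np.isin(names, list(causal))
    fn = set(names[is_causal & (p_cmlm >= threshold)])
    fp = set(names[~is_causal & (p_cmlm < threshold) & (p_mlmm < threshold)])
    return fn, fp, len(names)


def quartile_breakdown(assignment: QTLAssignment, fn: set,
                       marker_names: np.ndarray, distribution: str
                       ) -> tuple[float, float]:
    """FN fractions restricted to the strongest 1/4 and 3/4 of effects.

    Only meaningful when effects differ (linear distribution); returns
    (nan, nan) for uniform effects, matching the NA convention.
    """
    if distribution == "uniform":
        return float("nan"), float("nan")
    n = len(assignment.effects)
    order = np.argsort(-assignment.effects)  # strongest first
    names = marker_names[assignment.qtl_markers]
    out = []
    for frac in (0.25, 0.75):
        top = int(np.ceil(frac * n))
        top_names = set(names[order[:top]])
        out.append(len(fn & top_names) / top)
    return out[0], out[1]


def run_study(g: GenotypeMatrix, grid: list[ArchitectureSpec],
              n_replicates: int = 5,
              thresholds: tuple = DEFAULT_THRESHOLDS,
              seed: int = 0, n_pcs: int = 3, group_step: int = 20,
              max_steps: int = 20) -> EvalTable:
    """Run the full architecture grid and average over replicates.

    For each condition and replicate: draw QTL, attach effects, simulate the
    phenotype, run both scans, classify detections at every threshold.
    Kinship, principal components, the cluster tree and the compression-level
    eigendecompositions depend only on the panel, so they are computed once
    and shared by all replicates.  Per-(condition, replicate) child seeds
    derive from the master seed by a fixed counter scheme, so any table cell
    can be re-run in isolation.  A failed condition is recorded and skipped;
    the study continues.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not grid:
        raise ValueError("empty architecture grid")
    if g.has_missing():
        raise ValueError("impute missing dosages before the study")

    k = kinship(g)
    pcs = pca(g, n_pcs)
    covar = np.column_stack([np.ones(g.n_lines), pcs.scores])
    tree = cluster_lines(k)
    sweep = CompressionSweep.build(k, covar, group_step, tree)
    # the multi-locus scan needs homozygous input; resolve once per panel
    het_seed = seed * 7919 % (2 ** 31)
    g_hom = resolve_heterozygotes(g, het_seed)
    marker_names = g.markers["name"].to_numpy()

    rep_rows = []
    for ci, arch in enumerate(grid):
        for rep in range(n_replicates):
            child = (seed * 100_003 + ci * 1_009 + rep) % (2 ** 31)
            try:
                qtl = draw_qtl(g, arch.n_qtl, child)
                eff = effect_sizes(arch.n_qtl, arch.effect_distribution)
                assignment = QTLAssignment(qtl, eff)
                trait = simulate_phenotype(g, assignment, arch.h2,
                                           child + 1)
                cmlm = scan_cmlm(trait.phenotype, g, covar, k,
                                 group_step, sweep=sweep)
                path = mlmm_scan(trait.phenotype, g_hom, covar, k,
                                 max_steps=max_steps, het_seed=het_seed)
            except Exception as exc:  # noqa: BLE001 - study must continue
                warnings.warn(f"condition {arch.label()} replicate {rep} "
                              f"failed: {exc}")
                rep_rows.append({"n_qtl": arch.n_qtl,
                                 "distribution": arch.effect_distribution,
                                 "h2": arch.h2, "replicate": rep,
                                 "failed": True})
                continue
            for thr in thresholds:
                fn, fp, n_tested = classify(assignment, cmlm, path, thr)
                top14, top34 = quartile_breakdown(
                    assignment, fn, marker_names, arch.effect_distribution)
                rep_rows.append({
                    "n_qtl": arch.n_qtl,
                    "distribution": arch.effect_distribution,
                    "h2": arch.h2, "replicate": rep, "threshold": thr,
                    "fn_total": len(fn) / arch.n_qtl,
                    "fn_top_quartile": top14,
                    "fn_top_three_quartiles": top34,
                    "n_fp": len(fp), "n_tested": n_tested,
                    "pseudo_h2_null": cmlm.fit.pseudo_h2,
                    "n_groups": cmlm.n_groups,
                    "mlmm_size": path.selected_size,
                    "failed": False,
                })

    reps = pd.DataFrame(rep_rows)
    good = reps[~reps["failed"]].copy() if "failed" in reps else reps
    agg_rows = []
    for (nq, dist, h2, thr), sub in good.groupby(
            ["n_qtl", "distribution", "h2", "threshold"], sort=False):
        agg_rows.append({
            "n_qtl": nq, "distribution": dist, "h2": h2, "threshold": thr,
            "fn_total": sub["fn_total"].mean(),
            "fn_top_quartile": sub["fn_top_quartile"].mean(),
            "fn_top_three_quartiles": sub["fn_top_three_quartiles"].mean(),
            # FP rate: false positives per marker tested per replicate scan
            "fp_rate": sub["n_fp"].sum() / sub["n_tested"].sum(),
            "n_replicates": len(sub),
        })
    return EvalTable(table=pd.DataFrame(agg_rows), replicates=reps)


def paper_grid(h2_values=(0.95, 0.5), n_qtl_values=(4, 20, 200),
               seed: int = 0) -> list[ArchitectureSpec]:
    """The full condition grid of the emulated study (Table-1 layout)."""
    grid = []
    for nq in n_qtl_values:
        dists = ["linear", "uniform"] if nq in (4, 20) else ["linear"]
        for dist in dists:
            for h2 in h2_values:
                grid.append(ArchitectureSpec(nq, dist, h2, seed))
    return grid
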