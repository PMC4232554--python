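"""Multi-locus stepwise mixed model (forward cofactor selection).

Starting from the null mixed model, markers are added one at a time as
fixed-effect cofactors: at each step every non-cofactor marker is tested
(P3D at that step's REML variance components), the minimum-p marker joins
the model, and the variance components are re-estimated.  Iteration stops
when the remaining pseudo-heritability falls below 0.01 or a step cap is
reached.  Model size is then chosen by the extended BIC (default) or a
multiple-Bonferroni rule, and per-marker p-values are reported in the
selected model: add-one tests for non-cofactors, drop-one tests for
cofactors.

This scan requires fully homozygous input (resolve heterozygotes first);
the resolution seed travels in the path metadata for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import GenotypeMatrix
from .mlm_core import (EigenKinship, MixedModelFit, ScanResult, fit_null,
                       p3d_marker_tests)
from .popstruct import KinshipMatrix


@dataclass
class StepwisePath:
    """Forward-selection trajectory and the selected model's p-values."""

    steps: pd.DataFrame   # step, marker, p_at_addition, pseudo_h2, criterion
    selected_size: int
    selected_cofactors: list
    selected_pvalues: pd.Series  # all markers, in the selected model
    null_fit: MixedModelFit
    criterion: str
    het_seed: int | None = None

    def cofactor_order(self) -> dict:
        """marker name -> 1-based discovery order, selected cofactors only."""
        return {m: i + 1 for i, m in enumerate(self.selected_cofactors)}


def _log_binom(m: int, k: int) -> float:
    return float(gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1))


def mlmm_scan(y: np.ndarray, g: GenotypeMatrix, covariates: np.ndarray,
              k: KinshipMatrix, max_steps: int = 20,
              criterion: str = "ebic", h2_floor: float = 0.01,
              backward: bool = False,
              het_seed: int | None = None) -> StepwisePath:
    """Run the forward stepwise mixed-model scan.

    ``criterion`` selects the model size: "ebic" (extended BIC, gamma = 1)
    or "mbonf" (largest model whose cofactors all pass 0.05 / n_markers).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if (g.dosages == 1).any():
        raise ValueError("heterozygotes present: resolve them before the "
                         "multi-locus scan")
    y = np.asarray(y, dtype=float)
    x0 = np.asarray(covariates, dtype=float)
    n = len(y)
    m = g.n_markers
    names = g.markers["name"].to_numpy()

    dec = EigenKinship.from_kinship(k)
    yt = dec.rotate(y)
    gt = g.dosages.astype(float) @ dec.eigenvectors  # marker x rotated-line
    dos = g.dosages.astype(float)

    cofactors: list[int] = []
    rows = []
    fits_ml = []
    null_fit = None

    def model_x(cof):
        if not cof:
            return x0
        return np.hstack([x0, dos[cof].T])

    pending_p = None
    while True:
        x = model_x(cofactors)
        fit = fit_null(y, x, dec, method="REML")
        fit_ml = fit_null(y, x, dec, method="ML")
        fits_ml.append(fit_ml)
        s = len(cofactors)
        ebic = (-2.0 * fit_ml.log_likelihood + s * np.log(n)
                + 2.0 * _log_binom(m, s))
        if s == 0:
            null_fit = fit
        rows.append({"step": s,
                     "marker": names[cofactors[-1]] if s else None,
                     "p_at_addition": pending_p,
                     "pseudo_h2": fit.pseudo_h2, "ebic": ebic})
        # the floor applies after at least one forward step: with a
        # degenerate kinship (e.g. identity) the null pseudo-h2 is not
        # informative and step 1 must still reduce to a single-locus scan
        if s >= max_steps or (s >= 1 and fit.pseudo_h2 < h2_floor):
            break
        if n <= x.shape[1] + 2:
            warnings.warn("too few lines for further cofactors; stopping")
            break
        candidates = np.setdiff1d(np.arange(m), cofactors)
        xt = dec.rotate(x)
        _, _, pval, flag = p3d_marker_tests(
            yt, xt, gt[candidates], dec.eigenvalues, fit.delta)
        usable = flag == ""
        if not usable.any():
            warnings.warn("no testable candidate markers; stopping")
            break
        pval = np.where(usable, pval, np.inf)
        best_local = int(np.argmin(pval))  # ties: lowest marker index
        pending_p = float(pval[best_local])
        cofactors.append(int(candidates[best_local]))

    steps_df = pd.DataFrame(rows)

    # ----- model-size selection -----
    if criterion == "ebic":
        selected_size = int(steps_df["ebic"].idxmin())
        selected_size = int(steps_df.loc[selected_size, "step"])
    elif criterion == "mbonf":
        thr = 0.05 / m
        selected_size = 0
        for s in range(len(steps_df) - 1, 0, -1):
            cof_s = cofactors[:s]
            fit_s = fit_null(y, model_x(cof_s), dec, method="REML")
            ps = _drop_one_pvalues(yt, dec, x0, dos, gt, cof_s, fit_s.delta)
            if np.all(ps < thr):
                selected_size = s
                break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    selected_cof = cofactors[:selected_size]
    if backward and selected_cof:
        selected_cof = _backward_prune(y, yt, dec, x0, dos, gt, selected_cof,
                                       0.05 / m)
        selected_size = len(selected_cof)

    # ----- p-values in the selected model -----
    x_sel = model_x(selected_cof)
    fit_sel = fit_null(y, x_sel, dec, method="REML") if selected_cof \
        else null_fit
    pvals = np.ones(m)
    noncof = np.setdiff1d(np.arange(m), selected_cof)
    xt_sel = dec.rotate(x_sel)
    _, _, p_add, _ = p3d_marker_tests(yt, xt_sel, gt[noncof],
                                      dec.eigenvalues, fit_sel.delta)
    pvals[noncof] = p_add
    if selected_cof:
        pvals[selected_cof] = _drop_one_pvalues(
            yt, dec, x0, dos, gt, selected_cof, fit_sel.delta)

    return StepwisePath(
        steps=steps_df,
        selected_size=selected_size,
        selected_cofactors=[names[i] for i in selected_cof],
        selected_pvalues=pd.Series(pvals, index=names),
        null_fit=null_fit,
        criterion=criterion,
        het_seed=het_seed,
    )


def _drop_one_pvalues(yt, dec, x0, dos, gt, cofactors, delta) -> np.ndarray:
    """Each cofactor tested against the model holding the others."""
    out = np.empty(len(cofactors))
    for i, ci in enumerate(cofactors):
        others = [c for c in cofactors if c != ci]
        x = np.hstack([x0, dos[others].T]) if others else x0
        _, _, p, _ = p3d_marker_tests(yt, dec.rotate(x), gt[[ci]],
                                      dec.eigenvalues, delta)
        out[i] = p[0]
    return out


def _backward_prune(y, yt, dec, x0, dos, gt, cofactors, thr) -> list:
    cof = list(cofactors)
    while cof:
        fit = fit_null(y, np.hstack([x0, dos[cof].T]), dec, method="REML")
        ps = _drop_one_pvalues(yt, dec, x0, dos, gt, cof, fit.delta)
        worst = int(np.argmax(ps))
        if ps[worst] < thr:
            break
        cof.pop(worst)
    return cof


def dual_model_report(cmlm: ScanResult, path: StepwisePath,
                      threshold: float = 1e-4) -> pd.DataFrame:
    """Markers significant under BOTH the compressed and multi-locus scans.

    Requiring agreement between the single-marker compressed scan and the
    stepwise model suppresses LD-driven false positives; each reported
    record carries both p-values, the discovery order if the marker is a
    selected cofactor, and the compressed-scan allelic effect.
    """
    tab = cmlm.table.set_index("marker")
    p_mlmm = path.selected_pvalues
    common = tab.index.intersection(p_mlmm.index)
    if len(common) != len(tab.index) or len(common) != len(p_mlmm.index):
        raise ValueError("CMLM and MLMM marker universes differ")
    keep = common[(tab.loc[common, "p_value"] < threshold)
                  & (p_mlmm.loc[common] < threshold)]
    order = path.cofactor_order()
    out = pd.DataFrame({
        "marker": keep,
        "chrom": tab.loc[keep, "chrom"].to_numpy(),
        "pos": tab.loc[keep, "pos"].to_numpy(),
        "p_cmlm": tab.loc[keep, "p_value"].to_numpy(),
        "p_mlmm": p_mlmm.loc[keep].to_numpy(),
        "allelic_effect": tab.loc[keep, "effect"].to_numpy(),
        "discovery_order": [order.get(mk, None) for mk in keep],
    }).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out
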