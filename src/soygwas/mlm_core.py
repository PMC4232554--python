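"""EMMA-style variance-component engine and compressed single-marker scan.

The model is y = X b + u + e with u ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I).  Writing delta = sigma_e^2 / sigma_g^2, the
covariance is sigma_g^2 (K + delta I); a single eigendecomposition of K
reduces the (RE)ML problem to a one-dimensional profile likelihood in
delta, optimized on a log grid refined by bounded scalar search.

The compressed scan (CMLM) replaces K by the line-level expansion of a
group-averaged kinship: candidate group counts are swept in fixed
increments, the count maximizing the null REML likelihood is kept, and
markers are then tested one at a time as fixed effects with the variance
components frozen at the null optimum (P3D).  Because the eigendecomposition
at each compression level depends only on the kinship, a
:class:`CompressionSweep` can be built once per panel and reused across
traits and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix
from .popstruct import (KinshipMatrix, LineDendrogram, cluster_lines,
                        compress_kinship, expand_compressed)

_DELTA_GRID = np.logspace(-5, 5, 100)


@dataclass
class MixedModelFit:
    """Variance components of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    pseudo_h2: float
    log_likelihood: float
    method: str  # "REML" | "ML"


@dataclass
class EigenKinship:
    """Spectral decomposition of a PSD-stabilized, trace-normalized kinship.

    Eigenvalues below -1e-8 * max are treated as numerical noise and clamped
    to zero (subsampled or compressed kinship can be slightly indefinite).
    The spectrum is then rescaled to unit mean eigenvalue (trace(K) = n):
    a VanRaden matrix on fully inbred lines has diagonal near 2, and without
    the rescaling sigma_g^2 / (sigma_g^2 + sigma_e^2) would understate the
    share of phenotypic variance carried by the random effect.  Rescaling K
    is absorbed by sigma_g^2, so p-values, effects and the likelihood
    optimum are unchanged; only the variance-component scale is fixed.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns
    scale: float = 1.0        # divisor applied to the raw kinship

    @classmethod
    def from_kinship(cls, k) -> "EigenKinship":
        if isinstance(k, EigenKinship):
            return k
        mat = k.values if isinstance(k, KinshipMatrix) else np.asarray(k)
        w, v = np.linalg.eigh(mat)
        w = np.clip(w, 0.0, None)
        scale = float(w.mean())
        if scale <= 0:
            raise ValueError("kinship has no positive eigenvalues")
        return cls(w / scale, v, scale)

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.eigenvectors.T @ a


def _profile_neg_loglik(delta: float, lam: np.ndarray, yt: np.ndarray,
                        xt: np.ndarray, method: str,
                        logdet_xtx: float) -> float:
    """Negative profile (RE)ML log-likelihood in delta (sigma_g2 profiled)."""
    n, q = xt.shape
    w = 1.0 / (lam + delta)
    xw = xt * w[:, None]
    a = xt.T @ xw
    b = xw.T @ yt
    try:
        beta = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - xt @ beta
    rss = float(np.sum(w * r * r))
    if rss <= 0:
        return np.inf
    logdet_h = float(np.sum(np.log(lam + delta)))
    if method == "ML":
        s2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet_h + n)
    else:  # REML
        df = n - q
        s2 = rss / df
        sign, logdet_a = np.linalg.slogdet(a)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (df * np.log(2 * np.pi * s2) + logdet_h
                     + logdet_a - logdet_xtx + df)
    return -ll


def fit_null(y: np.ndarray, covariates: np.ndarray, k,
             method: str = "REML") -> MixedModelFit:
    """Fit the null mixed model by profile (RE)ML over delta.

    ``covariates`` must include the intercept column.  ``k`` may be a
    KinshipMatrix, a raw square array, or a precomputed EigenKinship.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    dec = EigenKinship.from_kinship(k)
    if dec.n != len(y) or x.shape[0] != len(y):
        raise ValueError("y, covariates and kinship are not conformable")
    yt = dec.rotate(y)
    xt = dec.rotate(x)
    lam = dec.eigenvalues
    sign, logdet_xtx = np.linalg.slogdet(x.T @ x)
    if sign <= 0:
        raise ValueError("covariate matrix is rank deficient")

    neg = [_profile_neg_loglik(d, lam, yt, xt, method, logdet_xtx)
           for d in _DELTA_GRID]
    i = int(np.argmin(neg))  # argmin takes the first optimum: smaller delta
    lo = _DELTA_GRID[max(i - 1, 0)]
    hi = _DELTA_GRID[min(i + 1, len(_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda t: _profile_neg_loglik(np.exp(t), lam, yt, xt, method,
                                      logdet_xtx),
        bounds=(np.log(lo), np.log(hi)), method="bounded")
    delta = float(np.exp(res.x))
    if res.fun > neg[i]:  # keep the grid point if refinement did not help
        delta, best = float(_DELTA_GRID[i]), neg[i]
    else:
        best = float(res.fun)

    n, q = xt.shape
    w = 1.0 / (lam + delta)
    xw = xt * w[:, None]
    beta = np.linalg.solve(xt.T @ xw, xw.T @ yt)
    r = yt - xt @ beta
    rss = float(np.sum(w * r * r))
    sigma_g2 = rss / (n if method == "ML" else n - q)
    sigma_e2 = delta * sigma_g2
    if sigma_g2 + sigma_e2 == 0:
        raise ValueError("degenerate fit: both variance components zero")
    return MixedModelFit(sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
                         pseudo_h2=1.0 / (1.0 + delta),
                         log_likelihood=-best, method=method)


def estimate_pseudo_h2(fit: MixedModelFit) -> float:
    """Pseudo-heritability: share of variance on the kinship term."""
    tot = fit.sigma_g2 + fit.sigma_e2
    if tot == 0:
        raise ValueError("both variance components are zero")
    return fit.sigma_g2 / tot


# ---------------------------------------------------------------------------
# P3D marker tests
# ---------------------------------------------------------------------------

def p3d_marker_tests(yt: np.ndarray, xt: np.ndarray, gt: np.ndarray,
                     lam: np.ndarray, delta: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Wald tests of each marker added to the covariates, variance fixed.

    All inputs are rotated into the kinship eigenbasis (gt is marker x line).
    Returns (effect, t statistic, p-value, flag) arrays; effect is the GLS
    coefficient per minor-allele copy.  Markers whose dosage is collinear
    with the covariates (or constant) are flagged and reported with p = 1.
    """
    n, q = xt.shape
    sw = np.sqrt(1.0 / (lam + delta))
    a = xt * sw[:, None]
    b = yt * sw
    qmat, _ = np.linalg.qr(a)
    b_perp = b - qmat @ (qmat.T @ b)
    g_w = gt * sw[None, :]
    g_perp = g_w - (g_w @ qmat) @ qmat.T
    gg = np.einsum("ij,ij->i", g_perp, g_perp)
    gb = g_perp @ b_perp
    df = n - q - 1
    scale = np.max(gg) if len(gg) else 1.0
    ok = gg > max(scale, 1.0) * 1e-12
    effect = np.full(len(gg), np.nan)
    tstat = np.zeros(len(gg))
    pval = np.ones(len(gg))
    effect[ok] = gb[ok] / gg[ok]
    rss = float(b_perp @ b_perp) - np.where(ok, gb * effect_safe(effect), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(rss, 1e-300) / df / np.where(ok, gg, 1.0))
        t = np.where(ok, effect_safe(effect) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tstat[ok] = t[ok]
    pval[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    flag = np.where(ok, "", "inestimable")
    return effect, tstat, pval, flag


def effect_safe(effect: np.ndarray) -> np.ndarray:
    return np.nan_to_num(effect, nan=0.0)


@dataclass
class ScanResult:
    """Per-marker association results from a (compressed) mixed-model scan."""

    table: pd.DataFrame  # marker, chrom, pos, maf, effect, stat, p_value,
    #                      minus_log10_p, flag
    fit: MixedModelFit
    n_groups: int
    n_covariates: int

    def pvalues(self) -> pd.Series:
        return self.table.set_index("marker")["p_value"]


@dataclass
class CompressionSweep:
    """Cached eigendecompositions for every candidate compression level.

    Built once per (kinship, covariates, group step); selecting the optimal
    compression for a new trait then costs only 1-D delta optimizations.
    """

    levels: list            # requested group counts
    decomps: list           # EigenKinship per level
    assignments: list       # group labels per level
    covariates: np.ndarray
    group_step: int

    @classmethod
    def build(cls, k: KinshipMatrix, covariates: np.ndarray,
              group_step: int = 20,
              tree: LineDendrogram | None = None) -> "CompressionSweep":
        if group_step < 1:
            raise ValueError("group_step must be >= 1")
        n = k.n_lines
        if tree is None:
            tree = cluster_lines(k)
        levels = list(range(group_step, n, group_step)) + [n]
        decomps, assignments = [], []
        for g_count in levels:
            if g_count == n:
                expanded = k.values
                assignment = np.arange(n)
            else:
                assignment, compressed = compress_kinship(k, g_count, tree)
                expanded = expand_compressed(assignment, compressed)
            decomps.append(EigenKinship.from_kinship(expanded))
            assignments.append(assignment)
        return cls(levels, decomps, assignments,
                   np.asarray(covariates, dtype=float), group_step)

    def select(self, y: np.ndarray) -> tuple[int, MixedModelFit, EigenKinship]:
        """Fit the null at every level; return the likelihood-optimal one."""
        best = None
        for g_count, dec in zip(self.levels, self.decomps):
            fit = fit_null(y, self.covariates, dec, method="REML")
            if best is None or fit.log_likelihood > best[1].log_likelihood:
                best = (g_count, fit, dec)
        return best


def scan_cmlm(y: np.ndarray, g: GenotypeMatrix, covariates: np.ndarray,
              k: KinshipMatrix, group_step: int = 20,
              sweep: CompressionSweep | None = None,
              tree: LineDendrogram | None = None) -> ScanResult:
    """Compressed mixed linear model scan.

    Sweeps candidate group counts (multiples of ``group_step`` plus the
    uncompressed model), keeps the compression whose null REML likelihood is
    highest, and tests each marker as a fixed effect with variance
    components frozen at that null optimum (P3D).  The reported effect is
    the trait change per minor-allele copy, i.e. half the opposite-homozygote
    difference.
    """
    y = np.asarray(y, dtype=float)
    if sweep is None:
        sweep = CompressionSweep.build(k, covariates, group_step, tree)
    n_groups, fit, dec = sweep.select(y)
    yt = dec.rotate(y)
    xt = dec.rotate(sweep.covariates)
    gt = g.dosages.astype(float) @ dec.eigenvectors  # marker x line rotated
    effect, tstat, pval, flag = p3d_marker_tests(
        yt, xt, gt, dec.eigenvalues, fit.delta)
    table = pd.DataFrame({
        "marker": g.markers["name"].to_numpy(),
        "chrom": g.markers["chrom"].to_numpy(),
        "pos": g.markers["pos"].to_numpy(),
        "maf": g.maf(),
        "effect": effect,
        "stat": tstat,
        "p_value": pval,
        "minus_log10_p": -np.log10(pval),
        "flag": flag,
    })
    return ScanResult(table=table, fit=fit, n_groups=n_groups,
                      n_covariates=sweep.covariates.shape[1])


def write_scan(result: ScanResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)
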