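"""Regional linkage disequilibrium, sliding-window Tajima's D, and
allele-distribution / enrichment operations.

These diagnostics target highly inbred panels: a homozygous genotype is its
own haplotype, so two-locus haplotype frequencies (for D') can be read
directly from homozygous genotype pairs, with no phasing.  Residual
heterozygous calls are excluded pairwise (LD) or per site (diversity).

Tajima's D is computed over sliding windows of a fixed number of markers so
that monomorphic markers count toward a window's footprint: a window's S is
its polymorphic-site count, monomorphic sites contribute zero to both S and
the pairwise diversity, and the constants use n = number of lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PhenotypeTable
from .popstruct import LineDendrogram


@dataclass
class LDMatrix:
    r2: np.ndarray
    d_prime: np.ndarray
    markers: pd.DataFrame  # name, chrom, pos of retained markers
    region: tuple  # (chrom, start bp, end bp)

    def to_long(self) -> pd.DataFrame:
        names = self.markers["name"].to_numpy()
        rows = []
        for i in range(len(names)):
            for j in range(i, len(names)):
                rows.append((names[i], names[j],
                             self.r2[i, j], self.d_prime[i, j]))
        return pd.DataFrame(rows,
                            columns=["marker_a", "marker_b", "r2", "d_prime"])


@dataclass
class DiversityWindows:
    table: pd.DataFrame  # chrom, start_bp, end_bp, first/last marker,
    #                      n_markers, S, pi, tajimas_d, truncated
    width: int
    step: int


def _tajima_constants(n: int) -> tuple[float, float, float]:
    """a1, e1, e2 of Tajima's test for n sampled sequences."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites, pairwise diversity, sample size."""
    if S == 0 or n < 4:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def _site_stats(dosage_row: np.ndarray) -> tuple[int, float]:
    """(is-polymorphic, per-site pairwise diversity) for one marker.

    Lines are treated as haplotypes; heterozygous or missing calls are
    excluded at this site, and the per-site diversity is estimated from the
    remaining m homozygous calls as k(m-k)/C(m,2).
    """
    hom = (dosage_row == 0) | (dosage_row == 2)
    m = int(hom.sum())
    if m < 2:
        return 0, 0.0
    k = int((dosage_row[hom] == 2).sum())
    if k == 0 or k == m:
        return 0, 0.0
    return 1, k * (m - k) / (m * (m - 1) / 2.0)


def tajimas_d_windows(g_all: GenotypeMatrix, width: int = 20,
                      step: int = 10) -> DiversityWindows:
    """Sliding-window Tajima's D over all markers, monomorphic included.

    ``g_all`` must come from an ingestion path with no MAF filter so that
    monomorphic markers occupy window slots.  Windows advance by ``step``
    markers within each chromosome; a trailing window shorter than ``width``
    is emitted with its actual width and flagged.
    """
    if width < 2 or step < 1:
        raise ValueError("need width >= 2 and step >= 1")
    n = g_all.n_lines
    rows = []
    for chrom, idx in g_all.markers.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        start = 0
        while start < len(idx):
            sel = idx[start:start + width]
            poly, pis = zip(*(_site_stats(g_all.dosages[j]) for j in sel))
            S = int(sum(poly))
            pi = float(sum(pis))
            rows.append({
                "chrom": chrom,
                "start_bp": int(g_all.markers["pos"].iloc[sel[0]]),
                "end_bp": int(g_all.markers["pos"].iloc[sel[-1]]),
                "first_marker": g_all.markers["name"].iloc[sel[0]],
                "last_marker": g_all.markers["name"].iloc[sel[-1]],
                "n_markers": len(sel),
                "S": S,
                "pi": pi,
                "tajimas_d": tajimas_d(S, pi, n),
                "truncated": len(sel) < width,
            })
            if start + width >= len(idx):
                break
            start += step
    return DiversityWindows(pd.DataFrame(rows), width, step)


def ld_region(g: GenotypeMatrix, region: tuple) -> LDMatrix:
    """Pairwise r2 and D' for MAF > 0.05 markers inside a region.

    ``region`` is (chrom, start bp, end bp), bounds inclusive.  r2 is the
    squared Pearson correlation of dosage/2 over lines homozygous at both
    markers of a pair; D' uses two-locus haplotype frequencies read directly
    from those homozygous genotype pairs.
    """
    chrom, start, end = region
    in_region = ((g.markers["chrom"] == chrom)
                 & (g.markers["pos"] >= start)
                 & (g.markers["pos"] <= end)).to_numpy()
    maf_ok = g.maf() > 0.05
    sel = np.where(in_region & maf_ok)[0]
    markers = g.markers.iloc[sel][["name", "chrom", "pos"]] \
        .reset_index(drop=True)
    if len(sel) < 2:
        import warnings
        warnings.warn(f"region {region} has {len(sel)} polymorphic markers; "
                      "empty LD matrix")
        z = np.zeros((len(sel), len(sel)))
        return LDMatrix(z, z.copy(), markers, region)

    d = g.dosages[sel].astype(float)
    hom = (d == 0) | (d == 2)
    h = d / 2.0  # haplotype allele indicator for homozygous calls
    m = len(sel)
    r2 = np.eye(m)
    dp = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            ok = hom[i] & hom[j]
            n_ok = int(ok.sum())
            if n_ok < 2:
                r2[i, j] = r2[j, i] = np.nan
                dp[i, j] = dp[j, i] = np.nan
                continue
            a, b = h[i, ok], h[j, ok]
            pa, pb = a.mean(), b.mean()
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                r2[i, j] = r2[j, i] = np.nan
                dp[i, j] = dp[j, i] = np.nan
                continue
            pab = float((a * b).mean())
            dd = pab - pa * pb
            r2_ij = dd * dd / (pa * (1 - pa) * pb * (1 - pb))
            if dd >= 0:
                dmax = min(pa * (1 - pb), (1 - pa) * pb)
            else:
                dmax = min(pa * pb, (1 - pa) * (1 - pb))
            dp_ij = abs(dd) / dmax if dmax > 0 else np.nan
            r2[i, j] = r2[j, i] = r2_ij
            dp[i, j] = dp[j, i] = dp_ij
    return LDMatrix(r2, dp, markers, region)


def allele_trait_table(g: GenotypeMatrix, trait: PhenotypeTable,
                       markers: list[str], dendrogram: LineDendrogram,
                       trait_name: str | None = None) -> pd.DataFrame:
    """Lines in dendrogram leaf order with allele calls and trait value.

    The tabular backing of an allele-distribution heatmap: one row per line,
    one column per requested marker carrying the nucleotide the line is
    homozygous for (het/missing shown as 'N'), plus the trait value.
    """
    name_to_idx = {n: i for i, n in enumerate(g.markers["name"])}
    unknown = [m for m in markers if m not in name_to_idx]
    if unknown:
        raise KeyError(f"unknown markers: {unknown}")
    if trait_name is None:
        trait_name = trait.records["trait"].iloc[0]
    vals, matched, _ = trait.trait_vector(trait_name, g.line_ids)
    lut = dict(zip(matched, vals))
    order = dendrogram.leaf_order
    rows = []
    for li in order:
        lid = g.line_ids[li]
        row = {"line_id": lid, trait_name: lut.get(lid, np.nan)}
        for mk in markers:
            j = name_to_idx[mk]
            dos = int(g.dosages[j, li])
            if dos == 0:
                row[mk] = str(g.markers["major"].iloc[j])
            elif dos == 2:
                row[mk] = str(g.markers["minor"].iloc[j])
            else:
                row[mk] = "N"
            row[f"{mk}_dosage"] = dos if dos != MISSING else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def enrich_minor_allele(g: GenotypeMatrix, marker: str, seed: int = 0
                        ) -> list[str]:
    """Line subset enriching a marker's minor allele to frequency 0.5.

    Keeps every minor-allele homozygote and adds an equal-size uniform
    random sample of major-allele homozygotes.
    """
    idx = g.markers.index[g.markers["name"] == marker]
    if len(idx) == 0:
        raise KeyError(f"unknown marker {marker!r}")
    row = g.dosages[int(idx[0])]
    minor_lines = np.where(row == 2)[0]
    major_lines = np.where(row == 0)[0]
    if len(minor_lines) == 0:
        raise ValueError(f"marker {marker!r} has no minor-allele homozygotes")
    if len(minor_lines) > len(major_lines):
        raise ValueError(
            f"minor class ({len(minor_lines)}) exceeds major class "
            f"({len(major_lines)}); cannot balance to 0.5")
    rng = np.random.default_rng(seed)
    sampled = rng.choice(major_lines, size=len(minor_lines), replace=False)
    chosen = np.concatenate([minor_lines, sampled])
    ids = np.asarray(g.line_ids)
    return ids[np.sort(chosen)].tolist()
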