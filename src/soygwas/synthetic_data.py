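"""Structured inbred panels and simulated quantitative traits.

The genotype generator emulates a soybean-like association panel: ~900
nearly fully homozygous lines drawn from a few unequal subpopulations,
~30,000 biallelic SNPs on 20 chromosomes, block-wise linkage disequilibrium
that decays with marker distance, and a minor-allele-frequency spectrum
skewed toward rare variants.  Subpopulation allele frequencies follow the
Balding-Nichols model around a low-frequency-skewed ancestral spectrum, and
lines copy chromosome segments from a finite founder-haplotype pool so that
LD exists within chromosomes and vanishes between them.

Traits are additive: a set of causal markers (QTL) sampled uniformly from
the MAF > 0.05 markers, per-QTL effects from a uniform or linearly declining
distribution normalised to sum to 1, and Gaussian residuals scaled so the
narrow-sense heritability matches its target in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

_NUC = np.array(list("ACGT"))


@dataclass
class PanelSpec:
    """Parameters of a simulated inbred association panel.

    Defaults mirror the emulated study panel: 900 lines in 3 unequal
    subpopulations, 30,000 SNPs on 20 chromosomes, F_ST 0.15, founder-segment
    length 20 markers, and a residual heterozygosity of 1e-3 (roughly one
    heterozygous call per 1,000 SNPs, as seen in inbred soybean).
    """

    n_lines: int = 900
    n_markers: int = 30_000
    n_chromosomes: int = 20
    n_subpops: int = 3
    subpop_proportions: tuple = (0.5, 0.3, 0.2)
    fst: float = 0.15
    ld_block_length: int = 20
    residual_het_rate: float = 1e-3
    n_founders: int = 30  # founder haplotypes per subpopulation
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.subpop_proportions, dtype=float)
        if len(props) != self.n_subpops:
            raise ValueError("subpop_proportions length != n_subpops")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subpop proportions must sum to 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if self.ld_block_length < 1:
            raise ValueError("ld_block_length must be >= 1")


@dataclass
class ArchitectureSpec:
    """A simulated genetic architecture: QTL count, effect law, heritability."""

    n_qtl: int
    effect_distribution: str  # "uniform" | "linear"
    h2: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        if self.effect_distribution not in {"uniform", "linear"}:
            raise ValueError(f"unknown effect distribution "
                             f"{self.effect_distribution!r}")

    def label(self) -> str:
        return (f"{self.n_qtl}qtl_{self.effect_distribution}"
                f"_h2_{self.h2:g}")


@dataclass
class QTLAssignment:
    """Sampled causal markers with their additive allelic effects.

    ``effects[i]`` is the phenotypic difference between opposite homozygotes
    at ``qtl_markers[i]`` (per-QTL effects sum to 1, so 1 is the maximum total
    genotypic effect in any simulation).  Effects are stored sorted
    descending; rank 1 = strongest.
    """

    qtl_markers: np.ndarray  # marker indices into the panel
    effects: np.ndarray

    def __post_init__(self) -> None:
        self.qtl_markers = np.asarray(self.qtl_markers, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.qtl_markers) != len(self.effects):
            raise ValueError("qtl_markers and effects length mismatch")
        if (self.effects <= 0).any():
            raise ValueError("effects must be strictly positive")


@dataclass
class SimulatedTrait:
    phenotype: np.ndarray
    genetic_value: np.ndarray
    residual_sd: float
    h2: float
    assignment: QTLAssignment
    seed: int = 0


def simulate_genotypes(spec: PanelSpec) -> GenotypeMatrix:
    """Generate a structured inbred genotype panel.

    Model: ancestral minor-allele frequencies are log-uniform on
    [0.02, 0.5] (rare-skewed spectrum); each subpopulation's frequency is a
    Balding-Nichols draw Beta(p(1-F)/F, (1-p)(1-F)/F); each subpopulation
    carries ``n_founders`` founder haplotypes sampled from those frequencies;
    each line walks along each chromosome copying a founder haplotype and
    switching to a fresh founder with probability 1/ld_block_length per
    marker step.  The walk restarts on every chromosome, so LD decays
    geometrically with marker distance within chromosomes and is absent
    between them.  Lines are homozygous (dosage 0/2) except for entries
    flipped to dosage 1 at ``residual_het_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n_m, n_l = spec.n_markers, spec.n_lines

    # markers per chromosome: distribute remainder, never fail
    base = n_m // spec.n_chromosomes
    counts = np.full(spec.n_chromosomes, base, dtype=int)
    counts[: n_m - base * spec.n_chromosomes] += 1

    # ancestral frequencies: log-uniform, folded spectrum heavy at low MAF
    lo, hi = 0.02, 0.5
    p_anc = lo * (hi / lo) ** rng.random(n_m)

    # subpopulation frequencies (Balding-Nichols)
    F = spec.fst
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p_sub = np.stack([np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
                      for _ in range(spec.n_subpops)])  # subpop x marker

    # line -> subpopulation (deterministic proportional split)
    props = np.asarray(spec.subpop_proportions, dtype=float)
    sizes = np.floor(props * n_l).astype(int)
    sizes[-1] = n_l - sizes[:-1].sum()
    subpop_of = np.repeat(np.arange(spec.n_subpops), sizes)

    # founder haplotypes per subpopulation: founders x markers (0/1 minor)
    founders = (rng.random((spec.n_subpops, spec.n_founders, n_m))
                < p_sub[:, None, :]).astype(np.int8)

    r = 1.0 / spec.ld_block_length  # per-step founder-switch probability
    hap = np.empty((n_l, n_m), dtype=np.int8)
    chrom_starts = np.concatenate([[0], np.cumsum(counts)])
    for s in range(spec.n_subpops):
        rows = np.where(subpop_of == s)[0]
        if len(rows) == 0:
            continue
        fidx = np.empty((len(rows), n_m), dtype=np.int32)
        for c in range(spec.n_chromosomes):
            lo_i, hi_i = chrom_starts[c], chrom_starts[c + 1]
            span = hi_i - lo_i
            if span == 0:
                continue
            switch = rng.random((len(rows), span)) < r
            switch[:, 0] = True  # restart on each chromosome
            new_f = rng.integers(0, spec.n_founders,
                                 size=(len(rows), span), dtype=np.int32)
            # carry the last switched-to founder forward
            idx = np.where(switch, np.arange(span), 0)
            idx = np.maximum.accumulate(idx, axis=1)
            fidx[:, lo_i:hi_i] = np.take_along_axis(new_f, idx, axis=1)
        hap[rows] = founders[s][fidx, np.arange(n_m)[None, :]]

    dos = (2 * hap).T.astype(np.int8)  # markers x lines
    if spec.residual_het_rate > 0:
        het = rng.random(dos.shape) < spec.residual_het_rate
        dos[het] = 1

    # coordinates: sorted random positions per chromosome
    names, chroms, poss = [], [], []
    for c in range(spec.n_chromosomes):
        pos = np.sort(rng.integers(1, 50_000_000, size=counts[c]))
        pos += np.arange(counts[c])  # force strictly increasing positions
        for p_ in pos:
            names.append(f"SYN1.01Gm{c + 1:02d}_{p_}")
            chroms.append(c + 1)
            poss.append(int(p_))

    pair = rng.permuted(np.tile(_NUC, (n_m, 1)), axis=1)[:, :2]
    markers = pd.DataFrame({"name": names, "chrom": chroms, "pos": poss,
                            "minor": pair[:, 0], "major": pair[:, 1]})
    lines = pd.DataFrame({
        "line_id": [f"L{i:04d}" for i in range(n_l)],
        "country": [f"C{s}" for s in subpop_of],
        "maturity_group": None,
        "subpop": subpop_of,
    })
    g = GenotypeMatrix(dos, markers, lines)
    g.recompute_minor()
    return g


def draw_qtl(g: GenotypeMatrix, n_qtl: int, seed: int) -> np.ndarray:
    """Sample causal-marker indices uniformly from markers with MAF > 0.05."""
    eligible = np.where(g.maf() > 0.05)[0]
    if len(eligible) < n_qtl:
        raise ValueError(
            f"need {n_qtl} markers with MAF > 0.05, only {len(eligible)} "
            "eligible")
    rng = np.random.default_rng(seed)
    # kept in sampled order: effects attach to markers as drawn
    return rng.choice(eligible, size=n_qtl, replace=False)


def effect_sizes(n: int, distribution: str) -> np.ndarray:
    """Per-QTL allelic effects summing to 1, sorted descending.

    uniform: every QTL gets 1/n.  linear: effects decline linearly toward
    (but never reaching) zero, e_k = 2(n+1-k) / (n(n+1)) for k = 1..n; the
    largest is 2/(n+1), which evaluates to 0.4 at n = 4.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if distribution == "uniform":
        return np.full(n, 1.0 / n)
    if distribution == "linear":
        k = np.arange(1, n + 1)
        return 2.0 * (n + 1 - k) / (n * (n + 1.0))
    raise ValueError(f"unknown effect distribution {distribution!r}")


def make_assignment(g: GenotypeMatrix, arch: ArchitectureSpec
                    ) -> QTLAssignment:
    """Draw QTL and attach effects (largest effect to first sampled marker)."""
    idx = draw_qtl(g, arch.n_qtl, arch.seed)
    eff = effect_sizes(arch.n_qtl, arch.effect_distribution)
    return QTLAssignment(qtl_markers=idx, effects=eff)


def simulate_phenotype(g: GenotypeMatrix, assignment: QTLAssignment,
                       h2: float, seed: int) -> SimulatedTrait:
    """Additive phenotype: genetic value plus heritability-scaled noise.

    The genetic value of line i is sum_k effect_k * dosage_ik / 2, so a
    heterozygote is exactly intermediate between the homozygotes and an
    effect of 1 is the full opposite-homozygote difference.  Residuals are
    i.i.d. Normal(0, sigma_e^2) with sigma_e^2 = Var(g) (1 - h2) / h2
    (sample variance, ddof=1), which makes realized narrow-sense
    heritability match the target in expectation.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    if (assignment.qtl_markers >= g.n_markers).any():
        raise ValueError("assignment refers to markers outside the panel")
    dos = g.dosages[assignment.qtl_markers].astype(float)  # qtl x lines
    if (dos < 0).any():
        raise ValueError("impute missing dosages before simulating")
    gv = (assignment.effects @ dos) / 2.0
    var_g = float(np.var(gv, ddof=1))
    if var_g == 0.0:
        raise ValueError("all lines genetically identical at the QTL; "
                         "cannot target a heritability")
    sigma_e = float(np.sqrt(var_g * (1.0 - h2) / h2))
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma_e, size=g.n_lines) if sigma_e > 0 \
        else np.zeros(g.n_lines)
    return SimulatedTrait(phenotype=gv + eps, genetic_value=gv,
                          residual_sd=sigma_e, h2=h2,
                          assignment=assignment, seed=seed)


def write_trait(trait: SimulatedTrait, g: GenotypeMatrix, trait_name: str,
                pheno_path, sidecar_path) -> None:
    """Write phenotype TSV plus a JSON sidecar naming QTL, effects, seeds."""
    df = pd.DataFrame({"line_id": g.line_ids, "trait": trait_name,
                       "value": trait.phenotype})
    df.to_csv(pheno_path, sep="\t", index=False)
    names = g.markers["name"].iloc[trait.assignment.qtl_markers].tolist()
    with open(sidecar_path, "w") as fh:
        json.dump({
            "trait": trait_name,
            "h2": trait.h2,
            "residual_sd": trait.residual_sd,
            "seed": trait.seed,
            "qtl": [{"marker": n, "effect": float(e)}
                    for n, e in zip(names, trait.assignment.effects)],
        }, fh, indent=2)
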