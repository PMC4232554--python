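"""End-to-end trait scans, cross-population concordance, and plot exports.

`run_trait_scan` wires the full pipeline: ingestion -> replicate averaging
-> line matching -> MAF filter -> imputation -> kinship/PCA -> compressed
scan -> heterozygote resolution -> multi-locus scan -> dual-model report,
with a structured JSONL log (one event per stage, with seeds and counts).

Concordance reproduces the reporting conventions of multi-population
tables: a reported marker is flagged as shared across populations (or
across traits) when another report contains a marker on the same chromosome
within a configurable window — 4 Mbp for broadly mapped seed-composition
traits, 200 Kbp for fine-mapped amino-acid traits, boundary inclusive.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from .mlm_core import MixedModelFit, ScanResult, scan_cmlm
from .mlmm import StepwisePath, dual_model_report, mlmm_scan
from .popstruct import cluster_lines, kinship, pca


@dataclass
class ScanConfig:
    """Configuration of one trait scan; serializes round-trip via YAML."""

    population: str
    genotype_path: str
    genotype_format: str
    phenotype_path: str
    trait: str
    maf_threshold: float = 0.05
    n_pcs: int = 3
    group_step: int = 20
    kinship_marker_fraction: float = 1.0
    report_threshold: float = 1e-4
    max_steps: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold out of range")
        if not (0.0 < self.kinship_marker_fraction <= 1.0):
            raise ValueError("kinship_marker_fraction out of range")
        if not (0.0 < self.report_threshold < 1.0):
            raise ValueError("report_threshold out of range")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageLogger:
    """JSONL stage log; events carry seeds and in/out counts."""

    def __init__(self, path=None):
        self.path = Path(path) if path else None
        self.events = []

    def log(self, stage: str, **payload) -> None:
        event = {"stage": stage, "wall_time": time.time(), **payload}
        self.events.append(event)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(event) + "\n")


def run_trait_scan(config: ScanConfig, log_path=None
                   ) -> tuple[ScanResult, StepwisePath, pd.DataFrame,
                              MixedModelFit]:
    """Execute the full pipeline for one (population, trait) dataset.

    Returns (compressed-scan result, stepwise path, dual-model report,
    null mixed-model fit carrying the trait's pseudo-heritability).
    """
    log = StageLogger(log_path)
    seed = config.master_seed

    g = gio.read_genotypes(config.genotype_path, config.genotype_format)
    log.log("ingest_genotypes", markers=g.n_markers, lines=g.n_lines)
    phen = gio.average_replicates(gio.read_phenotypes(config.phenotype_path))
    y, matched, unmatched = phen.trait_vector(config.trait, g.line_ids)
    log.log("match_phenotypes", matched=len(matched),
            unmatched=len(unmatched), unmatched_ids=unmatched[:20])
    if len(matched) < 50:
        raise ValueError(f"only {len(matched)} lines have both genotype and "
                         f"phenotype; need >= 50")
    g = g.subset_lines(matched)

    g = gio.impute_missing(g, seed=seed + 1)
    g = gio.filter_maf(g, config.maf_threshold)
    log.log("filter_maf", threshold=config.maf_threshold,
            markers=g.n_markers, seed=seed + 1)

    k = kinship(g, config.kinship_marker_fraction, seed=seed + 2)
    pcs = pca(g, config.n_pcs)
    covar = np.column_stack([np.ones(g.n_lines), pcs.scores])
    log.log("kinship_pca", marker_fraction=config.kinship_marker_fraction,
            seed=seed + 2, n_pcs=config.n_pcs)

    cmlm = scan_cmlm(y, g, covar, k, config.group_step)
    log.log("cmlm_scan", n_groups=cmlm.n_groups,
            pseudo_h2=cmlm.fit.pseudo_h2)

    g_hom = gio.resolve_heterozygotes(g, seed=seed + 3)
    path = mlmm_scan(y, g_hom, covar, k, max_steps=config.max_steps,
                     het_seed=seed + 3)
    log.log("mlmm_scan", selected_size=path.selected_size, seed=seed + 3)

    report = dual_model_report(cmlm, path, config.report_threshold)
    log.log("dual_report", threshold=config.report_threshold,
            n_reported=len(report))
    return cmlm, path, report, cmlm.fit


def abbreviate_marker(name: str) -> str:
    """Reduce a marker name to chromosome_position form
    (e.g. BARC1.01Gm08_8462762 -> 8_8462762)."""
    try:
        chrom, pos = gio.parse_marker_name(name)
        return f"{chrom}_{pos}"
    except gio.GenotypeParseError:
        return name


def concordance(reports: list[tuple[str, str, pd.DataFrame]],
                window_bp: int) -> pd.DataFrame:
    """Flag markers shared across populations and across traits.

    ``reports`` is a list of (population, trait, dual-model report table).
    Two reported markers match when they sit on the same chromosome within
    ``window_bp`` (inclusive).  A marker is shared_across_populations when a
    match comes from a different population-dataset of the same trait, and
    shared_across_traits when it comes from a different trait.  Flags are
    symmetric by construction.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 reports for concordance")
    rows = []
    for pop, trait, tab in reports:
        for _, r in tab.iterrows():
            rows.append({"population": pop, "trait": trait,
                         "marker": r["marker"], "chrom": r["chrom"],
                         "pos": r["pos"], "p_cmlm": r["p_cmlm"],
                         "p_mlmm": r["p_mlmm"],
                         "allelic_effect": r["allelic_effect"]})
    df = pd.DataFrame(rows)
    if df.empty:
        df["shared_across_populations"] = []
        df["shared_across_traits"] = []
        df["window_bp"] = []
        return df
    shared_pop = np.zeros(len(df), dtype=bool)
    shared_trait = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        for j in range(len(df)):
            if i == j:
                continue
            a, b = df.iloc[i], df.iloc[j]
            if a["chrom"] != b["chrom"]:
                continue
            if abs(int(a["pos"]) - int(b["pos"])) > window_bp:
                continue
            if a["trait"] == b["trait"] \
                    and a["population"] != b["population"]:
                shared_pop[i] = True
            if a["trait"] != b["trait"]:
                shared_trait[i] = True
    df["shared_across_populations"] = shared_pop
    df["shared_across_traits"] = shared_trait
    df["window_bp"] = window_bp
    df["marker_short"] = df["marker"].map(abbreviate_marker)
    return df


def manhattan_export(cmlm: ScanResult, path: StepwisePath,
                     threshold_line: float = 1e-5) -> pd.DataFrame:
    """Plot-ready table: cumulative genome coordinate, -log10 p, shading
    parity, multi-locus selection flag and discovery order."""
    tab = cmlm.table.copy()
    offsets = {}
    cum = 0
    for chrom, sub in tab.groupby("chrom", sort=True):
        offsets[chrom] = cum
        cum += int(sub["pos"].max()) + 1
    tab["cumulative_pos"] = [int(p) + offsets[c]
                             for c, p in zip(tab["chrom"], tab["pos"])]
    tab["chrom_parity"] = tab["chrom"].astype(int) % 2
    order = path.cofactor_order()
    tab["mlmm_selected"] = tab["marker"].isin(order)
    tab["mlmm_order"] = tab["marker"].map(order)
    tab["mlmm_minus_log10_p"] = -np.log10(
        path.selected_pvalues.reindex(tab["marker"]).to_numpy())
    tab["threshold_minus_log10_p"] = -np.log10(threshold_line)
    return tab.sort_values("cumulative_pos").reset_index(drop=True)
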