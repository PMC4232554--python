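#!/usr/bin/env python
"""Generate the study's synthetic association panel and an example trait.

Emulates a soybean-like panel: 900 nearly homozygous lines in three unequal
subpopulations, 5,000 SNPs on 20 chromosomes (a desk-scale stand-in for a
~30k-SNP array), block-wise LD, and a rare-skewed MAF spectrum.  Writes the
panel in the marker x line TSV dialect plus one simulated trait (20 QTL,
linear effects, h2 = 0.5) with its QTL sidecar.
"""

from pathlib import Path

import numpy as np

from soygwas import (ArchitectureSpec, make_assignment, simulate_genotypes,
                     simulate_phenotype)
from soygwas.genotype_io import write_genotypes
from soygwas.synthetic_data import PanelSpec, write_trait

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 5


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    panel = simulate_genotypes(PanelSpec(n_lines=900, n_markers=5000,
                                         seed=SEED))
    write_genotypes(panel, SCRATCH / "panel.tsv", "tsv")
    # passport-style line metadata (the dosage TSV carries only IDs)
    panel.lines.to_csv(SCRATCH / "panel_lines.tsv", sep="\t", index=False)
    maf = panel.maf()
    print(f"panel: {panel.n_markers} markers x {panel.n_lines} lines, "
          f"{panel.lines['subpop'].nunique()} subpopulations")
    print(f"median MAF {np.median(maf):.3f}; "
          f"{(maf < 0.25).mean():.0%} of markers below MAF 0.25; "
          f"heterozygous calls {(panel.dosages == 1).mean():.4%}")

    arch = ArchitectureSpec(20, "linear", 0.5, seed=SEED + 1)
    assignment = make_assignment(panel, arch)
    trait = simulate_phenotype(panel, assignment, arch.h2, seed=SEED + 2)
    write_trait(trait, panel, "sim_protein", OUT / "trait_sim.tsv",
                OUT / "trait_sim_qtl.json")
    print(f"trait: {arch.n_qtl} QTL, {arch.effect_distribution} effects, "
          f"target h2 {arch.h2}; residual sd {trait.residual_sd:.4f}")


if __name__ == "__main__":
    main()
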