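#!/usr/bin/env python
"""Diversity diagnostics: sliding-window Tajima's D, regional LD, and
minor-allele enrichment around the strongest association.

Tajima's D runs over all markers (monomorphic included) in 20-marker
windows stepping by 10.  The LD matrix (r2 above, D' below the diagonal in
the plotted rendering; exported long-form here) covers the region around
the top scan hit from 03_trait_scan.  The enrichment operation balances the
top marker's minor allele to frequency 0.5, the design used to test whether
a rare allele's phenotypic contrast survives in a balanced subpanel.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from soygwas import (allele_trait_table, cluster_lines, enrich_minor_allele,
                     kinship, ld_region, tajimas_d_windows)
from soygwas.genotype_io import read_genotypes, read_phenotypes

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    panel = read_genotypes(SCRATCH / "panel.tsv", "tsv")  # unfiltered ingestion
    windows = tajimas_d_windows(panel, width=20, step=10)
    windows.table.to_csv(OUT / "tajimas_d_windows.tsv", sep="\t",
                         index=False)
    d = windows.table["tajimas_d"]
    print(f"{len(windows.table)} windows; median Tajima's D "
          f"{np.nanmedian(d):.2f}, range [{np.nanmin(d):.2f}, "
          f"{np.nanmax(d):.2f}]")

    scan = pd.read_csv(SCRATCH / "scan_POPA_cmlm.tsv", sep="\t")
    top = scan.loc[scan["p_value"].idxmin()]
    chrom, pos = int(top["chrom"]), int(top["pos"])
    region = (chrom, max(1, pos - 4_000_000), pos + 4_000_000)
    ld = ld_region(panel, region)
    ld.to_long().round(4).to_csv(OUT / "ld_top_region.tsv", sep="\t",
                                 index=False)
    mean_r2 = np.nanmean(ld.r2[np.triu_indices(len(ld.markers), 1)])
    print(f"LD region around {top['marker']}: {len(ld.markers)} markers, "
          f"mean r2 {mean_r2:.3f}")

    pheno = read_phenotypes(OUT / "trait_sim.tsv")
    tree = cluster_lines(kinship(panel))
    table = allele_trait_table(panel, pheno, [top["marker"]], tree)
    table.to_csv(OUT / "allele_trait_table.tsv", sep="\t", index=False)

    enriched = enrich_minor_allele(panel, top["marker"], seed=11)
    pd.Series(enriched, name="line_id").to_csv(
        OUT / "enriched_lines.tsv", sep="\t", index=False)
    sub = panel.subset_lines(enriched)
    j = sub.markers.index[sub.markers["name"] == top["marker"]][0]
    print(f"enriched subpanel: {sub.n_lines} lines, top-marker MAF "
          f"{sub.maf()[j]:.2f}")


if __name__ == "__main__":
    main()
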