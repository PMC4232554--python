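"""Shared fixtures: synthetic panels at the study scale and a small scale.

The large panel (900 lines x 5,000 markers, 3 unequal subpopulations)
matches the conditions of the power and calibration studies; its kinship,
principal components, cluster tree and compression-sweep eigendecompositions
depend only on the panel, so they are built once per session and shared.
"""

import numpy as np
import pytest

from soygwas import cluster_lines, kinship, pca, resolve_heterozygotes, \
    simulate_genotypes
from soygwas.mlm_core import CompressionSweep
from soygwas.synthetic_data import PanelSpec


@pytest.fixture(scope="session")
def big_panel():
    return simulate_genotypes(PanelSpec(n_lines=900, n_markers=5000, seed=5))


@pytest.fixture(scope="session")
def big_ctx(big_panel):
    """Kinship, covariates and cached compression sweep for the big panel."""
    k = kinship(big_panel)
    pcs = pca(big_panel, 3)
    covar = np.column_stack([np.ones(big_panel.n_lines), pcs.scores])
    tree = cluster_lines(k)
    sweep = CompressionSweep.build(k, covar, 20, tree)
    g_hom = resolve_heterozygotes(big_panel, 977)
    return {"k": k, "covar": covar, "tree": tree, "sweep": sweep,
            "g_hom": g_hom}


@pytest.fixture(scope="session")
def small_panel():
    return simulate_genotypes(PanelSpec(
        n_lines=300, n_markers=1500, n_subpops=2,
        subpop_proportions=(0.6, 0.4), seed=7))


@pytest.fixture(scope="session")
def flat_panel():
    """Unstructured panel: one subpopulation, minimal differentiation,
    no within-chromosome LD blocks."""
    return simulate_genotypes(PanelSpec(
        n_lines=500, n_markers=1200, n_subpops=1, subpop_proportions=(1.0,),
        fst=0.01, ld_block_length=1, residual_het_rate=0.0, seed=13))
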