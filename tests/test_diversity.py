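"""LD measures, sliding-window Tajima's D, allele tables and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soygwas import (GenotypeMatrix, PhenotypeTable, QTLAssignment,
                     allele_trait_table, cluster_lines, enrich_minor_allele,
                     kinship, ld_region, simulate_phenotype, tajimas_d,
                     tajimas_d_windows)
from soygwas.synthetic_data import PanelSpec, simulate_genotypes


def matrix_from(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    chrom = chrom if chrom is not None else np.ones(m, dtype=int)
    pos = pos if pos is not None else np.arange(1, m + 1)
    markers = pd.DataFrame({
        "name": [f"V1.01Gm{c:02d}_{p}" for c, p in zip(chrom, pos)],
        "chrom": chrom, "pos": pos, "minor": "A", "major": "T"})
    lines = pd.DataFrame({"line_id": [f"L{i}" for i in range(n)]})
    return GenotypeMatrix(dosages, markers, lines)


def brute_force_tajima(hap):
    """Independent evaluation of Tajima's formula on 0/1 haplotypes."""
    n, m = hap.shape
    S = sum(1 for j in range(m) if 0 < hap[:, j].sum() < n)
    pi = sum((hap[i] != hap[j]).sum()
             for i, j in itertools.combinations(range(n), 2))
    pi /= n * (n - 1) / 2
    i = np.arange(1, n)
    a1, a2 = (1 / i).sum(), (1 / i ** 2).sum()
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_monomorphic_window_is_na(self):
        g = matrix_from(np.zeros((20, 10), dtype=np.int8))
        out = tajimas_d_windows(g, width=20, step=10)
        assert np.isnan(out.table["tajimas_d"]).all()
        assert (out.table["S"] == 0).all()

    def test_singleton_excess_negative(self):
        """All polymorphic sites singletons: pi is small, S/a1 large."""
        dos = np.zeros((20, 10), dtype=np.int8)
        for j in range(20):
            dos[j, j % 10] = 2
        out = tajimas_d_windows(matrix_from(dos), width=20, step=10)
        assert out.table["tajimas_d"].iloc[0] < 0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        dos = rng.choice([0, 2], size=(20, 10)).astype(np.int8)
        out = tajimas_d_windows(matrix_from(dos), width=20, step=10)
        expected = brute_force_tajima(dos.T // 2)
        assert out.table["tajimas_d"].iloc[0] == \
            pytest.approx(expected, abs=1e-10)

    def test_windowing_tiles_with_overlap(self):
        rng = np.random.default_rng(1)
        dos = rng.choice([0, 2], size=(55, 8)).astype(np.int8)
        out = tajimas_d_windows(matrix_from(dos), width=20, step=10)
        t = out.table
        # starts advance by `step` markers; trailing short window flagged
        assert len(t) == 5
        assert t["truncated"].iloc[-1]
        assert (~t["truncated"].iloc[:-1]).all()

    def test_whole_region_consistency(self):
        rng = np.random.default_rng(2)
        dos = rng.choice([0, 2], size=(40, 12)).astype(np.int8)
        g = matrix_from(dos)
        whole = tajimas_d_windows(g, width=40, step=99).table
        assert len(whole) == 1
        expected = brute_force_tajima(dos.T // 2)
        assert whole["tajimas_d"].iloc[0] == pytest.approx(expected,
                                                           abs=1e-10)

    def test_small_sample_is_na(self):
        dos = np.array([[0, 2, 0], [2, 0, 2]], dtype=np.int8)
        assert np.isnan(tajimas_d(2, 1.0, n=3))

    def test_neutral_panel_band(self, flat_panel):
        out = tajimas_d_windows(flat_panel, width=20, step=10)
        med = np.nanmedian(out.table["tajimas_d"])
        assert -2.0 < med < 2.0

    def test_argument_validation(self, flat_panel):
        with pytest.raises(ValueError):
            tajimas_d_windows(flat_panel, width=1)
        with pytest.raises(ValueError):
            tajimas_d_windows(flat_panel, width=20, step=0)


class TestLdRegion:
    def test_complete_coupling(self):
        rng = np.random.default_rng(3)
        row = rng.choice([0, 2], size=30).astype(np.int8)
        g = matrix_from(np.vstack([row, row]))
        ld = ld_region(g, (1, 1, 10))
        assert ld.r2[0, 1] == pytest.approx(1.0)
        assert ld.d_prime[0, 1] == pytest.approx(1.0)

    def test_independent_markers(self):
        rng = np.random.default_rng(4)
        dos = rng.choice([0, 2], size=(2, 2000)).astype(np.int8)
        ld = ld_region(matrix_from(dos), (1, 1, 10))
        assert ld.r2[0, 1] < 0.01

    def test_hand_computed_four_line_example(self):
        """Haplotype counts AB=2, Ab=1, aB=1, bb=0 over 4 inbred lines."""
        dos = np.array([[2, 2, 0, 0],
                        [2, 0, 2, 0]], dtype=np.int8)
        ld = ld_region(matrix_from(dos), (1, 1, 10))
        pa = pb = 0.5
        pab = 0.25  # both minor together in 1 of 4 lines
        d = pab - pa * pb
        r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
        dmax = min(pa * pb, (1 - pa) * (1 - pb))  # d = 0 here
        assert ld.r2[0, 1] == pytest.approx(r2, abs=1e-12)
        assert ld.d_prime[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_positive_d(self):
        dos = np.array([[2, 2, 0, 0, 0, 2],
                        [2, 2, 0, 0, 2, 0]], dtype=np.int8)
        ld = ld_region(matrix_from(dos), (1, 1, 10))
        pa = pb = 0.5
        pab = 2 / 6
        d = pab - 0.25
        assert ld.r2[0, 1] == pytest.approx(d * d / 0.0625, abs=1e-12)
        assert ld.d_prime[0, 1] == pytest.approx(d / 0.25, abs=1e-12)

    def test_diagonal_and_flip_invariance(self):
        rng = np.random.default_rng(5)
        dos = rng.choice([0, 2], size=(4, 60)).astype(np.int8)
        g = matrix_from(dos)
        ld = ld_region(g, (1, 1, 10))
        assert np.allclose(np.diag(ld.r2), 1.0)
        flipped = dos.copy()
        flipped[0] = 2 - flipped[0]
        ld2 = ld_region(matrix_from(flipped), (1, 1, 10))
        np.testing.assert_allclose(ld.r2, ld2.r2, atol=1e-12)

    def test_low_maf_markers_excluded(self):
        dos = np.zeros((3, 40), dtype=np.int8)
        dos[0, :20] = 2   # MAF 0.5 kept
        dos[1, 0] = 2     # MAF 0.0125 dropped
        dos[2, :10] = 2   # MAF 0.25 kept
        ld = ld_region(matrix_from(dos), (1, 1, 10))
        assert len(ld.markers) == 2

    def test_sparse_region_warns(self):
        dos = np.zeros((2, 40), dtype=np.int8)
        dos[0, :20] = 2
        with pytest.warns(UserWarning, match="polymorphic"):
            ld = ld_region(matrix_from(dos), (1, 1, 1))
        assert ld.r2.shape == (1, 1)


@pytest.fixture(scope="module")
def setup():
    g = simulate_genotypes(PanelSpec(
        n_lines=60, n_markers=300, n_subpops=1,
        subpop_proportions=(1.0,), fst=0.05, ld_block_length=1,
        residual_het_rate=0.0, seed=40))
    maf = g.maf()
    j = int(np.argmin(np.abs(maf - 0.4)))
    asg = QTLAssignment(np.array([j]), np.array([1.0]))
    tr = simulate_phenotype(g, asg, h2=0.95, seed=41)
    pheno = PhenotypeTable(pd.DataFrame({
        "line_id": g.line_ids, "trait": "sim", "value": tr.phenotype}))
    tree = cluster_lines(kinship(g))
    return g, pheno, tree, j


class TestAlleleTraitTable:
    def test_rows_in_leaf_order(self, setup):
        g, pheno, tree, j = setup
        mk = g.markers["name"].iloc[j]
        tab = allele_trait_table(g, pheno, [mk], tree)
        assert len(tab) == g.n_lines
        expected = [g.line_ids[i] for i in tree.leaf_order]
        assert tab["line_id"].tolist() == expected

    def test_effect_direction_visible(self, setup):
        g, pheno, tree, j = setup
        mk = g.markers["name"].iloc[j]
        tab = allele_trait_table(g, pheno, [mk], tree)
        means = tab.groupby(f"{mk}_dosage")["sim"].mean()
        assert means.loc[2] > means.loc[0]  # positive simulated effect

    def test_unknown_marker_errors(self, setup):
        g, pheno, tree, _ = setup
        with pytest.raises(KeyError, match="nope"):
            allele_trait_table(g, pheno, ["nope"], tree)


class TestEnrichMinorAllele:
    def _panel(self):
        dos = np.zeros((1, 500), dtype=np.int8)
        dos[0, :10] = 2
        return matrix_from(dos)

    def test_balanced_construction(self):
        g = self._panel()
        sub = enrich_minor_allele(g, g.markers["name"].iloc[0], seed=1)
        assert len(sub) == 20
        keep = g.subset_lines(sub)
        assert keep.maf()[0] == pytest.approx(0.5)

    def test_deterministic(self):
        g = self._panel()
        mk = g.markers["name"].iloc[0]
        assert enrich_minor_allele(g, mk, seed=2) == \
            enrich_minor_allele(g, mk, seed=2)

    def test_majority_sample_uniform(self):
        g = self._panel()
        mk = g.markers["name"].iloc[0]
        major_ids = [f"L{i}" for i in range(10, 500)]
        counts = {lid: 0 for lid in major_ids}
        for s in range(1000):
            for lid in enrich_minor_allele(g, mk, seed=s):
                if lid in counts:
                    counts[lid] += 1
        observed = np.array(list(counts.values()))
        chi2 = ((observed - observed.mean()) ** 2 / observed.mean()).sum()
        p = stats.chi2.sf(chi2, df=len(observed) - 1)
        assert p > 0.001

    def test_minor_majority_errors(self):
        # mis-coded input (allele coded 2 is actually the common one):
        # balancing to 0.5 is impossible and must be refused
        dos = np.zeros((1, 30), dtype=np.int8)
        dos[0, :20] = 2
        g = matrix_from(dos)
        with pytest.raises(ValueError, match="exceeds"):
            enrich_minor_allele(g, g.markers["name"].iloc[0], seed=0)
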