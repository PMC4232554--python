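"""Ingestion, dosage coding, filtering and phenotype handling."""

import io

import numpy as np
import pandas as pd
import pytest

from soygwas import (GenotypeMatrix, PhenotypeTable, average_replicates,
                     filter_maf, impute_missing, read_genotypes,
                     resolve_heterozygotes, write_genotypes)
from soygwas.genotype_io import (MISSING, GenotypeParseError,
                                 parse_marker_name, read_phenotypes)


def toy_matrix(dosages, n_chrom=1):
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    markers = pd.DataFrame({
        "name": [f"T1.01Gm{(j % n_chrom) + 1:02d}_{1000 + j}"
                 for j in range(m)],
        "chrom": [(j % n_chrom) + 1 for j in range(m)],
        "pos": [1000 + j for j in range(m)],
        "minor": "A", "major": "T",
    })
    lines = pd.DataFrame({"line_id": [f"L{i}" for i in range(n)]})
    return GenotypeMatrix(dosages, markers, lines)


def test_parse_marker_name():
    assert parse_marker_name("BARC1.01Gm20_31972955") == (20, 31972955)
    assert parse_marker_name("BARC1.01Gm08_8462762") == (8, 8462762)
    with pytest.raises(GenotypeParseError):
        parse_marker_name("rs12345")


def test_tsv_dosage_coding(tmp_path):
    """AA/AT/TT at a marker map to dosages counting the minor allele."""
    p = tmp_path / "toy.tsv"
    p.write_text("marker\tL1\tL2\n"
                 "X1.01Gm01_100\t0\t1\n"
                 "X1.01Gm01_200\t2\tNA\n"
                 "X1.01Gm02_50\t1\t1\n")
    g = read_genotypes(p, "tsv")
    assert g.n_markers == 3 and g.n_lines == 2
    # sorted by (chrom, pos)
    assert g.markers["chrom"].tolist() == [1, 1, 2]
    row = g.dosages[g.markers.index[g.markers["pos"] == 200][0]]
    assert row[0] in (0, 2) and row[1] == MISSING


def test_hapmap_coding_minor_allele(tmp_path):
    """2 counts copies of the panel minor allele, not of a fixed allele."""
    cols = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
            "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
            "L1", "L2", "L3"]
    p = tmp_path / "toy.hmp.txt"
    p.write_text("\t".join(cols) + "\n"
                 "M1.01Gm01_100\tA/T\t1\t100\t+\tNA\tNA\tNA\tNA\tNA\tNA"
                 "\tA\tW\tT\n")
    g = read_genotypes(p, "hapmap")
    # A appears 3 times, T 3 times -> tie; lexicographically greater (T)
    # is minor, so dosages count T copies
    assert g.dosages[0].tolist() == [0, 1, 2]
    assert g.markers["minor"].iloc[0] == "T"


def test_vcf_multiallelic_skipped(tmp_path):
    header = ("##fileformat=VCFv4.2\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
              "##contig=<ID=Gm01>\n"
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
              "\tL1\tL2\n")
    body = ""
    for i in range(1, 6):
        alt = "T,G" if i == 3 else "T"
        body += (f"Gm01\t{i * 100}\tm{i}\tA\t{alt}\t.\t.\t.\tGT"
                 "\t0/0\t1/1\n")
    p = tmp_path / "toy.vcf"
    p.write_text(header + body)
    with pytest.warns(UserWarning, match="non-biallelic"):
        g = read_genotypes(p, "vcf")
    assert g.n_markers == 4


@pytest.mark.parametrize("fmt", ["tsv", "hapmap", "vcf"])
def test_round_trip(fmt, tmp_path):
    """Write-then-read preserves dosages, coordinates and line IDs."""
    from soygwas.synthetic_data import PanelSpec, simulate_genotypes
    g = simulate_genotypes(PanelSpec(n_lines=50, n_markers=100,
                                     residual_het_rate=0.02, seed=3))
    p = tmp_path / f"panel.{fmt}"
    write_genotypes(g, p, fmt)
    g2 = read_genotypes(p, fmt)
    np.testing.assert_array_equal(g.dosages, g2.dosages)
    assert g.markers["chrom"].tolist() == g2.markers["chrom"].tolist()
    assert g.markers["pos"].tolist() == g2.markers["pos"].tolist()
    assert g.line_ids == g2.line_ids


class TestFilterMaf:
    def test_boundary_inclusive(self):
        dos = np.zeros((1, 100), dtype=np.int8)
        dos[0, :5] = 2  # MAF exactly 0.05
        g = toy_matrix(dos)
        assert filter_maf(g, 0.05).n_markers == 1

    def test_monomorphic_removed(self):
        g = toy_matrix(np.zeros((3, 40), dtype=np.int8))
        assert filter_maf(g, 0.01).n_markers == 0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        dos = rng.choice([0, 1, 2], size=(1000, 60),
                         p=[0.7, 0.02, 0.28]).astype(np.int8)
        g = toy_matrix(dos)
        kept = set(filter_maf(g, 0.05).markers["name"])
        expected = set()
        for j in range(1000):
            f = dos[j].sum() / (2 * 60)
            if min(f, 1 - f) >= 0.05:
                expected.add(g.markers["name"].iloc[j])
        assert kept == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        g = toy_matrix(rng.choice([0, 2], size=(200, 30)).astype(np.int8))
        once = filter_maf(g, 0.1)
        twice = filter_maf(once, 0.1)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_threshold_range(self):
        g = toy_matrix(np.zeros((1, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            filter_maf(g, 0.7)


class TestImputeMissing:
    def test_no_missing_identity(self):
        g = toy_matrix([[0, 2, 2], [2, 0, 0]])
        g2 = impute_missing(g, seed=1)
        np.testing.assert_array_equal(g.dosages, g2.dosages)

    def test_deterministic(self):
        dos = np.array([[0, 2, MISSING, 0, 2, MISSING]], dtype=np.int8)
        g = toy_matrix(dos)
        a = impute_missing(g, seed=5).dosages
        b = impute_missing(g, seed=5).dosages
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) <= {0, 2}

    def test_binomial_frequencies(self):
        """Imputed class frequencies track the observed homozygote ratio."""
        dos = np.full((1, 11_000), MISSING, dtype=np.int8)
        dos[0, :900] = 0
        dos[0, 900:1000] = 2  # observed 0.9 / 0.1
        g = toy_matrix(dos)
        imp = impute_missing(g, seed=2).dosages[0, 1000:]
        assert imp.min() >= 0
        frac_minor = (imp == 2).mean()
        assert abs(frac_minor - 0.1) < 0.01

    def test_all_missing_errors(self):
        dos = np.full((1, 5), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="all calls missing"):
            impute_missing(toy_matrix(dos), seed=0)


class TestResolveHeterozygotes:
    def test_identity_without_hets(self):
        g = toy_matrix([[0, 2], [2, 0]])
        np.testing.assert_array_equal(
            g.dosages, resolve_heterozygotes(g, 3).dosages)

    def test_binomial_at_maf_half(self):
        dos = np.ones((1, 10_000), dtype=np.int8)  # MAF 0.5, all het
        out = resolve_heterozygotes(toy_matrix(dos), seed=4).dosages[0]
        assert not (out == 1).any()
        assert abs((out == 2).sum() - 5000) < 150

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        dos = rng.choice([0, 1, 2], size=(50, 40)).astype(np.int8)
        g = toy_matrix(dos)
        a = resolve_heterozygotes(g, 9).dosages
        b = resolve_heterozygotes(g, 9).dosages
        np.testing.assert_array_equal(a, b)

    def test_preserves_expected_maf_at_half(self):
        """At MAF 0.5 the draw is unbiased: mean post-resolution MAF over
        100 seeds stays within 3 SE of the input MAF."""
        rng = np.random.default_rng(10)
        dos = np.zeros((10, 80), dtype=np.int8)
        for j in range(10):
            n_het = 10 + 2 * j
            n_hom = (80 - n_het) // 2
            row = np.array([1] * n_het + [2] * n_hom
                           + [0] * (80 - n_het - n_hom), dtype=np.int8)
            dos[j] = rng.permutation(row)
        g = toy_matrix(dos)

        def freq(mat):  # unfolded frequency of the allele coded 2
            return mat.dosages.sum(axis=1) / (2.0 * mat.n_lines)

        pre = freq(g)
        post = np.array([freq(resolve_heterozygotes(g, s))
                         for s in range(100)])
        se = post.std(axis=0, ddof=1) / np.sqrt(post.shape[0])
        assert np.all(np.abs(post.mean(axis=0) - pre) <= 3 * se + 1e-12)

    def test_rare_hets_leave_frequencies_essentially_unchanged(self):
        """At realistic residual heterozygosity (~1/1000 calls) resolution
        shifts per-marker allele frequency by at most one copy per het."""
        rng = np.random.default_rng(11)
        dos = rng.choice([0, 2], size=(200, 500),
                         p=[0.7, 0.3]).astype(np.int8)
        het = rng.random(dos.shape) < 0.001
        dos[het] = 1
        g = toy_matrix(dos)
        post = resolve_heterozygotes(g, 12)
        shift = np.abs(post.dosages.sum(axis=1) - g.dosages.sum(axis=1))
        hets_per_marker = (g.dosages == 1).sum(axis=1)
        assert np.all(shift <= hets_per_marker)


class TestPhenotypes:
    def test_average_pair(self):
        p = PhenotypeTable(pd.DataFrame({
            "line_id": ["A", "A"], "trait": ["protein"] * 2,
            "value": [40.0, 44.0], "replicate": ["r1", "r2"]}))
        out = average_replicates(p)
        assert out.records["value"].iloc[0] == 42.0
        assert len(out.records) == 1

    def test_single_replicate_identity(self):
        p = PhenotypeTable(pd.DataFrame({
            "line_id": ["A"], "trait": ["oil"], "value": [18.5]}))
        assert average_replicates(p).records["value"].iloc[0] == 18.5

    def test_groupby_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "line_id": rng.choice(list("ABCDE"), 60),
            "trait": rng.choice(["t1", "t2"], 60),
            "value": rng.normal(size=60)})
        out = average_replicates(PhenotypeTable(df)).records
        for _, r in out.iterrows():
            exp = df[(df["line_id"] == r["line_id"])
                     & (df["trait"] == r["trait"])]["value"].mean()
            assert r["value"] == pytest.approx(exp)

    def test_non_numeric_value_errors(self, tmp_path):
        p = tmp_path / "ph.tsv"
        p.write_text("line_id\ttrait\tvalue\nA\tprotein\toops\n")
        with pytest.raises(GenotypeParseError, match="oops"):
            read_phenotypes(p)

    def test_unmatched_ids_reported(self):
        p = PhenotypeTable(pd.DataFrame({
            "line_id": ["A", "B"], "trait": ["t"] * 2, "value": [1.0, 2.0]}))
        vals, matched, unmatched = p.trait_vector("t", ["A", "C"])
        assert matched == ["A"] and unmatched == ["C"]
        assert vals.tolist() == [1.0]


def test_subset_lines_recomputes_minor():
    """An allele common in the full panel can be minor in a subset."""
    dos = np.array([[2, 2, 2, 0, 0, 0, 0, 0]], dtype=np.int8)
    g = toy_matrix(dos)
    sub = g.subset_lines(["L0", "L1", "L2", "L3"])  # now 'minor' is 3/4
    assert sub.maf()[0] == pytest.approx(0.25)
    assert sub.dosages[0].tolist() == [0, 0, 0, 2]
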