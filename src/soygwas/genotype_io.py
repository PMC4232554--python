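"""Genotype and phenotype ingestion, filtering and transformation.

The central container is :class:`GenotypeMatrix`: a biallelic marker x line
dosage matrix coded so that 2 counts two copies of the panel's minor allele.
Soybean panels are nearly fully inbred, so dosages are almost entirely 0/2;
residual heterozygotes (dosage 1) are kept until a downstream stage resolves
or excludes them.

Supported dialects: HapMap tab-separated (11 metadata columns then one IUPAC
genotype column per line), VCF v4.x (read through cyvcf2), and a plain
marker x line TSV of 0/1/2/NA dosages.  Marker names of the form
``<prefix>Gm<CC>_<POS>`` (e.g. ``BARC1.01Gm20_31972955``) carry the
chromosome and 1-based bp position.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel in the int8 dosage matrix

_IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_HET_IUPAC = {v: tuple(sorted(k)) for k, v in _IUPAC_HET.items()}

_MARKER_NAME_RE = re.compile(r"Gm0*(\d+)_(\d+)$")


class GenotypeParseError(ValueError):
    """Malformed genotype input; message names the offending line."""


def parse_marker_name(name: str) -> tuple[int, int]:
    """Extract (chromosome, position) from a ``<prefix>Gm<CC>_<POS>`` name."""
    m = _MARKER_NAME_RE.search(name)
    if m is None:
        raise GenotypeParseError(
            f"marker name {name!r} does not match <prefix>Gm<CC>_<POS>"
        )
    return int(m.group(1)), int(m.group(2))


def _designate_minor(n_minor_candidate: int, n_total: int,
                     allele_a: str, allele_b: str) -> bool:
    """Tie-break rule shared by every reader: at exactly 50/50 the
    lexicographically greater allele is 'minor'.  Returns True if allele_a
    (with count ``n_minor_candidate`` out of ``n_total``) is the minor one."""
    if 2 * n_minor_candidate < n_total:
        return True
    if 2 * n_minor_candidate > n_total:
        return False
    return allele_a > allele_b


@dataclass
class GenotypeMatrix:
    """Marker x line minor-allele dosage matrix with coordinates and metadata.

    Attributes
    ----------
    dosages : int8 ndarray, shape (n_markers, n_lines)
        0/1/2 minor-allele copy counts; -1 marks a missing call.
    markers : DataFrame with columns name, chrom, pos, minor, major
        Sorted by (chrom, pos).
    lines : DataFrame with columns line_id, country, maturity_group
        plus optional extras (e.g. ``subpop`` for simulated panels).
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    lines: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.markers), len(self.lines)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.markers)} markers x {len(self.lines)} lines"
            )
        if (self.markers["pos"] <= 0).any():
            raise ValueError("marker positions must be strictly positive")
        self._sort_markers()

    def _sort_markers(self) -> None:
        order = np.lexsort((self.markers["pos"].to_numpy(),
                            self.markers["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[order]
        else:
            self.markers = self.markers.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[1]

    @property
    def line_ids(self) -> list[str]:
        return self.lines["line_id"].tolist()

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing calls.

        Heterozygous calls contribute one copy of each allele.  Because the
        coding is recomputed after any subsetting, the returned frequency is
        min(f, 1-f) of the allele coded 2.
        """
        d = self.dosages
        obs = d != MISSING
        n_called = obs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs, d, 0).sum(axis=1) / (2.0 * n_called)
        f = np.where(n_called == 0, np.nan, f)
        return np.minimum(f, 1.0 - f)

    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING).any())

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index].copy(),
            markers=self.markers.iloc[index].reset_index(drop=True).copy(),
            lines=self.lines.copy(),
        )

    def subset_lines(self, line_ids: list[str]) -> "GenotypeMatrix":
        """Restrict to the named lines and recompute the minor-allele coding.

        The minor allele is panel-relative: a marker common in one population
        can be rare in another, so subsetting re-designates alleles (and flips
        dosages where needed).
        """
        idx_map = {lid: i for i, lid in enumerate(self.line_ids)}
        missing_ids = [l for l in line_ids if l not in idx_map]
        if missing_ids:
            raise KeyError(f"line IDs not in panel: {missing_ids[:5]}"
                           + ("..." if len(missing_ids) > 5 else ""))
        cols = np.array([idx_map[l] for l in line_ids])
        g = GenotypeMatrix(
            dosages=self.dosages[:, cols].copy(),
            markers=self.markers.copy(),
            lines=self.lines.iloc[cols].reset_index(drop=True).copy(),
        )
        g.recompute_minor()
        return g

    def recompute_minor(self) -> None:
        """Re-orient coding so the allele coded 2 is the panel minor allele."""
        d = self.dosages
        obs = d != MISSING
        counts = np.where(obs, d, 0).sum(axis=1)
        totals = 2 * obs.sum(axis=1)
        minor = self.markers["minor"].to_numpy(dtype=object)
        major = self.markers["major"].to_numpy(dtype=object)
        flip = np.zeros(len(minor), dtype=bool)
        for j in range(len(minor)):
            if totals[j] == 0:
                continue
            # current 'minor' allele has count counts[j]
            if not _designate_minor(counts[j], totals[j],
                                    str(minor[j]), str(major[j])):
                flip[j] = True
        if flip.any():
            rows = np.where(flip)[0]
            sub = d[rows]
            sub = np.where(sub == MISSING, MISSING, 2 - sub).astype(np.int8)
            d[rows] = sub
            self.markers.loc[flip, ["minor", "major"]] = (
                self.markers.loc[flip, ["major", "minor"]].to_numpy())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.markers.copy(),
                              self.lines.copy())


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one row per (line, trait[, replicate])."""

    records: pd.DataFrame  # columns: line_id, trait, value [, replicate]

    def __post_init__(self) -> None:
        needed = {"line_id", "trait", "value"}
        if not needed.issubset(self.records.columns):
            raise ValueError(f"phenotype table needs columns {sorted(needed)}")

    def trait_vector(self, trait: str, line_ids: list[str]
                     ) -> tuple[np.ndarray, list[str], list[str]]:
        """Values for `trait` aligned to `line_ids`.

        Returns (values, matched line IDs, unmatched line IDs).  Unmatched IDs
        are reported to the caller, never silently dropped.
        """
        sub = self.records[self.records["trait"] == trait]
        lut = dict(zip(sub["line_id"], sub["value"]))
        matched, unmatched, vals = [], [], []
        for lid in line_ids:
            if lid in lut:
                matched.append(lid)
                vals.append(float(lut[lid]))
            else:
                unmatched.append(lid)
        return np.asarray(vals, dtype=float), matched, unmatched


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped with a warning (count logged); the
    dosage coding is fixed so 2 = homozygous for the minor allele as computed
    across the read panel.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path, format: str) -> None:
    if format == "tsv":
        _write_tsv(g, path)
    elif format == "hapmap":
        _write_hapmap(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _finalize(names, chroms, poss, minors, majors, rows, line_ids,
              extra_line_cols=None) -> GenotypeMatrix:
    markers = pd.DataFrame({
        "name": names, "chrom": np.asarray(chroms, dtype=int),
        "pos": np.asarray(poss, dtype=int),
        "minor": minors, "major": majors,
    })
    lines = pd.DataFrame({"line_id": line_ids})
    lines["country"] = None
    lines["maturity_group"] = None
    if extra_line_cols:
        for k, v in extra_line_cols.items():
            lines[k] = v
    d = np.asarray(rows, dtype=np.int8)
    g = GenotypeMatrix(d, markers, lines)
    g.recompute_minor()
    return g


def _read_tsv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: need marker column plus >=1 line")
    line_ids = list(df.columns[1:])
    names, chroms, poss, rows = [], [], [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = row[0]
        try:
            chrom, pos = parse_marker_name(str(name))
        except GenotypeParseError as exc:
            raise GenotypeParseError(f"{path} line {i}: {exc}") from exc
        vals = []
        for cell in row[1:]:
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).upper() in {"NA", "NAN", ""}:
                vals.append(MISSING)
            elif str(cell) in {"0", "1", "2"}:
                vals.append(int(cell))
            else:
                raise GenotypeParseError(
                    f"{path} line {i}: bad dosage {cell!r}")
        names.append(str(name)); chroms.append(chrom); poss.append(pos)
        rows.append(vals)
    minors = ["A"] * len(names)  # TSV carries no allele letters
    majors = ["T"] * len(names)
    return _finalize(names, chroms, poss, minors, majors, rows, line_ids)


def _write_tsv(g: GenotypeMatrix, path) -> None:
    d = g.dosages.astype(object)
    d[g.dosages == MISSING] = "NA"
    out = pd.DataFrame(d, columns=g.line_ids)
    out.insert(0, "marker", g.markers["name"].to_numpy())
    out.to_csv(path, sep="\t", index=False)


_HAPMAP_COLS = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def _read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] <= 11:
        raise GenotypeParseError(f"{path}: HapMap needs 11 metadata columns "
                                 "plus genotype columns")
    line_ids = list(df.columns[11:])
    names, chroms, poss, minors, majors, rows = [], [], [], [], [], []
    n_skipped = 0
    for i, row in df.iterrows():
        name = row.iloc[0]
        alleles = str(row.iloc[1]).split("/")
        if len(alleles) != 2 or any(a not in "ACGT" for a in alleles):
            n_skipped += 1
            warnings.warn(f"skipping non-biallelic HapMap record {name!r}")
            continue
        a, b = alleles
        chrom, pos = int(row.iloc[2]), int(row.iloc[3])
        calls = row.iloc[11:]
        vals = []
        count_a = 0
        n_called = 0
        for cell in calls:
            c = str(cell).upper()
            if c in {"N", "NA", "NN"}:
                vals.append(MISSING)
            elif c == a:
                vals.append("A2")  # two copies of allele a; decode later
                count_a += 2; n_called += 2
            elif c == b:
                vals.append("B2")
                n_called += 2
            elif c in _HET_IUPAC and set(_HET_IUPAC[c]) == {a, b}:
                vals.append("H")
                count_a += 1; n_called += 2
            else:
                raise GenotypeParseError(
                    f"{path} row {i + 2}: bad genotype code {cell!r} "
                    f"for alleles {a}/{b}")
        a_is_minor = _designate_minor(count_a, n_called, a, b) \
            if n_called else True
        minor, major = (a, b) if a_is_minor else (b, a)
        code = {"A2": 2 if a_is_minor else 0,
                "B2": 0 if a_is_minor else 2,
                "H": 1, MISSING: MISSING}
        names.append(str(name)); chroms.append(chrom); poss.append(pos)
        minors.append(minor); majors.append(major)
        rows.append([code[v] for v in vals])
    if n_skipped:
        logger.info("skipped %d non-biallelic HapMap records", n_skipped)
    return _finalize(names, chroms, poss, minors, majors, rows, line_ids)


def _write_hapmap(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_COLS + g.line_ids) + "\n")
        for j in range(g.n_markers):
            m = g.markers.iloc[j]
            minor, major = str(m["minor"]), str(m["major"])
            het = _IUPAC_HET.get(frozenset((minor, major)), "N")
            code = {0: major, 1: het, 2: minor, MISSING: "N"}
            meta = [str(m["name"]), f"{major}/{minor}", str(m["chrom"]),
                    str(m["pos"]), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            fh.write("\t".join(meta + [code[int(v)] for v in g.dosages[j]])
                     + "\n")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    names, chroms, poss, minors, majors, rows = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            warnings.warn(f"skipping non-biallelic VCF record at "
                          f"{var.CHROM}:{var.POS}")
            continue
        gts = var.genotype.array()  # sample x (a1, a2, phased)
        alt_dose = np.where((gts[:, :2] < 0).any(axis=1), MISSING,
                            gts[:, :2].clip(min=0).sum(axis=1))
        obs = alt_dose != MISSING
        alt_count = int(alt_dose[obs].sum())
        n_called = 2 * int(obs.sum())
        alt_is_minor = _designate_minor(alt_count, n_called,
                                        var.ALT[0], var.REF) if n_called \
            else True
        if alt_is_minor:
            dose = alt_dose
            minor, major = var.ALT[0], var.REF
        else:
            dose = np.where(alt_dose == MISSING, MISSING, 2 - alt_dose)
            minor, major = var.REF, var.ALT[0]
        name = var.ID if var.ID else f"{var.CHROM}_{var.POS}"
        chrom = int(re.sub(r"^(chr|Gm)0*", "", str(var.CHROM)))
        names.append(name); chroms.append(chrom); poss.append(var.POS)
        minors.append(minor); majors.append(major)
        rows.append(dose.astype(int).tolist())
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    return _finalize(names, chroms, poss, minors, majors, rows, line_ids)


def _write_vcf(g: GenotypeMatrix, path) -> None:
    # minimal plain-text VCF v4.2: REF = major, ALT = minor, GT-only
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(g.markers["chrom"].unique()):
            fh.write(f"##contig=<ID=Gm{int(c):02d}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.line_ids) + "\n")
        gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(g.n_markers):
            m = g.markers.iloc[j]
            cells = [gt[int(v)] for v in g.dosages[j]]
            fh.write(f"Gm{int(m['chrom']):02d}\t{m['pos']}\t{m['name']}\t"
                     f"{m['major']}\t{m['minor']}\t.\t.\t.\tGT\t"
                     + "\t".join(cells) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype TSV: line_id, trait, value[, replicate]."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "trait": str})
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        i = int(np.where(bad)[0][0])
        raise GenotypeParseError(
            f"{path}: non-numeric trait value {df['value'].iloc[i]!r} "
            f"(line {df['line_id'].iloc[i]!r}, trait {df['trait'].iloc[i]!r})")
    df["value"] = pd.to_numeric(df["value"])
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path) -> None:
    p.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop markers with minor-allele frequency below ``threshold``.

    Boundary is inclusive: MAF exactly equal to the threshold is retained.
    MAF is computed on non-missing calls, so filtering before imputation is
    valid. Marker order is preserved.
    """
    if not (0.0 <= threshold <= 0.5):
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    maf = g.maf()
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= threshold)[0]
    return g.subset_markers(keep)


def impute_missing(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls by frequency-proportional homozygote draws.

    Each missing call becomes 0 or 2 with probability equal to that marker's
    observed homozygote-class frequencies; a heterozygote is never imputed.
    This is a deliberately simple stand-in for haplotype-aware imputation:
    at the MAF >= 0.05 markers used downstream the analyses are insensitive
    to the imputer.  Deterministic under a fixed seed.
    """
    if not g.has_missing():
        return g.copy()
    rng = np.random.default_rng(seed)
    d = g.dosages.copy()
    all_missing = [str(g.markers["name"].iloc[j])
                   for j in range(g.n_markers)
                   if (d[j] == MISSING).all()]
    if all_missing:
        raise ValueError(f"markers with all calls missing: {all_missing[:10]}")
    for j in np.where((d == MISSING).any(axis=1))[0]:
        row = d[j]
        miss = row == MISSING
        n0 = int((row == 0).sum())
        n2 = int((row == 2).sum())
        if n0 + n2 > 0:
            p2 = n2 / (n0 + n2)
        else:  # only heterozygous calls observed; fall back to allele freq
            p2 = 0.5
        draws = rng.random(miss.sum()) < p2
        row[miss] = np.where(draws, 2, 0)
    return GenotypeMatrix(d, g.markers.copy(), g.lines.copy())


def resolve_heterozygotes(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Randomly assign residual heterozygotes to a homozygous class.

    Each dosage-1 entry becomes 2 with probability equal to the marker's
    minor-allele frequency (from total allele counts), else 0.  In highly
    inbred panels this touches ~1 in 1000 calls and adds only minor,
    nonsystematic noise; it is applied on the path feeding the multi-locus
    scan, which requires homozygous input.
    """
    het = g.dosages == 1
    if not het.any():
        return g.copy()
    rng = np.random.default_rng(seed)
    maf = g.maf()
    d = g.dosages.copy()
    for j in np.where(het.any(axis=1))[0]:
        mask = d[j] == 1
        draws = rng.random(mask.sum()) < maf[j]
        d[j, mask] = np.where(draws, 2, 0)
    return GenotypeMatrix(d, g.markers.copy(), g.lines.copy())


def average_replicates(p: PhenotypeTable) -> PhenotypeTable:
    """Arithmetic mean per (line, trait); replicate labels are dropped."""
    df = p.records
    out = (df.groupby(["line_id", "trait"], as_index=False, sort=False)
             ["value"].mean())
    return PhenotypeTable(out)
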