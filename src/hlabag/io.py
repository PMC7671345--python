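"""Readers and writers for the on-disk formats of the pipeline.

Genotypes travel as VCF 4.2 (the canonical format, read through ``cyvcf2``)
or as a plain TSV dosage dialect that keeps unit-test fixtures readable.
HLA typings, phenotypes and imputation calls are TSV tables with headers.
All coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CLASSICAL_LOCI

log = logging.getLogger(__name__)

MISSING = -1  # missing-dosage sentinel inside GenotypeMatrix

_TWO_FIELD = re.compile(r"^([A-Z][A-Z0-9]*)\*(\d+):(\d+)")


class FormatError(ValueError):
    """A file violated its format contract."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Unphased biallelic SNP genotypes as alt-allele dosages.

    ``dosage`` is an ``(n_samples, n_snps)`` int8 array with values in
    {0, 1, 2} or :data:`MISSING` (-1).
    """

    samples: list[str]
    snp_ids: list[str]
    positions: np.ndarray          # int64, 1-based
    ref: list[str]
    alt: list[str]
    dosage: np.ndarray             # int8 (n_samples, n_snps)
    chrom: str = "6"
    n_skipped: int = 0             # non-SNP / multiallelic records dropped on read

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.snp_ids):
            raise ValueError("dosage shape inconsistent with sample/SNP lists")
        if len(self.ref) != m or len(self.alt) != m or len(self.positions) != m:
            raise ValueError("per-SNP metadata length mismatch")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,missing}")
        if len(set(self.snp_ids)) != m:
            dupes = sorted({s for s in self.snp_ids if self.snp_ids.count(s) > 1})
            raise FormatError(f"duplicated SNP IDs: {', '.join(dupes)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.snp_ids)}

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = [idx[s] for s in keep]
        return GenotypeMatrix(list(keep), list(self.snp_ids), self.positions.copy(),
                              list(self.ref), list(self.alt),
                              self.dosage[rows].copy(), self.chrom)

    def subset_snps(self, keep: list[str]) -> "GenotypeMatrix":
        idx = self.snp_index()
        cols = [idx[s] for s in keep]
        return GenotypeMatrix(list(self.samples), list(keep), self.positions[cols].copy(),
                              [self.ref[c] for c in cols], [self.alt[c] for c in cols],
                              self.dosage[:, cols].copy(), self.chrom)


@dataclass
class HLATyping:
    """Two-field HLA allele pairs per sample and locus.

    ``calls[sample][locus]`` is an unordered pair stored as a sorted tuple;
    homozygotes repeat the allele.
    """

    calls: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)

    def set(self, sample: str, locus: str, a1: str, a2: str) -> None:
        pair = tuple(sorted((a1, a2)))
        self.calls.setdefault(sample, {})[locus] = pair

    def get(self, sample: str, locus: str) -> tuple[str, str] | None:
        return self.calls.get(sample, {}).get(locus)

    def samples(self) -> list[str]:
        return list(self.calls)

    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for by_locus in self.calls.values():
            for loc in by_locus:
                seen.setdefault(loc)
        return list(seen)

    def alleles(self, locus: str) -> list[str]:
        out: set[str] = set()
        for by_locus in self.calls.values():
            pair = by_locus.get(locus)
            if pair:
                out.update(pair)
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, loc, p[0], p[1])
                for s, by_locus in self.calls.items()
                for loc, p in by_locus.items()]
        return pd.DataFrame(rows, columns=["sample", "locus", "allele1", "allele2"])


def normalize_allele(allele: str, *, sample: str = "?", locus: str = "?") -> str:
    """Truncate an HLA allele name to two-field resolution.

    ``"B*07:02:01:01"`` becomes ``"B*07:02"``.  One-field names (no colon)
    are rejected: they do not identify a protein.
    """
    m = _TWO_FIELD.match(allele.strip())
    if not m:
        raise FormatError(
            f"allele {allele!r} for sample {sample}, locus {locus} is not "
            "two-field HLA nomenclature (expected GENE*FF:FF)")
    return f"{m.group(1)}*{m.group(2)}:{m.group(3)}"


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format_name: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF or the TSV dosage dialect.

    Only biallelic SNP records are kept; multiallelic or non-SNP records
    are skipped and counted in ``GenotypeMatrix.n_skipped``.  Missing
    genotypes are preserved as missing.
    """
    if format_name == "vcf":
        return _read_vcf(str(path))
    if format_name == "tsv-dosage":
        return _read_tsv_dosage(path)
    raise ValueError(f"unknown genotype format {format_name!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    cols: list[np.ndarray] = []
    chrom = "6"
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom = var.CHROM
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        gt = var.genotype.array()[:, :2]
        col = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        cols.append(col.astype(np.int8))
    vcf.close()
    if n_skipped:
        log.info("read_genotypes: skipped %d non-SNP/multiallelic records", n_skipped)
    dosage = (np.stack(cols, axis=1) if cols
              else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, snp_ids, np.array(positions, dtype=np.int64),
                          ref, alt, dosage, chrom=chrom, n_skipped=n_skipped)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT field only)."""
    half = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={g.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j in range(g.n_snps):
            gts = "\t".join(half[int(d)] for d in g.dosage[:, j])
            fh.write(f"{g.chrom}\t{g.positions[j]}\t{g.snp_ids[j]}\t"
                     f"{g.ref[j]}\t{g.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def _read_tsv_dosage(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    required = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FormatError(f"dosage TSV missing columns: {missing_cols}")
    samples = [c for c in df.columns if c not in required]
    dosage = df[samples].to_numpy(dtype=float).T
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    chrom = str(df["chrom"].iloc[0]) if len(df) else "6"
    return GenotypeMatrix(samples, df["snp_id"].tolist(),
                          df["pos"].to_numpy(dtype=np.int64),
                          df["ref"].tolist(), df["alt"].tolist(), dosage, chrom)


def write_tsv_dosage(g: GenotypeMatrix, path) -> None:
    data = {"snp_id": g.snp_ids, "chrom": [g.chrom] * g.n_snps,
            "pos": g.positions, "ref": g.ref, "alt": g.alt}
    df = pd.DataFrame(data)
    dos = g.dosage.astype(float)
    dos[dos == MISSING] = np.nan
    for i, s in enumerate(g.samples):
        df[s] = dos[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")


# ---------------------------------------------------------------------------
# HLA typing tables
# ---------------------------------------------------------------------------

def read_hla_table(path, known_loci: tuple[str, ...] = CLASSICAL_LOCI) -> HLATyping:
    """Read a TSV with columns sample, locus, allele1, allele2.

    Alleles are normalised to two-field resolution; pairs are stored
    unordered.  Conflicting duplicate (sample, locus) rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "locus", "allele1", "allele2"):
        if col not in df.columns:
            raise FormatError(f"HLA table missing column {col!r}")
    typing = HLATyping()
    for row in df.itertuples(index=False):
        if row.locus not in known_loci:
            raise FormatError(f"unknown locus label {row.locus!r} "
                              f"for sample {row.sample}")
        a1 = normalize_allele(row.allele1, sample=row.sample, locus=row.locus)
        a2 = normalize_allele(row.allele2, sample=row.sample, locus=row.locus)
        pair = tuple(sorted((a1, a2)))
        existing = typing.get(row.sample, row.locus)
        if existing is not None and existing != pair:
            raise FormatError(f"conflicting duplicate rows for "
                              f"({row.sample}, {row.locus}): {existing} vs {pair}")
        typing.set(row.sample, row.locus, a1, a2)
    return typing


def write_hla_table(t: HLATyping, path) -> None:
    t.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes and imputation calls
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "status" not in df.columns:
        raise FormatError("phenotype TSV needs 'sample' and 'status' columns")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


CALL_COLUMNS = ["sample", "locus", "allele1", "allele2", "posterior", "batch"]


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "locus": str})
    for col in ("sample", "locus", "allele1", "allele2", "posterior"):
        if col not in df.columns:
            raise FormatError(f"calls TSV missing column {col!r}")
    if "batch" not in df.columns:
        df["batch"] = 0
    return df


def write_calls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
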