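"""Cross-platform, cross-build SNP harmonization.

Reference panels and biobank target data are typically genotyped on
different array platforms and annotated on different genome builds.  Before
any model is trained, the SNP sets are intersected by rsID and filtered to
SNPs whose allele pair is preserved across builds, with strand flips
normalised by complementation and strand-ambiguous (palindromic A/T, C/G)
SNPs removed.  Identity is by rsID only; positions may legitimately differ
between builds and are carried along per build.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, FormatError, GenotypeMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

#: exclusion reason labels
ABSENT = "absent-from-platform"
MISMATCH = "allele-mismatch"
AMBIGUOUS = "strand-ambiguous"


@dataclass
class SNPManifest:
    """Per-platform, per-build SNP annotation (rsID, position, alleles)."""

    platform: str
    build: str
    table: pd.DataFrame  # columns: rsid, chrom, pos, alleleA, alleleB

    def __post_init__(self) -> None:
        required = ["rsid", "chrom", "pos", "alleleA", "alleleB"]
        for col in required:
            if col not in self.table.columns:
                raise FormatError(f"manifest missing column {col!r}")
        dupes = self.table["rsid"][self.table["rsid"].duplicated()]
        if len(dupes):
            raise FormatError(f"rsID occurs twice in manifest "
                              f"{self.platform}/{self.build}: "
                              f"{sorted(set(dupes))}")
        for row in self.table.itertuples(index=False):
            pair = {row.alleleA, row.alleleB}
            if len(pair) != 2 or not pair <= set("ACGT"):
                raise FormatError(f"{row.rsid}: allele pair must be two distinct "
                                  f"bases, got {row.alleleA}/{row.alleleB}")

    def allele_set(self, rsid: str) -> frozenset[str]:
        row = self.table.loc[self.table["rsid"] == rsid].iloc[0]
        return frozenset((row["alleleA"], row["alleleB"]))


def read_manifest(path) -> list[SNPManifest]:
    """Read one or more manifests from a TSV with columns
    rsID, build, chrom, pos, alleleA, alleleB, platform; one manifest per
    (platform, build) pair found in the file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={"rsID": "rsid"})
    out = []
    for (platform, build), grp in df.groupby(["platform", "build"], sort=True):
        tab = grp[["rsid", "chrom", "pos", "alleleA", "alleleB"]].reset_index(drop=True)
        out.append(SNPManifest(platform, build, tab))
    return out


def write_manifest(manifests: list[SNPManifest], path) -> None:
    frames = []
    for m in manifests:
        tab = m.table.copy()
        tab["platform"] = m.platform
        tab["build"] = m.build
        frames.append(tab)
    pd.concat(frames).to_csv(path, sep="\t", index=False,
                             columns=["rsid", "build", "chrom", "pos",
                                      "alleleA", "alleleB", "platform"])


@dataclass
class HarmonizedSNPSet:
    """SNPs retained after intersection and allele-consistency filtering."""

    rsids: list[str]
    alleles: dict[str, tuple[str, str]]          # agreed ordered pair per rsID
    positions: dict[str, dict[str, int]]         # rsid -> build -> pos
    exclusions: dict[str, str] = field(default_factory=dict)  # rsid -> reason

    def to_frame(self) -> pd.DataFrame:
        builds = sorted({b for pos in self.positions.values() for b in pos})
        rows = []
        for rs in self.rsids:
            row = {"rsid": rs, "alleleA": self.alleles[rs][0],
                   "alleleB": self.alleles[rs][1]}
            for b in builds:
                row[f"pos_{b}"] = self.positions[rs].get(b)
            rows.append(row)
        return pd.DataFrame(rows)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.exclusions.items()),
                            columns=["rsid", "reason"])


def _is_palindromic(pair: frozenset[str]) -> bool:
    return set(pair) in _PALINDROMIC


def _complement(pair: frozenset[str]) -> frozenset[str]:
    return frozenset(_COMPLEMENT[a] for a in pair)


def harmonize_snps(manifests: list[SNPManifest]) -> HarmonizedSNPSet:
    """Intersect manifests by rsID and keep allele-consistent SNPs.

    A SNP is retained when every manifest reports the same unordered allele
    pair, possibly after complementing (a strand flip).  Palindromic pairs
    (A/T, C/G) are excluded as strand-ambiguous: a complement cannot be
    distinguished from identity.  The retained set is invariant to manifest
    order; the agreed allele orientation is taken from the manifest with the
    lexicographically smallest (platform, build) label, so it too is
    order-independent.
    """
    if len(manifests) < 2:
        raise ValueError("harmonization needs at least two manifests")

    per_manifest: list[dict[str, tuple[frozenset[str], int]]] = []
    for m in manifests:
        d = {row.rsid: (frozenset((row.alleleA, row.alleleB)), int(row.pos))
             for row in m.table.itertuples(index=False)}
        per_manifest.append(d)

    union = sorted(set().union(*[set(d) for d in per_manifest]))
    anchor_idx = min(range(len(manifests)),
                     key=lambda i: (manifests[i].platform, manifests[i].build))

    exclusions: dict[str, str] = {}
    retained: list[str] = []
    alleles: dict[str, tuple[str, str]] = {}
    positions: dict[str, dict[str, int]] = {}

    for rs in union:
        if not all(rs in d for d in per_manifest):
            exclusions[rs] = ABSENT
            continue
        sets = [d[rs][0] for d in per_manifest]
        if any(_is_palindromic(s) for s in sets):
            exclusions[rs] = AMBIGUOUS
            continue
        ref_set = sets[0]
        ok = all(s == ref_set or s == _complement(ref_set) for s in sets)
        if not ok:
            exclusions[rs] = MISMATCH
            continue
        retained.append(rs)
        anchor_row = manifests[anchor_idx].table
        arow = anchor_row.loc[anchor_row["rsid"] == rs].iloc[0]
        alleles[rs] = (arow["alleleA"], arow["alleleB"])
        positions[rs] = {manifests[i].build: per_manifest[i][rs][1]
                         for i in range(len(manifests))}

    if not retained:
        raise ValueError("empty harmonized SNP set: no rsID survives "
                         "intersection and allele-consistency filtering")
    return HarmonizedSNPSet(retained, alleles, positions, exclusions)


def subset_genotypes(g: GenotypeMatrix, h: HarmonizedSNPSet) -> GenotypeMatrix:
    """Restrict a genotype matrix to the harmonized SNPs, in harmonized order.

    Dosages are flipped (d -> 2-d) where the matrix's ref/alt orientation is
    reversed relative to the agreed pair (directly or on the opposite
    strand).  SNPs absent from the matrix, or with alleles incompatible with
    the agreed pair, are dropped with a logged count.
    """
    import logging
    log = logging.getLogger(__name__)

    idx = g.snp_index()
    keep_cols: list[int] = []
    keep_ids: list[str] = []
    flip: list[bool] = []
    n_absent = 0
    for rs in h.rsids:
        j = idx.get(rs)
        if j is None:
            n_absent += 1
            continue
        pair = h.alleles[rs]
        obs = (g.ref[j], g.alt[j])
        comp = tuple(_COMPLEMENT.get(a, "?") for a in obs)
        if obs == pair or comp == pair:
            f = False
        elif obs == pair[::-1] or comp == pair[::-1]:
            f = True
        else:
            n_absent += 1
            continue
        keep_cols.append(j)
        keep_ids.append(rs)
        flip.append(f)
    if n_absent:
        log.info("subset_genotypes: %d harmonized SNPs absent/incompatible "
                 "in genotype matrix", n_absent)
    dosage = g.dosage[:, keep_cols].copy()
    flip_arr = np.array(flip, dtype=bool)
    if flip_arr.any():
        cols = dosage[:, flip_arr]
        flipped = np.where(cols == MISSING, MISSING, 2 - cols)
        dosage[:, flip_arr] = flipped
    ref = [h.alleles[rs][0] for rs in keep_ids]
    alt = [h.alleles[rs][1] for rs in keep_ids]
    return GenotypeMatrix(list(g.samples), keep_ids,
                          g.positions[keep_cols].copy(), ref, alt,
                          dosage.astype(np.int8), g.chrom)
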