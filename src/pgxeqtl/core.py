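"""Core genomic containers and the single coordinate convention.

Everything downstream speaks 0-based, half-open intervals. SNPs are recorded
with their conventional 1-based position and convert as ``start = pos - 1``,
``end = pos``. Genes carry an explicit strand because promoter extension is
strand-dependent; peaks and loop anchors may be unstranded (``.``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """Whether the 0-based position falls inside this interval."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with 1-based position."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in VALID_BASES:
                raise ValueError(f"invalid allele {allele!r}")

    @property
    def start(self) -> int:
        """0-based start under the internal half-open convention."""
        return self.pos - 1

    @property
    def end(self) -> int:
        return self.pos

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with mandatory strand (promoter extension needs it)."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with attached SNP metadata.

    Dosages are 0 (hom-ref), 1 (het), 2 (hom-alt) stored as floats so that
    missing calls can be carried as NaN. Missing values are never imputed;
    statistical operations drop them pairwise.

    ``snps`` is indexed by snp_id with columns chrom, pos, ref_allele,
    alt_allele; QC columns (call_rate, maf, hwe_p) are filled by the SNP
    filter stage.
    """

    dosages: pd.DataFrame  # samples x SNPs, float, NaN = missing
    snps: pd.DataFrame  # indexed by snp_id

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snps.index):
            raise ValueError("dosage columns must match SNP metadata index")
        # canonical axis names so round-trips through any dialect compare equal
        self.dosages.index.name = "sample_id"
        self.dosages.columns.name = "snp_id"
        self.snps.index.name = "snp_id"
        if self.snps.index.has_duplicates:
            dupes = self.snps.index[self.snps.index.duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids: {dupes[:5]}")
        values = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {values[i, j]!r} at sample "
                f"{self.dosages.index[i]!r}, SNP {self.dosages.columns[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP over non-missing calls."""
        alt_freq = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(alt_freq, 1.0 - alt_freq)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) over non-missing calls."""
        col = self.dosages[snp_id]
        return (
            int((col == 0).sum()),
            int((col == 1).sum()),
            int((col == 2).sum()),
        )

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        return GenotypeMatrix(
            dosages=self.dosages[snp_ids].copy(),
            snps=self.snps.loc[snp_ids].copy(),
        )

    def snp_records(self) -> list[SnpRecord]:
        return [
            SnpRecord(sid, row.chrom, int(row.pos), row.ref_allele, row.alt_allele)
            for sid, row in self.snps.iterrows()
        ]


class IntervalIndex:
    """Overlap-queryable index over a set of intervals.

    Wraps one interval tree per chromosome; query semantics are strict
    half-open overlap (>= 1 shared bp), matching what a brute-force
    all-pairs scan reports.
    """

    def __init__(self, intervals: pd.DataFrame):
        """``intervals``: DataFrame with chrom/start/end columns."""
        self._trees: dict[str, IntervalTree] = {}
        self._df = intervals.reset_index(drop=True)
        for idx, row in self._df.iterrows():
            tree = self._trees.setdefault(row["chrom"], IntervalTree())
            tree.addi(int(row["start"]), int(row["end"]), idx)

    def query(self, chrom: str, start: int, end: int) -> list[int]:
        """Row indices of intervals overlapping [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(start, end))

    def query_point(self, chrom: str, pos0: int) -> list[int]:
        return self.query(chrom, pos0, pos0 + 1)

    def rows(self, indices) -> pd.DataFrame:
        return self._df.iloc[list(indices)]
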