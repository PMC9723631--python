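"""Readers and writers for every external format the pipeline touches.

Formats
-------
* genotypes: wide TSV (rows = samples, columns = SNP ids, values 0/1/2/NA)
  with a companion ``<path>.snps.tsv`` carrying SNP metadata, or a minimal
  VCF dialect (GT-only, ``0/0``, ``0/1``, ``1/1``, ``./.``);
* BED3+ for peaks and chromatin-state segmentations (0-based half-open);
* BEDPE for chromatin loops, with count and FDR columns;
* typed TSV tables: counts, baseline p-values, LD pairs, GWAS/PheWAS
  catalog rows, reporter-assay allele counts.

Every reader validates its contract and raises :class:`FormatError` with
file/line context; every (format, writer) pair round-trips exactly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, GenotypeMatrix


class FormatError(ValueError):
    """Malformed input file."""


_DOSAGE_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan, "": np.nan}
_GT_TOKENS = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan}

# ---------------------------------------------------------------------------
# genotypes


def _snp_sidecar(path: str) -> str:
    return str(path) + ".snps.tsv"


def read_genotypes(path: str, dialect: str = "tsv") -> GenotypeMatrix:
    """Load a dosage matrix with attached SNP metadata.

    ``dialect="tsv"`` expects a wide sample-by-SNP table; SNP coordinates are
    taken from ``<path>.snps.tsv`` when present, otherwise placeholder
    metadata (pos = SNP rank) is attached so purely statistical use remains
    possible.
    """
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "vcf-min":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    raw = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    if raw.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate SNP id in header")
    values = np.empty(raw.shape, dtype=float)
    for j, snp in enumerate(raw.columns):
        for i, token in enumerate(raw[snp].fillna("NA")):
            try:
                values[i, j] = _DOSAGE_TOKENS[token.strip()]
            except KeyError:
                raise FormatError(
                    f"{path}: invalid dosage {token!r} at sample "
                    f"{raw.index[i]!r}, SNP {snp!r}"
                ) from None
    dosages = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    sidecar = _snp_sidecar(path)
    if os.path.exists(sidecar):
        snps = pd.read_csv(sidecar, sep="\t").set_index("snp_id")
        missing = set(raw.columns) - set(snps.index)
        if missing:
            raise FormatError(f"{sidecar}: missing SNP metadata for {sorted(missing)[:5]}")
        snps = snps.loc[raw.columns]
    else:
        snps = pd.DataFrame(
            {
                "chrom": "chrUn",
                "pos": np.arange(1, raw.shape[1] + 1),
                "ref_allele": "A",
                "alt_allele": "G",
            },
            index=pd.Index(raw.columns, name="snp_id"),
        )
    return GenotypeMatrix(dosages=dosages, snps=snps)


def write_genotypes(gm: GenotypeMatrix, path: str, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        out = gm.dosages.copy()

        def fmt(v: float) -> str:
            return "NA" if np.isnan(v) else str(int(v))

        out = out.map(fmt)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
        meta = gm.snps.copy()
        meta.index.name = "snp_id"
        meta.to_csv(_snp_sidecar(path), sep="\t")
        return
    if dialect == "vcf-min":
        _write_genotypes_vcf(gm, path)
        return
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_vcf(path: str) -> GenotypeMatrix:
    rows, snp_meta, samples = [], [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            if samples is None:
                raise FormatError(f"{path}:{lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}:{lineno}: expected >= 10 columns")
            chrom, pos, snp_id, ref, alt = fields[:5]
            gts = []
            for sample, token in zip(samples, fields[9:]):
                gt = token.split(":")[0]
                try:
                    gts.append(_GT_TOKENS[gt])
                except KeyError:
                    raise FormatError(
                        f"{path}:{lineno}: unsupported GT {gt!r} for {sample}"
                    ) from None
            rows.append(gts)
            snp_meta.append((snp_id, chrom, int(pos), ref, alt))
    snps = pd.DataFrame(
        snp_meta, columns=["snp_id", "chrom", "pos", "ref_allele", "alt_allele"]
    ).set_index("snp_id")
    if snps.index.has_duplicates:
        raise FormatError(f"{path}: duplicate SNP id")
    dosages = pd.DataFrame(
        np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=snps.index,
    )
    return GenotypeMatrix(dosages=dosages, snps=snps)


def _write_genotypes_vcf(gm: GenotypeMatrix, path: str) -> None:
    inv_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.dosages.index)
            + "\n"
        )
        for snp_id, meta in gm.snps.iterrows():
            calls = [
                inv_gt.get(v, "./.") for v in gm.dosages[snp_id].to_numpy()
            ]
            fh.write(
                f"{meta.chrom}\t{int(meta.pos)}\t{snp_id}\t{meta.ref_allele}\t"
                f"{meta.alt_allele}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# BED / BEDPE


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3+ into a sorted DataFrame (chrom, start, end, extras...).

    Extra columns beyond BED3 are preserved under the names
    name/score/strand/fdr/... in file order.
    """
    extra_names = ["name", "score", "strand", "fdr", "extra1", "extra2"]
    records = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            n_extra = max(n_extra, len(fields) - 3)
            records.append([chrom, start, end] + fields[3:])
    columns = ["chrom", "start", "end"] + extra_names[:n_extra]
    df = pd.DataFrame(
        [r + [None] * (len(columns) - len(r)) for r in records], columns=columns
    )
    for col in ("score", "fdr"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str) -> pd.DataFrame:
    """Read loops: BEDPE with count and FDR columns.

    Anchors are canonicalized so anchor1 <= anchor2 by (chrom, start);
    a ``trans`` flag marks inter-chromosomal rows (excluded downstream).
    Returns columns chrom1,start1,end1,chrom2,start2,end2,count,fdr,trans.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"{path}:{lineno}: BEDPE needs >= 8 columns "
                    "(two anchors + count + FDR)"
                )
            c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
            c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
            for s, e in ((s1, e1), (s2, e2)):
                if e <= s or s < 0:
                    raise FormatError(f"{path}:{lineno}: invalid anchor [{s},{e})")
            count, fdr = int(fields[6]), float(fields[7])
            if (c2, s2) < (c1, s1):
                (c1, s1, e1), (c2, s2, e2) = (c2, s2, e2), (c1, s1, e1)
            rows.append((c1, s1, e1, c2, s2, e2, count, fdr, c1 != c2))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "count", "fdr", "trans",
        ],
    )


def write_bedpe(df: pd.DataFrame, path: str) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "count", "fdr"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# typed TSV tables

TABLE_SCHEMAS: dict[str, list[str]] = {
    "counts": ["gene_id"],  # + one column per sample
    "baseline_pvals": ["snp_id", "gene_id", "p"],
    "ld": ["snp_a", "snp_b", "r2"],
    "gwas": ["snp_id", "phenotype", "source"],
    "starr_counts": [
        "locus_id", "snp_id", "condition", "replicate",
        "ref_count", "alt_count", "is_indel", "is_multiallelic",
    ],
}


def read_table(path: str, schema: str) -> pd.DataFrame:
    """Read and validate one of the typed TSV tables."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t")
    for col in TABLE_SCHEMAS[schema]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if schema == "counts":
        count_cols = [c for c in df.columns if c != "gene_id"]
        values = df[count_cols].to_numpy()
        if len(df) and ((values < 0).any() or not np.isfinite(values).all()):
            raise FormatError(f"{path}: counts must be finite and non-negative")
    elif schema == "baseline_pvals":
        p = df["p"].to_numpy(dtype=float)
        ok = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not ok.all():
            raise FormatError(f"{path}: p-values must lie in [0, 1] or be NA")
    elif schema == "ld":
        r2 = df["r2"].to_numpy(dtype=float)
        if len(df) and ((r2 < 0) | (r2 > 1)).any():
            raise FormatError(f"{path}: r2 must lie in [0, 1]")
    elif schema == "starr_counts":
        for col in ("ref_count", "alt_count"):
            if len(df) and (df[col].to_numpy() < 0).any():
                raise FormatError(f"{path}: {col} must be non-negative")
        for col in ("is_indel", "is_multiallelic"):
            df[col] = df[col].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes


def read_genes(path: str) -> list[GeneModel]:
    """Read gene bodies from BED6 (name = gene id; strand required)."""
    df = read_bed(path)
    if "strand" not in df.columns or "name" not in df.columns:
        raise FormatError(f"{path}: gene BED needs name and strand columns")
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneModel(
                gene_id=row["name"],
                interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                strand=row["strand"],
            )
        )
    return genes


def write_genes(genes: list[GeneModel], path: str) -> None:
    df = pd.DataFrame(
        {
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    )
    write_bed(df, path)
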