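"""Chromatin-loop integration at 5 kb anchor bins.

Loops are validated (cis, distance <= 2000 kb, FDR < 0.01, >= 1 anchor in
an H3K27ac peak), genes gain a 2000 bp 5' promoter extension, and features
(SNPs or peaks) are connected to genes either directly (one loop bridging
feature and gene anchors) or through a common contact (two loops sharing
an intermediate anchor bin). Drug-dependent loop dynamics are classified
from the number of distinct connecting loops per condition: induced when
the count rises more than 1.5-fold (or from zero to more than 1),
repressed symmetrically, constitutive otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, IntervalIndex

BIN_SIZE = 5_000


def validate_loops(
    raw: pd.DataFrame,
    h3k27ac_peaks: pd.DataFrame,
    max_distance: int = 2_000_000,
    fdr_max: float = 0.01,
    bin_size: int = BIN_SIZE,
    rebin: bool = False,
) -> pd.DataFrame:
    """Keep cis loops with distance <= max_distance, FDR strictly below
    fdr_max, and at least one anchor overlapping an H3K27ac peak.

    Distance is between anchor start bins. Anchors must be bin-aligned
    (``rebin`` snaps them to the containing bin instead of raising).
    Idempotent: validating a validated set is the identity.
    """
    df = raw.copy()
    aligned = (
        (df["start1"] % bin_size == 0) & (df["end1"] - df["start1"] == bin_size)
        & (df["start2"] % bin_size == 0) & (df["end2"] - df["start2"] == bin_size)
    )
    if not aligned.all():
        if not rebin:
            raise ValueError(
                f"{(~aligned).sum()} loop anchor(s) not aligned to {bin_size} bp "
                "bins (pass rebin=True to snap)"
            )
        for side in ("1", "2"):
            df[f"start{side}"] = (df[f"start{side}"] // bin_size) * bin_size
            df[f"end{side}"] = df[f"start{side}"] + bin_size
    cis = df["chrom1"] == df["chrom2"]
    dist = (df["start2"] - df["start1"]).abs()
    keep = cis & (dist <= max_distance) & (df["fdr"] < fdr_max)
    df = df[keep].reset_index(drop=True)

    if h3k27ac_peaks.empty:
        df["anchor_valid"] = False
        return df.iloc[0:0].reset_index(drop=True)
    index = IntervalIndex(h3k27ac_peaks[["chrom", "start", "end"]])
    valid = np.zeros(len(df), dtype=bool)
    for i, row in df.iterrows():
        valid[i] = bool(
            index.query(row["chrom1"], row["start1"], row["end1"])
            or index.query(row["chrom2"], row["start2"], row["end2"])
        )
    df["anchor_valid"] = valid
    return df[df["anchor_valid"]].reset_index(drop=True)


def gene_anchor(gene: GeneModel, extension: int = 2000) -> GenomicInterval:
    """Gene body extended by ``extension`` bp at the 5' end (strand-aware,
    clipped at 0) to include the promoter."""
    start, end = gene.interval.start, gene.interval.end
    if gene.strand == "+":
        start = max(0, start - extension)
    else:
        end = end + extension
    return GenomicInterval(gene.interval.chrom, start, end, gene.strand)


def _overlapping_loops(
    loops: pd.DataFrame, chrom: str, start: int, end: int
) -> tuple[set[int], set[int]]:
    """(row ids whose anchor1 overlaps, row ids whose anchor2 overlaps)."""
    a1 = set(
        loops.index[
            (loops["chrom1"] == chrom)
            & (loops["start1"] < end)
            & (loops["end1"] > start)
        ]
    )
    a2 = set(
        loops.index[
            (loops["chrom2"] == chrom)
            & (loops["start2"] < end)
            & (loops["end2"] > start)
        ]
    )
    return a1, a2


def connect_feature_to_gene(
    feature: GenomicInterval,
    gene: GeneModel,
    loops: pd.DataFrame,
    extension: int = 2000,
) -> tuple[str, pd.DataFrame]:
    """Connectivity mode between a feature interval and a gene.

    ``direct``: one loop with one anchor overlapping the feature and the
    other overlapping the promoter-extended gene. ``common_contact``: loops
    L1 (feature <-> X) and L2 (X <-> gene) sharing an anchor bin X (one
    intermediate only). Direct takes precedence. Overlap means >= 1 bp.

    Returns (mode, supporting loop rows).
    """
    anchor = gene_anchor(gene, extension)
    f1, f2 = _overlapping_loops(loops, feature.chrom, feature.start, feature.end)
    g1, g2 = _overlapping_loops(loops, anchor.chrom, anchor.start, anchor.end)
    direct = (f1 & g2) | (f2 & g1)
    if direct:
        return "direct", loops.loc[sorted(direct)]

    feat_other = {}
    for i in f1:
        feat_other[i] = (loops.loc[i, "chrom2"], loops.loc[i, "start2"])
    for i in f2 - f1:
        feat_other[i] = (loops.loc[i, "chrom1"], loops.loc[i, "start1"])
    gene_other = {}
    for i in g1:
        gene_other[i] = (loops.loc[i, "chrom2"], loops.loc[i, "start2"])
    for i in g2 - g1:
        gene_other[i] = (loops.loc[i, "chrom1"], loops.loc[i, "start1"])

    shared = set(feat_other.values()) & set(gene_other.values())
    if shared:
        support = sorted(
            [i for i, b in feat_other.items() if b in shared]
            + [i for i, b in gene_other.items() if b in shared]
        )
        return "common_contact", loops.loc[sorted(set(support))]
    return "none", loops.iloc[0:0]


def classify_dynamics(
    n_loops_vehicle: int, n_loops_drug: int, fold_min: float = 1.5
) -> str:
    """Loop-dynamics class from per-condition counts of connecting loops.

    induced: 0 -> more than 1, or fold increase > fold_min;
    repressed: the mirror image; constitutive: both present, neither fold
    exceeded; absent: no loops, or a bare 0 <-> 1 change (a single loop
    appearing from nothing does not satisfy the "to a number > 1" rule).
    Antisymmetric: swapping the counts swaps induced and repressed.
    """
    v, d = n_loops_vehicle, n_loops_drug
    if v < 0 or d < 0:
        raise ValueError("loop counts must be non-negative")
    if v == 0 and d == 0:
        return "absent"
    if v == 0:
        return "induced" if d > 1 else "absent"
    if d == 0:
        return "repressed" if v > 1 else "absent"
    if d / v > fold_min:
        return "induced"
    if v / d > fold_min:
        return "repressed"
    return "constitutive"


def connect_degs_to_peaks(
    deg_genes: list[GeneModel],
    gr_peaks: pd.DataFrame,
    loops_by_condition: dict[str, pd.DataFrame],
    vehicle: str = "vehicle",
    drug: str = "cortisol",
    extension: int = 2000,
) -> pd.DataFrame:
    """Per DEG, loops linking its promoter-extended anchor to any receptor
    peak, per condition, plus the dynamics of the connecting-loop counts.

    Returns (gene_id, n_loops_<vehicle>, n_loops_<drug>, mode, dynamics);
    mode is 'direct' if either condition has a direct connection.
    """
    peak_index = IntervalIndex(gr_peaks[["chrom", "start", "end"]])
    rows = []
    for gene in deg_genes:
        anchor = gene_anchor(gene, extension)
        per_cond = {}
        for cond in (vehicle, drug):
            loops = loops_by_condition[cond]
            g1, g2 = _overlapping_loops(loops, anchor.chrom, anchor.start, anchor.end)
            hits = set()
            for i in g1:
                row = loops.loc[i]
                if peak_index.query(row["chrom2"], row["start2"], row["end2"]):
                    hits.add(i)
            for i in g2:
                row = loops.loc[i]
                if peak_index.query(row["chrom1"], row["start1"], row["end1"]):
                    hits.add(i)
            per_cond[cond] = len(hits)
        mode = "direct" if (per_cond[vehicle] or per_cond[drug]) else "none"
        dyn = (
            classify_dynamics(per_cond[vehicle], per_cond[drug])
            if mode != "none"
            else "absent"
        )
        rows.append((gene.gene_id, per_cond[vehicle], per_cond[drug], mode, dyn))
    return pd.DataFrame(
        rows,
        columns=["gene_id", f"n_loops_{vehicle}", f"n_loops_{drug}", "mode", "dynamics"],
    )


def classify_pgx_loops(
    pgx_pairs: pd.DataFrame,
    snp_meta: pd.DataFrame,
    genes: list[GeneModel],
    loops_by_condition: dict[str, pd.DataFrame],
    vehicle: str = "vehicle",
    drug: str = "cortisol",
    extension: int = 2000,
) -> pd.DataFrame:
    """Connectivity and dynamics per (SNP, gene) pair.

    ``pgx_pairs``: frame with snp_id and gene_id columns. The per-condition
    loop count is the number of distinct supporting loops; dynamics are
    classified on those counts across conditions. Mode is the strongest
    connection seen in either condition (direct > common_contact > none);
    mode 'none' forces dynamics 'absent'.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    mode_rank = {"none": 0, "common_contact": 1, "direct": 2}
    rows = []
    for pr in pgx_pairs.itertuples():
        snp = snp_meta.loc[pr.snp_id]
        feature = GenomicInterval(snp["chrom"], int(snp["pos"]) - 1, int(snp["pos"]))
        gene = gene_by_id[pr.gene_id]
        counts, modes = {}, {}
        for cond in (vehicle, drug):
            mode, support = connect_feature_to_gene(
                feature, gene, loops_by_condition[cond], extension
            )
            modes[cond] = mode
            counts[cond] = len(support)
        best = max(modes.values(), key=lambda m: mode_rank[m])
        dyn = (
            classify_dynamics(counts[vehicle], counts[drug])
            if best != "none"
            else "absent"
        )
        rows.append(
            (pr.snp_id, pr.gene_id, modes[vehicle], modes[drug], best,
             counts[vehicle], counts[drug], dyn)
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "gene_id", f"mode_{vehicle}", f"mode_{drug}", "mode",
                 f"n_loops_{vehicle}", f"n_loops_{drug}", "dynamics"],
    )
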