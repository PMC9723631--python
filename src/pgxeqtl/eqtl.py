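"""Pharmacogenomic-eQTL discovery.

The stage chain: SNP quality control (HWE, call rate, MAF floor), cis
pairing within +/-200 kb of gene bodies, restriction to SNPs in or near
(+/-500 bp) receptor binding peaks, construction of per-sample drug/vehicle
log2 response ratios (which removes genotype effects at baseline and cell
line covariates), a genotype-class one-way ANOVA per pair, BH correction
within each condition's tested set, and the unmasking classification:
a pair is a pharmacogenomic eQTL for a drug when its drug-response
association is FDR-significant, the pair is silent at baseline (reference
cohort p > 0.05 or unreported), and — reported as a separate flag — the
association is lost under agonist+antagonist co-treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .core import GeneModel, GenotypeMatrix, IntervalIndex
from .expression import DrugExpressionSet, normalize


def min_maf_for_expected_homozygote(n_samples: int) -> float:
    """MAF floor q solving n * q^2 = 1, rounded to 2 decimals.

    Under HWE the expected number of minor-allele homozygotes in n samples
    is n * q^2; the smallest q for which that expectation reaches one cell
    line is sqrt(1/n), reported at the 2-decimal precision a study design
    quotes (0.18 at n = 30). Capped at 0.50, the maximum possible minor
    allele frequency.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    q = math.floor(math.sqrt(1.0 / n_samples) * 100.0 + 0.5) / 100.0
    if q > 0.5:
        import warnings

        warnings.warn(
            f"n = {n_samples} cannot guarantee an expected minor homozygote "
            "at any biallelic MAF; capping at 0.50",
            stacklevel=2,
        )
        return 0.5
    return q


def filter_snps(
    gm: GenotypeMatrix,
    hwe_min_p: float = 0.001,
    min_call: float = 0.95,
    min_maf: float = 0.18,
) -> GenotypeMatrix:
    """QC filter: HWE p > hwe_min_p, call rate > min_call, MAF >= min_maf.

    All three metrics are recorded on the SNP metadata of the returned
    matrix (and on the input's metadata, so dropped SNPs remain auditable).
    """
    call_rate = gm.call_rate()
    maf = gm.maf()
    hwe_p = pd.Series(
        {
            sid: stats.hwe_test(*gm.genotype_counts(sid))
            for sid in gm.dosages.columns
        }
    )
    gm.snps["call_rate"] = call_rate
    gm.snps["maf"] = maf
    gm.snps["hwe_p"] = hwe_p
    keep = (hwe_p > hwe_min_p) & (call_rate > min_call) & (maf >= min_maf)
    return gm.subset_snps(gm.snps.index[keep])


def pair_cis(
    gm: GenotypeMatrix, genes: list[GeneModel], window: int = 200_000
) -> pd.DataFrame:
    """All (SNP, gene) pairs with the SNP within +/-window of the gene body.

    The window anchors on the gene body (start - window .. end + window),
    inclusive at both boundaries; distance is 0 inside the gene body and
    the bp gap to the nearest gene edge otherwise.

    Returns a DataFrame (snp_id, gene_id, distance).
    """
    gene_df = pd.DataFrame(
        {
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "gene_id": [g.gene_id for g in genes],
        }
    )
    index = IntervalIndex(gene_df.assign(start=gene_df.start - window,
                                         end=gene_df.end + window + 1))
    rows = []
    for sid, meta in gm.snps.iterrows():
        p0 = int(meta["pos"]) - 1
        for gi in index.query_point(meta["chrom"], p0):
            g = gene_df.iloc[gi]
            if p0 < g["start"]:
                dist = int(g["start"] - p0)
            elif p0 >= g["end"]:
                dist = int(p0 - (g["end"] - 1))
            else:
                dist = 0
            if dist <= window:
                rows.append((sid, g["gene_id"], dist))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "distance"])


def restrict_to_peaks(
    pairs: pd.DataFrame, gm: GenotypeMatrix, peaks: pd.DataFrame, pad: int = 500
) -> pd.DataFrame:
    """Keep pairs whose SNP lies within any peak extended by pad on both
    sides (half-open: a SNP exactly pad bp past the peak edge is kept,
    pad+1 bp is not)."""
    if peaks.empty:
        return pairs.iloc[:0].copy()
    padded = peaks[["chrom", "start", "end"]].copy()
    padded["start"] = np.maximum(0, padded["start"] - pad)
    padded["end"] = padded["end"] + pad
    index = IntervalIndex(padded)
    in_peak = {
        sid: bool(index.query_point(meta["chrom"], int(meta["pos"]) - 1))
        for sid, meta in gm.snps.loc[pairs["snp_id"].unique()].iterrows()
    }
    return pairs[pairs["snp_id"].map(in_peak)].reset_index(drop=True)


def build_response(
    expr: DrugExpressionSet, condition: str, pseudo: float = 0.5
) -> pd.DataFrame:
    """Per-gene, per-sample log2 drug/vehicle response on the CPM scale.

    r = log2-CPM(drug) - log2-CPM(vehicle); pairing by sample removes
    baseline genotype effects and cell-line covariates.
    """
    norm = normalize(expr, pseudo=pseudo)
    if condition not in norm:
        raise KeyError(f"condition {condition!r} absent from expression set")
    return norm[condition] - norm["vehicle"]


def eqtl_scan(
    pairs: pd.DataFrame,
    response: pd.DataFrame,
    gm: GenotypeMatrix,
    merge_sparse: bool = False,
    min_class_size: int = 2,
) -> pd.DataFrame:
    """Genotype-class ANOVA of the drug response for every pair.

    The response is compared across the genotype classes {0, 1, 2} (2-df
    factor ANOVA when all three are populated). Missing genotypes are
    dropped pairwise. A class with fewer than ``min_class_size`` samples
    makes the pair not-testable by default; with ``merge_sparse`` a sparse
    homozygote class is merged into the heterozygote class instead.

    Returns (snp_id, gene_id, f, p, q, n_classes, tested); q is BH over
    the tested pairs.
    """
    rows = []
    dosages = gm.dosages
    for pr in pairs.itertuples():
        if pr.gene_id not in response.index or pr.snp_id not in dosages.columns:
            rows.append((pr.snp_id, pr.gene_id, np.nan, np.nan, 0, False))
            continue
        r = response.loc[pr.gene_id].to_numpy(dtype=float)
        g = dosages[pr.snp_id].to_numpy(dtype=float)
        ok = ~np.isnan(g) & ~np.isnan(r)
        r, g = r[ok], g[ok]
        if merge_sparse:
            for hom in (0.0, 2.0):
                if 0 < (g == hom).sum() < min_class_size:
                    g = np.where(g == hom, 1.0, g)
        groups = [r[g == lvl] for lvl in (0.0, 1.0, 2.0)]
        populated = [grp for grp in groups if len(grp) > 0]
        if len(populated) < 2 or any(len(grp) < min_class_size for grp in populated):
            rows.append((pr.snp_id, pr.gene_id, np.nan, np.nan, len(populated), False))
            continue
        try:
            res = stats.one_way_anova(populated)
        except stats.NotTestable:
            rows.append((pr.snp_id, pr.gene_id, np.nan, np.nan, len(populated), False))
            continue
        rows.append((pr.snp_id, pr.gene_id, res.f, res.p, len(populated), True))
    out = pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "f", "p", "n_classes", "tested"]
    )
    out["q"] = stats.bh_fdr(out["p"].to_numpy())
    return out


def classify_pgx(
    scan_cortisol: pd.DataFrame,
    scan_c297: pd.DataFrame,
    scan_combo: pd.DataFrame,
    baseline_pvals: pd.DataFrame,
    alpha_fdr: float = 0.05,
    alpha_baseline: float = 0.05,
    alpha_loss: float = 0.05,
    missing_baseline_is_silent: bool = True,
) -> pd.DataFrame:
    """The three-way unmasking classification.

    A pair is flagged ``pgx_cortisol`` (resp. ``pgx_c297``) when its
    drug-response q < alpha_fdr under that drug AND it is baseline-silent
    (reference-cohort p > alpha_baseline, with unreported pairs treated as
    silent by default — non-reporting is not evidence of a baseline
    effect). ``antagonist_lost`` flags loss of the association under
    agonist+antagonist co-treatment (nominal p > alpha_loss).

    All raw statistics are carried so every threshold is auditable.
    """
    key = ["snp_id", "gene_id"]
    out = scan_cortisol.rename(
        columns={"f": "f_cortisol", "p": "p_cortisol", "q": "q_cortisol",
                 "tested": "tested_cortisol"}
    )[key + ["f_cortisol", "p_cortisol", "q_cortisol", "tested_cortisol"]]
    for name, scan in (("c297", scan_c297), ("combo", scan_combo)):
        sub = scan.rename(
            columns={"f": f"f_{name}", "p": f"p_{name}", "q": f"q_{name}",
                     "tested": f"tested_{name}"}
        )[key + [f"f_{name}", f"p_{name}", f"q_{name}", f"tested_{name}"]]
        out = out.merge(sub, on=key, how="outer")
    base = baseline_pvals.rename(columns={"p": "baseline_p"})[key + ["baseline_p"]]
    out = out.merge(base, on=key, how="left")

    silent = out["baseline_p"] > alpha_baseline
    if missing_baseline_is_silent:
        silent = silent | out["baseline_p"].isna()
    out["baseline_silent"] = silent
    out["antagonist_lost"] = out["p_combo"].isna() | (out["p_combo"] > alpha_loss)
    out["pgx_cortisol"] = (
        (out["q_cortisol"] < alpha_fdr).fillna(False)
        & out["tested_cortisol"].eq(True)
        & out["baseline_silent"]
    )
    out["pgx_c297"] = (
        (out["q_c297"] < alpha_fdr).fillna(False)
        & out["tested_c297"].eq(True)
        & out["baseline_silent"]
    )
    return out.sort_values(key, kind="stable").reset_index(drop=True)


def tukey_posthoc(
    snp_id: str,
    gene_id: str,
    response: pd.DataFrame,
    gm: GenotypeMatrix,
) -> dict[str, float]:
    """Tukey pairwise adjusted p-values for one pair's genotype classes.

    The headline contrast reported by ``hom_hom`` is homozygous wildtype
    vs homozygous variant. Classes with no samples yield NaN for their
    contrasts.
    """
    r = response.loc[gene_id].to_numpy(dtype=float)
    g = gm.dosages[snp_id].to_numpy(dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(r)
    r, g = r[ok], g[ok]
    groups = [r[g == lvl] for lvl in (0.0, 1.0, 2.0)]
    adj = stats.tukey_hsd(groups)
    labels = {(0, 1): "homref_het", (0, 2): "hom_hom", (1, 2): "het_homalt"}
    out = {name: np.nan for name in labels.values()}
    for pair, p in adj.items():
        out[labels[pair]] = p
    return out
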