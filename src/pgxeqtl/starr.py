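"""Reporter-assay (STARR/MPRA) allele-shift and locus-activity analysis.

Variant-level calls: replicates are pooled by count summation, each
variant's 2x2 table (alt/ref x drug/vehicle) is tested with the two-tailed
Fisher exact test, the alternative-allele percentage difference
delta% = 100 * (Alt_drug/Total_drug - Alt_vehicle/Total_vehicle) is
computed, q-values are BH across tested variants, and a call requires
q < 0.05 and |delta%| > 10.

Locus-level activity: replicate log-CPM compared between conditions with
a two-sample t-test, BH across loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats


def filter_variants(
    counts: pd.DataFrame,
    contrast: tuple[str, str],
    min_total: int = 20,
) -> pd.DataFrame:
    """Drop indels, multi-allelic variants, and variants whose pooled
    (ref+alt over replicates) total is below ``min_total`` in either
    condition of the contrast."""
    sub = counts[counts["condition"].isin(contrast)].copy()
    sub = sub[~sub["is_indel"] & ~sub["is_multiallelic"]]
    totals = (
        sub.assign(total=sub["ref_count"] + sub["alt_count"])
        .groupby(["snp_id", "condition"])["total"]
        .sum()
        .unstack("condition")
        .reindex(columns=list(contrast))
        .fillna(0)
    )
    ok = (totals >= min_total).all(axis=1)
    keep = set(totals.index[ok])
    return sub[sub["snp_id"].isin(keep)].reset_index(drop=True)


def allele_shift_test(
    counts: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    min_delta_pct: float = 10.0,
    signed_delta: bool = False,
) -> pd.DataFrame:
    """Per-variant allelic shift between two conditions.

    ``contrast = (vehicle, drug)``. Replicates are pooled by summation
    before testing (the Fisher test of the summed table). The call rule is
    q < alpha and |delta%| > min_delta_pct (signed delta% > threshold if
    ``signed_delta``).

    Returns (snp_id, locus_id, ref/alt totals per condition, delta_pct,
    fisher_p, q, call).
    """
    vehicle, drug = contrast
    pooled = (
        counts.groupby(["snp_id", "condition"])[["ref_count", "alt_count"]]
        .sum()
        .reset_index()
    )
    locus_of = counts.drop_duplicates("snp_id").set_index("snp_id")["locus_id"]
    rows = []
    for sid, grp in pooled.groupby("snp_id", sort=True):
        by_cond = grp.set_index("condition")
        if vehicle not in by_cond.index or drug not in by_cond.index:
            continue
        rv, av = int(by_cond.loc[vehicle, "ref_count"]), int(by_cond.loc[vehicle, "alt_count"])
        rd, ad = int(by_cond.loc[drug, "ref_count"]), int(by_cond.loc[drug, "alt_count"])
        tv, td = rv + av, rd + ad
        if tv == 0 or td == 0:
            rows.append((sid, locus_of[sid], rv, av, rd, ad, np.nan, np.nan))
            continue
        delta_pct = 100.0 * (ad / td - av / tv)
        p = stats.fisher_exact_two_tailed(av, rv, ad, rd)
        rows.append((sid, locus_of[sid], rv, av, rd, ad, delta_pct, p))
    out = pd.DataFrame(
        rows,
        columns=["snp_id", "locus_id", "ref_vehicle", "alt_vehicle",
                 "ref_drug", "alt_drug", "delta_pct", "fisher_p"],
    )
    out["q"] = stats.bh_fdr(out["fisher_p"].to_numpy())
    effect = out["delta_pct"] if signed_delta else out["delta_pct"].abs()
    out["call"] = (out["q"] < alpha) & (effect > min_delta_pct)
    return out


def locus_activity_test(
    locus_counts: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Per-locus drug-responsive transcription on replicate log-CPM.

    ``locus_counts``: columns locus_id, condition, replicate, count. Each
    (condition, replicate) is one library; the two conditions' replicate
    log-CPM means are compared with a two-sample t statistic whose residual
    variance is pooled across loci (replicate pairs are too few for stable
    per-locus variances, so a common log-CPM variance is estimated from
    all within-condition residuals — the small-replicate strategy of the
    moderated-test family). Needs >= 2 replicates per condition.

    Libraries are normalized median-of-ratios style after the CPM step:
    each library's log-CPM is shifted so its median log-ratio to the
    per-locus geometric-mean reference is zero. Total-count scaling alone
    is composition-biased when a sizeable subset of loci is induced; the
    median-ratio offset is anchored by the non-responsive majority.

    Returns (locus_id, log2_fc, p, q, active).
    """
    vehicle, drug = contrast
    sub = locus_counts[locus_counts["condition"].isin(contrast)]
    mat = sub.pivot_table(
        index="locus_id", columns=["condition", "replicate"], values="count"
    )
    if mat.isna().any().any():
        raise ValueError("every locus needs counts in every library")
    raw = stats.log_cpm(mat.to_numpy(), pseudo=pseudo)
    ref = raw.mean(axis=1, keepdims=True)
    raw = raw - np.median(raw - ref, axis=0, keepdims=True)
    logcpm = pd.DataFrame(raw, index=mat.index, columns=mat.columns)
    v = logcpm[vehicle].to_numpy()
    d = logcpm[drug].to_numpy()
    nv, nd = v.shape[1], d.shape[1]
    if nv < 2 or nd < 2:
        raise stats.NotTestable("need >= 2 replicates per condition")
    resid = np.concatenate(
        [v - v.mean(axis=1, keepdims=True), d - d.mean(axis=1, keepdims=True)],
        axis=1,
    )
    df_resid = mat.shape[0] * (nv - 1 + nd - 1)
    pooled_var = float((resid**2).sum() / df_resid)
    if pooled_var == 0.0:
        p = np.where(d.mean(axis=1) == v.mean(axis=1), 1.0, 0.0)
    else:
        se = np.sqrt(pooled_var * (1.0 / nv + 1.0 / nd))
        t = (d.mean(axis=1) - v.mean(axis=1)) / se
        p = 2.0 * sps.t.sf(np.abs(t), df=df_resid)
    q = stats.bh_fdr(p)
    return pd.DataFrame(
        {
            "locus_id": mat.index,
            "log2_fc": d.mean(axis=1) - v.mean(axis=1),
            "p": p,
            "q": q,
            "active": q < alpha,
        }
    ).reset_index(drop=True)


def replicate_concordance(
    locus_counts: pd.DataFrame, pseudo: float = 0.5
) -> pd.DataFrame:
    """Squared Pearson correlation of log-CPM between replicate pairs,
    per condition. Zero-variance inputs yield NaN."""
    rows = []
    for cond, grp in locus_counts.groupby("condition", sort=True):
        mat = grp.pivot_table(index="locus_id", columns="replicate", values="count")
        logcpm = stats.log_cpm(mat.to_numpy(), pseudo=pseudo)
        reps = list(mat.columns)
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                r = stats.pearson_r(logcpm[:, i], logcpm[:, j])
                rows.append((cond, reps[i], reps[j], r**2 if not np.isnan(r) else np.nan))
    return pd.DataFrame(rows, columns=["condition", "rep_a", "rep_b", "r2"])
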