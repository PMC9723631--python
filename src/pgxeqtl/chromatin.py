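"""Chromatin-state assignment, enrichment, and peak-set reproducibility.

The segmentation (25 states in four broad categories: Promoter, Enhancer,
Transcribed, Repressive/Repetitive/Unknown; a subset of enhancer states
carry a predicted-looping flag) is consumed, not learned: it arrives as a
tiling BED plus a state-metadata table. SNPs take the state of the
half-open interval containing their position. Enrichment per state is
either hypergeometric against a SNP universe or binomial against the
state's bp share of the genome (the default, since the comparison is
against state occupancy).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .core import GenotypeMatrix, IntervalIndex

CATEGORIES = (
    "Promoter",
    "Enhancer",
    "Transcribed",
    "Repressive/Repetitive/Unknown",
)


def validate_segmentation(seg: pd.DataFrame, states: pd.DataFrame) -> None:
    """Check non-overlap per chromosome and full category coverage."""
    for chrom, grp in seg.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segmentation intervals on {chrom}")
    unknown = set(states["category"]) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown state categories: {sorted(unknown)}")


def assign_states(
    snps: pd.DataFrame, seg: pd.DataFrame
) -> pd.Series:
    """State id per SNP (index = snp_id); NaN with a warning for SNPs in
    segmentation gaps.

    ``snps``: frame indexed by snp_id with chrom and 1-based pos columns.
    Boundary positions follow the half-open convention: a SNP at an
    interval's start coordinate belongs to it, one at its end coordinate
    belongs to the next interval.
    """
    index = IntervalIndex(seg[["chrom", "start", "end"]])
    out = {}
    unassigned = []
    for sid, meta in snps.iterrows():
        hits = index.query_point(meta["chrom"], int(meta["pos"]) - 1)
        if hits:
            out[sid] = int(seg.iloc[hits[0]]["state_id"])
        else:
            out[sid] = np.nan
            unassigned.append(sid)
    if unassigned:
        import warnings

        warnings.warn(
            f"{len(unassigned)} SNP(s) fall in segmentation gaps "
            f"(e.g. {unassigned[:3]})",
            stacklevel=2,
        )
    return pd.Series(out, name="state_id")


def state_enrichment(
    assigned: pd.Series,
    seg: pd.DataFrame,
    states: pd.DataFrame,
    universe: str = "genome-bp",
    universe_assigned: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-state enrichment of the assigned SNPs.

    ``universe="genome-bp"``: binomial test of the per-state hit count
    against the state's fraction of segmented bp (invariant to uniform
    genome rescaling). ``universe="snp-set"``: hypergeometric against a
    background SNP assignment (``universe_assigned`` required).

    Returns (state_id, n_snps, fold, p, q) with BH across states.
    """
    n = int(assigned.notna().sum())
    if n == 0:
        raise ValueError("no assigned SNPs")
    hits = assigned.dropna().astype(int).value_counts()
    rows = []
    if universe == "genome-bp":
        bp = seg.assign(width=seg["end"] - seg["start"]).groupby("state_id")["width"].sum()
        total_bp = float(bp.sum())
        for sid in states["state_id"]:
            k = int(hits.get(sid, 0))
            frac = float(bp.get(sid, 0)) / total_bp
            if frac == 0.0:
                rows.append((sid, k, np.nan, 1.0))
                continue
            fold = (k / n) / frac
            p = float(sps.binomtest(k, n, frac, alternative="greater").pvalue)
            rows.append((sid, k, fold, p))
    elif universe == "snp-set":
        if universe_assigned is None:
            raise ValueError("snp-set universe requires universe_assigned")
        uni = universe_assigned.dropna().astype(int)
        N = len(uni)
        uni_counts = uni.value_counts()
        for sid in states["state_id"]:
            k = int(hits.get(sid, 0))
            K = int(uni_counts.get(sid, 0))
            if K == 0:
                rows.append((sid, k, np.nan, 1.0))
                continue
            fold, p = stats.hypergeom_enrichment(min(k, K), n, K, N)
            rows.append((sid, k, fold, p))
    else:
        raise ValueError(f"unknown universe {universe!r}")
    out = pd.DataFrame(rows, columns=["state_id", "n_snps", "fold", "p"])
    out["q"] = stats.bh_fdr(out["p"].to_numpy())
    return out


def category_fractions(assigned: pd.Series, states: pd.DataFrame) -> pd.Series:
    """Fraction of SNPs per broad category, plus the looping-enhancer
    fraction and the unassigned fraction.

    Category fractions are over all SNPs and sum to 1 together with
    ``unassigned``.
    """
    n = len(assigned)
    meta = states.set_index("state_id")
    cat = assigned.map(meta["category"])
    looping = assigned.map(meta["looping_flag"]).eq(True)
    out = {c: float((cat == c).sum()) / n for c in CATEGORIES}
    out["looping_enhancer"] = float(looping.sum()) / n
    out["unassigned"] = float(assigned.isna().sum()) / n
    return pd.Series(out)


def peak_reproducibility(
    peaks_a: pd.DataFrame, peaks_b: pd.DataFrame
) -> tuple[float, float]:
    """(fraction of A peaks with >= 1 bp overlap in B, Pearson r of scores
    over overlapping pairs using each A peak's best-overlap B partner).

    Empty A yields (nan, nan); fewer than 3 overlapping score pairs or
    zero score variance yields r = nan.
    """
    if peaks_a.empty:
        return (np.nan, np.nan)
    if peaks_b.empty:
        return (0.0, np.nan)
    index = IntervalIndex(peaks_b[["chrom", "start", "end"]])
    n_overlap = 0
    sa, sb = [], []
    has_scores = "score" in peaks_a.columns and "score" in peaks_b.columns
    for _, row in peaks_a.iterrows():
        hits = index.query(row["chrom"], int(row["start"]), int(row["end"]))
        if not hits:
            continue
        n_overlap += 1
        if has_scores:
            best, best_ov = None, -1
            for h in hits:
                b = peaks_b.iloc[h]
                ov = min(row["end"], b["end"]) - max(row["start"], b["start"])
                if ov > best_ov:
                    best, best_ov = b, ov
            sa.append(float(row["score"]))
            sb.append(float(best["score"]))
    frac = n_overlap / len(peaks_a)
    r = stats.pearson_r(sa, sb) if len(sa) >= 3 else np.nan
    return (frac, r)


def overlap_fraction_conditions(
    peak_sets: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Directional overlap-fraction matrix: entry (row A, column B) is the
    fraction of A's peaks overlapping >= 1 peak of B."""
    names = list(peak_sets)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            frac, _ = peak_reproducibility(peak_sets[a], peak_sets[b])
            mat.loc[a, b] = frac
    return mat
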