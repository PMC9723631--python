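"""Statistical primitives used by every pipeline stage.

Each routine is written out from its defining formula (group sums for the
one-way F, the step-up recursion for Benjamini-Hochberg, hypergeometric
enumeration for the two-tailed Fisher test, the Tukey-Kramer studentized
range) so that tests can check them against independent oracles: full
enumeration, permutation, and the reference implementations in scipy and
statsmodels. Only distribution functions (CDFs/pmfs) are delegated to
scipy.stats.

Conventions
-----------
* The two-tailed Fisher p-value follows the probability-mass definition:
  the sum over all tables with the observed margins whose hypergeometric
  probability does not exceed that of the observed table (the convention
  of R's ``fisher.test`` and scipy).
* "FDR" always means Benjamini-Hochberg step-up q-values.
* Degenerate inputs (zero variance, monomorphic SNPs) return the null
  answer (F = 0, p = 1) rather than NaN, and truly untestable layouts are
  reported via :class:`NotTestable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class NotTestable(Exception):
    """The requested test is undefined for this data layout."""


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "chisq") -> float:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``method="chisq"`` is the 1-df goodness-of-fit chi-square without
    continuity correction (standard array-QC practice); ``method="exact"``
    is the conditional exact test that enumerates heterozygote counts given
    the observed allele counts, summing probabilities <= that of the
    observed configuration. Monomorphic data is consistent with HWE by
    definition (p = 1).
    """
    for n in (n_AA, n_Aa, n_aa):
        if n < 0 or n != int(n):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0  # monomorphic: HWE trivially satisfied
    if method == "chisq":
        expected = np.array(
            [n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2]
        )
        observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return float(sps.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n_AA, n_Aa, n_aa)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test conditional on allele counts (mid-free, two-sided)."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (label-symmetric below)
    n_a = min(n_a, 2 * n - n_a)
    # P(n_het | allele counts) up to a shared constant:
    # C(n, het) * C(n-het, hom_rare) * 2^het; work in logs.
    parity = n_a % 2
    hets = range(parity, n_a + 1, 2)

    def logprob(het: int) -> float:
        hom_rare = (n_a - het) // 2
        hom_common = n - het - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2.0)
        )
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    observed = probs[list(hets).index(min(n_Aa, n_a))]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# ANOVA and Tukey


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Groups with no observations are dropped. All-identical data yields
    F = 0, p = 1 (no evidence of group structure, not an error).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2 or n <= k:
        raise NotTestable(f"need >= 2 populated groups and n > k (k={k}, n={n})")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w)
        return AnovaResult(np.inf, 0.0, df_b, df_w)
    f = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(float(f), float(sps.f.sf(f, df_b, df_w)), df_b, df_w)


def tukey_hsd(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Tukey-Kramer pairwise adjusted p-values over all group pairs.

    Keys are (i, j) indices into ``groups`` (i < j). For k = 2 the
    studentized-range distribution reduces exactly to |t|*sqrt(2), so the
    pooled two-sided t p-value is returned directly (numerically exact
    rather than quadrature-based). Pairs whose pooled variance is undefined
    are assigned NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    populated = [i for i, g in enumerate(arrays) if len(g) > 0]
    k = len(populated)
    n = sum(len(arrays[i]) for i in populated)
    df_w = n - k
    if k < 2 or df_w < 1:
        raise NotTestable("need >= 2 populated groups with residual df")
    ss_within = sum(((arrays[i] - arrays[i].mean()) ** 2).sum() for i in populated)
    msw = ss_within / df_w
    out: dict[tuple[int, int], float] = {}
    for a_pos in range(len(populated)):
        for b_pos in range(a_pos + 1, len(populated)):
            i, j = populated[a_pos], populated[b_pos]
            gi, gj = arrays[i], arrays[j]
            if msw == 0.0:
                out[(i, j)] = 1.0 if gi.mean() == gj.mean() else 0.0
                continue
            se = math.sqrt(msw / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
            q = abs(gi.mean() - gj.mean()) / se
            if k == 2:
                out[(i, j)] = float(2.0 * sps.t.sf(q / math.sqrt(2.0), df_w))
            else:
                out[(i, j)] = float(sps.studentized_range.sf(q, k, df_w))
    return out


# ---------------------------------------------------------------------------
# Fisher exact and hypergeometric enrichment


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates the full hypergeometric support of tables with the observed
    margins and sums the probabilities of all tables as or less probable
    than the observed one (relative tolerance 1e-7, matching R).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table cells must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = sps.hypergeom.pmf(support, n, row1, col1)
    observed = probs[int(np.searchsorted(support, a))]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-7)].sum()))


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric p for k hits in n
    draws against a category of size K in a universe of size N.

    Returns (fold, p) where fold = (k/n)/(K/N) and p = P(X >= k).
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError("need k <= min(n, K), n <= N, K <= N")
    if K == 0 or n == 0:
        return (np.nan, 1.0)
    fold = (k / n) / (K / N)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return (fold, min(1.0, p))


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaNs are propagated and excluded from the number of tests m.
    q(i) = min over j >= i (rank order) of p(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qvals = np.empty(m)
    qvals[order] = q
    out[mask] = qvals
    return out


# ---------------------------------------------------------------------------
# correlation, qPCR arithmetic, normalization


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN if either variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return np.nan
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method."""
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct))


def log_cpm(counts, pseudo: float = 0.5) -> np.ndarray:
    """log2 counts-per-million, columns = libraries.

    log2((count + pseudo) / (library_size + pseudo) * 1e6); the default
    pseudo-count of 0.5 keeps zero counts finite.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
        squeeze = True
    else:
        squeeze = False
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("every library must have a positive total count")
    out = np.log2((counts + pseudo) / (libsize + pseudo) * 1e6)
    return out[:, 0] if squeeze else out
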