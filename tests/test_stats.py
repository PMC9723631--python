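"""stats primitives versus independent oracles (scipy, statsmodels,
enumeration, permutation)."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from pgxeqtl import stats


# ---------------------------------------------------------------------------
# HWE


def test_hwe_chisq_matches_direct_chisquare():
    for counts in [(10, 12, 8), (50, 20, 30), (5, 25, 5), (90, 9, 1)]:
        n = sum(counts)
        p_hat = (2 * counts[0] + counts[1]) / (2 * n)
        expected = [n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
        assert stats.hwe_test(*counts) == pytest.approx(sps.chi2.sf(chi2, 1))


def test_hwe_monomorphic_is_one():
    assert stats.hwe_test(30, 0, 0) == 1.0
    assert stats.hwe_test(0, 0, 30) == 1.0


def test_hwe_exact_enumeration_oracle():
    """Exact test equals a brute-force enumeration of heterozygote counts."""
    def oracle(n_AA, n_Aa, n_aa):
        n = n_AA + n_Aa + n_aa
        n_a = min(2 * n_aa + n_Aa, 2 * n - (2 * n_aa + n_Aa))
        def prob(het):
            hom_r = (n_a - het) // 2
            hom_c = n - het - hom_r
            return (
                math.factorial(n)
                / (math.factorial(het) * math.factorial(hom_r) * math.factorial(hom_c))
                * 2.0**het
            )
        hets = list(range(n_a % 2, n_a + 1, 2))
        probs = np.array([prob(h) for h in hets], dtype=float)
        probs /= probs.sum()
        obs = probs[hets.index(min(n_Aa, n_a))]
        return probs[probs <= obs * (1 + 1e-12)].sum()

    for counts in [(5, 5, 5), (10, 2, 8), (12, 6, 2), (3, 14, 3), (8, 0, 8)]:
        assert stats.hwe_test(*counts, method="exact") == pytest.approx(
            oracle(*counts), rel=1e-10
        )


def test_hwe_rejects_bad_counts():
    with pytest.raises(ValueError):
        stats.hwe_test(-1, 2, 3)
    with pytest.raises(ValueError):
        stats.hwe_test(0, 0, 0)


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_matches_scipy_f_oneway(rng):
    for _ in range(25):
        k = int(rng.integers(2, 5))
        groups = [rng.normal(rng.normal(), 1.0, size=int(rng.integers(3, 12)))
                  for _ in range(k)]
        ours = stats.one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert ours.f == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)


def test_anova_identical_data_is_null():
    res = stats.one_way_anova([np.ones(5), np.ones(4), np.ones(3)])
    assert res.f == 0.0 and res.p == 1.0


def test_anova_zero_within_variance_with_signal():
    res = stats.one_way_anova([np.zeros(3), np.ones(3)])
    assert res.p == 0.0 and np.isinf(res.f)


def test_anova_untestable():
    with pytest.raises(stats.NotTestable):
        stats.one_way_anova([np.ones(3)])
    with pytest.raises(stats.NotTestable):
        stats.one_way_anova([np.array([1.0]), np.array([2.0])])


def test_anova_drops_empty_groups(rng):
    a, b = rng.normal(size=6), rng.normal(size=7)
    full = stats.one_way_anova([a, np.array([]), b])
    ref = sps.f_oneway(a, b)
    assert full.p == pytest.approx(ref.pvalue, rel=1e-12)


# ---------------------------------------------------------------------------
# Tukey


def test_tukey_k2_equals_pooled_t(rng):
    for _ in range(20):
        a = rng.normal(size=int(rng.integers(3, 15)))
        b = rng.normal(loc=rng.normal(), size=int(rng.integers(3, 15)))
        ours = stats.tukey_hsd([a, b])[(0, 1)]
        ref = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert abs(ours - ref) < 1e-9


def test_tukey_k3_matches_scipy(rng):
    for _ in range(10):
        groups = [rng.normal(rng.normal(), 1.0, size=int(rng.integers(4, 10)))
                  for _ in range(3)]
        ours = stats.tukey_hsd(groups)
        # scipy's tukey_hsd is the balanced/Tukey-Kramer reference
        ref = sps.tukey_hsd(*groups)
        for (i, j), p in ours.items():
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-6)


def test_tukey_skips_empty_groups(rng):
    a, b = rng.normal(size=5), rng.normal(size=5)
    out = stats.tukey_hsd([a, np.array([]), b])
    assert set(out) == {(0, 2)}


# ---------------------------------------------------------------------------
# Fisher exact


def test_fisher_matches_scipy_random_tables(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        if a + b + c + d == 0:
            continue
        ours = stats.fisher_exact_two_tailed(a, b, c, d)
        ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_degenerate_margins():
    assert stats.fisher_exact_two_tailed(5, 0, 7, 0) == 1.0
    assert stats.fisher_exact_two_tailed(0, 0, 3, 4) == 1.0


def test_fisher_symmetry():
    # transposing the table leaves the p-value unchanged
    assert stats.fisher_exact_two_tailed(3, 10, 12, 2) == pytest.approx(
        stats.fisher_exact_two_tailed(3, 12, 10, 2), rel=1e-12
    )


def test_fisher_rejects_negative():
    with pytest.raises(ValueError):
        stats.fisher_exact_two_tailed(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# BH FDR


def _bh_hand(p):
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def test_bh_matches_hand_stepup_and_statsmodels(rng):
    for _ in range(20):
        p = rng.random(size=int(rng.integers(1, 60)))
        ours = stats.bh_fdr(p)
        np.testing.assert_allclose(ours, _bh_hand(p), rtol=1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, rtol=1e-10)


def test_bh_fixed_vector():
    p = np.array([0.01, 0.04, 0.03, 0.005])
    np.testing.assert_allclose(stats.bh_fdr(p), [0.02, 0.04, 0.04, 0.02])


def test_bh_nan_excluded_from_m():
    p = np.array([0.01, np.nan, 0.04])
    out = stats.bh_fdr(p)
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], stats.bh_fdr(np.array([0.01, 0.04])))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        stats.bh_fdr([0.5, 1.5])


def test_bh_monotone_in_p(rng):
    p = np.sort(rng.random(30))
    q = stats.bh_fdr(p)
    assert (np.diff(q) >= -1e-15).all()


# ---------------------------------------------------------------------------
# enrichment / correlation / misc


def test_hypergeom_enrichment_matches_scipy():
    fold, p = stats.hypergeom_enrichment(8, 20, 50, 500)
    assert fold == pytest.approx((8 / 20) / (50 / 500))
    assert p == pytest.approx(sps.hypergeom.sf(7, 500, 50, 20))


def test_hypergeom_enrichment_empty_category():
    fold, p = stats.hypergeom_enrichment(0, 10, 0, 100)
    assert np.isnan(fold) and p == 1.0


def test_pearson_matches_numpy(rng):
    x, y = rng.normal(size=50), rng.normal(size=50)
    assert stats.pearson_r(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-12)


def test_pearson_zero_variance_nan():
    assert np.isnan(stats.pearson_r(np.ones(5), np.arange(5.0)))


def test_delta_delta_ct():
    # one cycle less in target vs reference after treatment => 2x expression
    assert stats.delta_delta_ct(20.0, 18.0, 21.0, 18.0) == pytest.approx(2.0)
    assert stats.delta_delta_ct(20.0, 18.0, 20.0, 18.0) == pytest.approx(1.0)


def test_log_cpm_basic():
    counts = np.array([[10, 0], [90, 100]], dtype=float)
    out = stats.log_cpm(counts, pseudo=0.5)
    assert out.shape == (2, 2)
    expected = np.log2((10 + 0.5) / (100 + 0.5) * 1e6)
    assert out[0, 0] == pytest.approx(expected)


def test_log_cpm_rejects_negative_and_empty_library():
    with pytest.raises(ValueError):
        stats.log_cpm(np.array([[-1.0], [2.0]]))
    with pytest.raises(ValueError):
        stats.log_cpm(np.zeros((3, 1)))
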