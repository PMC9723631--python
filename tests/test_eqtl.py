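"""PGx-eQTL discovery: QC, cis pairing, peak restriction, scan, and the
unmasking classification."""

import numpy as np
import pandas as pd
import pytest

from pgxeqtl import eqtl, stats
from pgxeqtl.core import GeneModel, GenomicInterval
from tests.conftest import make_gm


# ---------------------------------------------------------------------------
# MAF threshold derivation


def test_maf_threshold_values():
    assert eqtl.min_maf_for_expected_homozygote(30) == 0.18
    assert eqtl.min_maf_for_expected_homozygote(100) == 0.10
    assert eqtl.min_maf_for_expected_homozygote(25) == 0.20
    assert eqtl.min_maf_for_expected_homozygote(10_000) == 0.01


def test_maf_threshold_is_rounded_exact_solution():
    for n in (5, 17, 30, 61, 400):
        q = eqtl.min_maf_for_expected_homozygote(n)
        # two-decimal rounding of sqrt(1/n), the exact n*q^2 = 1 solution
        assert abs(q - np.sqrt(1.0 / n)) <= 0.005 + 1e-12


def test_maf_threshold_caps_at_half():
    with pytest.warns(UserWarning):
        assert eqtl.min_maf_for_expected_homozygote(2) == 0.5
    with pytest.raises(ValueError):
        eqtl.min_maf_for_expected_homozygote(0)


# ---------------------------------------------------------------------------
# SNP QC


def _qc_matrix():
    """Four SNPs: clean / low call rate / low MAF / HWE violating."""
    n = 30
    rng = np.random.default_rng(5)
    clean = rng.binomial(2, 0.4, size=n).astype(float)
    low_call = clean.copy()
    low_call[:2] = np.nan  # call rate 28/30 < 0.95
    low_maf = np.zeros(n)
    low_maf[:5] = 1.0  # MAF 5/60 = 0.083
    hwe_bad = np.array([0.0, 2.0] * (n // 2))  # no hets at freq 0.5
    return make_gm(np.column_stack([clean, low_call, low_maf, hwe_bad]))


def test_filter_snps_each_criterion():
    gm = _qc_matrix()
    kept = eqtl.filter_snps(gm)
    assert list(kept.snps.index) == ["rs0000"]
    # metrics recorded for all SNPs, including dropped ones
    assert {"call_rate", "maf", "hwe_p"} <= set(gm.snps.columns)
    assert gm.snps.loc["rs0001", "call_rate"] == pytest.approx(28 / 30)


def test_filter_snps_call_rate_boundary():
    # 29/30 = 0.9667 passes the strict > 0.95 rule; 28/30 does not
    n = 30
    rng = np.random.default_rng(8)
    base = rng.binomial(2, 0.4, size=n).astype(float)
    one_missing = base.copy()
    one_missing[0] = np.nan
    gm = make_gm(np.column_stack([base, one_missing]))
    kept = eqtl.filter_snps(gm)
    assert "rs0001" in kept.snps.index


def test_filter_snps_maf_boundary():
    # MAF exactly 0.18 is kept (>= rule); just below is dropped
    n = 50
    at = np.zeros(n)
    at[:18] = 1.0  # alt freq 18/100 = 0.18
    below = np.zeros(n)
    below[:17] = 1.0  # 0.17
    gm = make_gm(np.column_stack([at, below]))
    kept = eqtl.filter_snps(gm, hwe_min_p=0.0)  # isolate the MAF rule
    assert list(kept.snps.index) == ["rs0000"]


# ---------------------------------------------------------------------------
# cis pairing


def _gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end), strand)


def test_pair_cis_window_boundaries():
    genes = [_gene("g1", "chr1", 1_000_000, 1_010_000)]
    # SNP 0-based starts: exactly 200 kb upstream, 200 kb + 1, inside body,
    # exactly 200 kb downstream of the body end
    positions0 = [800_000, 799_999, 1_005_000, 1_209_999, 1_210_000]
    dosages = np.tile([0.0, 1.0, 2.0], (len(positions0), 1)).T
    gm = make_gm(dosages)
    gm.snps["pos"] = [p + 1 for p in positions0]
    pairs = eqtl.pair_cis(gm, genes, window=200_000)
    got = dict(zip(pairs["snp_id"], pairs["distance"]))
    assert got == {
        "rs0000": 200_000,
        "rs0002": 0,
        "rs0003": 200_000,
    }


def test_pair_cis_requires_same_chromosome():
    genes = [_gene("g1", "chr2", 0, 10_000)]
    gm = make_gm(np.zeros((3, 1)))
    gm.snps["pos"] = [5_000]
    assert eqtl.pair_cis(gm, genes).empty


# ---------------------------------------------------------------------------
# peak restriction


def test_restrict_to_peaks_pad_boundary():
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_300]})
    positions0 = [9_500, 9_499, 10_100, 10_799, 10_800]
    gm = make_gm(np.zeros((2, len(positions0))))
    gm.snps["pos"] = [p + 1 for p in positions0]
    pairs = pd.DataFrame(
        {"snp_id": list(gm.snps.index), "gene_id": "g1", "distance": 0}
    )
    kept = eqtl.restrict_to_peaks(pairs, gm, peaks, pad=500)
    # [start-500, end+500) half-open: 9_500 in, 9_499 out, 10_799 in, 10_800 out
    assert set(kept["snp_id"]) == {"rs0000", "rs0002", "rs0003"}


def test_restrict_to_peaks_empty_peaks():
    gm = make_gm(np.zeros((2, 1)))
    pairs = pd.DataFrame({"snp_id": ["rs0000"], "gene_id": ["g1"], "distance": [0]})
    assert eqtl.restrict_to_peaks(pairs, gm, pd.DataFrame()).empty


# ---------------------------------------------------------------------------
# response and scan


def _response(gene_ids, values):
    return pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"S{i:02d}" for i in range(np.shape(values)[1])],
    )


def test_eqtl_scan_recovers_planted_effect(rng):
    n = 30
    g = rng.binomial(2, 0.4, size=n).astype(float)
    r_true = g * 1.0 + rng.normal(0, 0.3, size=n)
    r_null = rng.normal(0, 0.3, size=n)
    gm = make_gm(np.column_stack([g, g]))
    response = _response(["gA", "gB"], np.vstack([r_true, r_null]))
    pairs = pd.DataFrame(
        {"snp_id": ["rs0000", "rs0001"], "gene_id": ["gA", "gB"], "distance": 0}
    )
    out = eqtl.eqtl_scan(pairs, response, gm)
    assert out.loc[0, "p"] < 1e-6
    assert out.loc[1, "p"] > 0.01


def test_eqtl_scan_singleton_class_not_testable():
    g = np.array([0.0] * 14 + [1.0] * 15 + [2.0])  # one hom-alt sample
    gm = make_gm(g[:, None])
    response = _response(["gA"], np.arange(30.0)[None, :])
    pairs = pd.DataFrame({"snp_id": ["rs0000"], "gene_id": ["gA"], "distance": [0]})
    out = eqtl.eqtl_scan(pairs, response, gm)
    assert not out.loc[0, "tested"]
    assert np.isnan(out.loc[0, "p"])
    merged = eqtl.eqtl_scan(pairs, response, gm, merge_sparse=True)
    assert merged.loc[0, "tested"]
    assert merged.loc[0, "n_classes"] == 2


def test_eqtl_scan_missing_genotypes_dropped_pairwise(rng):
    g = rng.binomial(2, 0.5, size=30).astype(float)
    g[:3] = np.nan
    gm = make_gm(g[:, None])
    response = _response(["gA"], rng.normal(size=(1, 30)))
    pairs = pd.DataFrame({"snp_id": ["rs0000"], "gene_id": ["gA"], "distance": [0]})
    out = eqtl.eqtl_scan(pairs, response, gm)
    r = response.loc["gA"].to_numpy()[3:]
    ref = stats.one_way_anova([r[g[3:] == k] for k in (0.0, 1.0, 2.0)])
    assert out.loc[0, "p"] == pytest.approx(ref.p)


def test_eqtl_scan_unknown_gene_or_snp_untested():
    gm = make_gm(np.zeros((5, 1)))
    response = _response(["gA"], np.zeros((1, 5)))
    pairs = pd.DataFrame(
        {"snp_id": ["rs0000", "rsX"], "gene_id": ["gZ", "gA"], "distance": 0}
    )
    out = eqtl.eqtl_scan(pairs, response, gm)
    assert not out["tested"].any()


def test_eqtl_scan_q_is_bh_over_tested(rng):
    n = 30
    gs = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
    gm = make_gm(gs)
    response = _response(
        [f"g{j}" for j in range(5)], rng.normal(size=(5, n))
    )
    pairs = pd.DataFrame(
        {"snp_id": list(gm.snps.index), "gene_id": [f"g{j}" for j in range(5)],
         "distance": 0}
    )
    out = eqtl.eqtl_scan(pairs, response, gm)
    np.testing.assert_allclose(
        out["q"].to_numpy(), stats.bh_fdr(out["p"].to_numpy())
    )


# ---------------------------------------------------------------------------
# classification


def _scan_frame(rows):
    return pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "f", "p", "n_classes", "tested", "q"]
    )


def test_classify_pgx_unmasking_rules():
    cort = _scan_frame([
        ("rs1", "g1", 30.0, 1e-6, 3, True, 0.001),   # significant
        ("rs2", "g2", 25.0, 1e-5, 3, True, 0.004),   # significant, baseline active
        ("rs3", "g3", 1.0, 0.5, 3, True, 0.6),       # not significant
    ])
    c297 = _scan_frame([("rs1", "g1", 1.0, 0.4, 3, True, 0.6)])
    combo = _scan_frame([
        ("rs1", "g1", 0.5, 0.7, 3, True, 0.9),       # lost under antagonist
        ("rs2", "g2", 20.0, 1e-4, 3, True, 0.01),    # retained
    ])
    baseline = pd.DataFrame(
        {"snp_id": ["rs2"], "gene_id": ["g2"], "p": [0.001]}  # baseline-active
    )
    out = eqtl.classify_pgx(cort, c297, combo, baseline).set_index("snp_id")
    assert bool(out.loc["rs1", "pgx_cortisol"])        # silent (unreported)
    assert not bool(out.loc["rs2", "pgx_cortisol"])    # baseline-active
    assert not bool(out.loc["rs3", "pgx_cortisol"])    # not significant
    assert bool(out.loc["rs1", "antagonist_lost"])
    assert not bool(out.loc["rs2", "antagonist_lost"])
    assert bool(out.loc["rs3", "antagonist_lost"])     # combo unreported => lost


def test_classify_pgx_missing_baseline_flag():
    cort = _scan_frame([("rs1", "g1", 30.0, 1e-6, 3, True, 0.001)])
    empty = _scan_frame([])
    baseline = pd.DataFrame({"snp_id": [], "gene_id": [], "p": []})
    strict = eqtl.classify_pgx(
        cort, empty, empty, baseline, missing_baseline_is_silent=False
    )
    assert not strict["pgx_cortisol"].any()


# ---------------------------------------------------------------------------
# post-hoc


def test_tukey_posthoc_labels_and_values(rng):
    n = 30
    g = np.array([0.0] * 12 + [1.0] * 12 + [2.0] * 6)
    r = g * 1.0 + rng.normal(0, 0.3, size=n)
    gm = make_gm(g[:, None])
    response = _response(["gA"], r[None, :])
    out = eqtl.tukey_posthoc("rs0000", "gA", response, gm)
    assert set(out) == {"homref_het", "hom_hom", "het_homalt"}
    ref = stats.tukey_hsd([r[g == k] for k in (0.0, 1.0, 2.0)])
    assert out["hom_hom"] == pytest.approx(ref[(0, 2)])
    assert out["hom_hom"] < 1e-4
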