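"""Loop validation, connectivity (with a brute-force oracle), dynamics."""

import numpy as np
import pandas as pd
import pytest

from pgxeqtl import loops
from pgxeqtl.core import GeneModel, GenomicInterval

BIN = loops.BIN_SIZE


def _loop(c1, b1, c2, b2, count=4, fdr=0.001):
    return (c1, b1 * BIN, (b1 + 1) * BIN, c2, b2 * BIN, (b2 + 1) * BIN, count, fdr)


def _loops(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "count", "fdr"],
    )


def _peaks_covering_bins(bins, chrom="chr1"):
    return pd.DataFrame(
        [(chrom, b * BIN, (b + 1) * BIN) for b in bins],
        columns=["chrom", "start", "end"],
    )


def _gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end), strand)


# ---------------------------------------------------------------------------
# validation


def test_validate_loops_filters():
    peaks = _peaks_covering_bins(range(0, 500))
    raw = _loops([
        _loop("chr1", 0, "chr1", 10),                       # valid
        _loop("chr1", 0, "chr2", 10),                       # trans
        _loop("chr1", 0, "chr1", 401),                      # > 2000 kb
        _loop("chr1", 0, "chr1", 400),                      # exactly 2000 kb: kept
        _loop("chr1", 0, "chr1", 10, fdr=0.01),             # FDR not < 0.01
        _loop("chr1", 600, "chr1", 610),                    # no H3K27ac anchor
    ])
    out = loops.validate_loops(raw, peaks)
    assert len(out) == 2
    assert set(out["start2"]) == {10 * BIN, 400 * BIN}


def test_validate_loops_rebin_and_idempotence():
    peaks = _peaks_covering_bins(range(0, 20))
    raw = _loops([
        ("chr1", 1234, 6234, "chr1", 50_100, 55_100, 3, 0.0001),
    ])
    with pytest.raises(ValueError, match="not aligned"):
        loops.validate_loops(raw, peaks)
    out = loops.validate_loops(raw, peaks, rebin=True)
    assert out.loc[0, "start1"] == 0 and out.loc[0, "start2"] == 50_000
    again = loops.validate_loops(out.drop(columns=["anchor_valid"]), peaks)
    pd.testing.assert_frame_equal(again, out)


def test_validate_loops_empty_peaks_removes_all():
    raw = _loops([_loop("chr1", 0, "chr1", 10)])
    out = loops.validate_loops(raw, pd.DataFrame(columns=["chrom", "start", "end"]))
    assert out.empty


# ---------------------------------------------------------------------------
# gene anchors


def test_gene_anchor_strand_aware():
    plus = loops.gene_anchor(_gene("g", "chr1", 10_000, 20_000, "+"))
    assert (plus.start, plus.end) == (8_000, 20_000)
    minus = loops.gene_anchor(_gene("g", "chr1", 10_000, 20_000, "-"))
    assert (minus.start, minus.end) == (10_000, 22_000)
    clipped = loops.gene_anchor(_gene("g", "chr1", 500, 2_000, "+"))
    assert clipped.start == 0


# ---------------------------------------------------------------------------
# connectivity


def test_connect_direct():
    gene = _gene("g", "chr1", 100_000, 110_000, "+")  # anchor bins 19..21
    feature = GenomicInterval("chr1", 12_000, 12_001)  # bin 2
    lp = _loops([_loop("chr1", 2, "chr1", 20)])
    mode, support = loops.connect_feature_to_gene(feature, gene, lp)
    assert mode == "direct"
    assert len(support) == 1


def test_connect_common_contact_single_intermediate():
    gene = _gene("g", "chr1", 100_000, 110_000, "+")
    feature = GenomicInterval("chr1", 12_000, 12_001)   # bin 2
    lp = _loops([
        _loop("chr1", 2, "chr1", 50),    # feature <-> X
        _loop("chr1", 50, "chr1", 20),   # X <-> gene
    ])
    mode, support = loops.connect_feature_to_gene(feature, gene, lp)
    assert mode == "common_contact"
    assert len(support) == 2


def test_connect_two_hops_is_not_connected():
    gene = _gene("g", "chr1", 100_000, 110_000, "+")
    feature = GenomicInterval("chr1", 12_000, 12_001)
    lp = _loops([
        _loop("chr1", 2, "chr1", 40),
        _loop("chr1", 40, "chr1", 60),
        _loop("chr1", 60, "chr1", 20),
    ])
    mode, support = loops.connect_feature_to_gene(feature, gene, lp)
    assert mode == "none"
    assert support.empty


def test_connect_direct_takes_precedence():
    gene = _gene("g", "chr1", 100_000, 110_000, "+")
    feature = GenomicInterval("chr1", 12_000, 12_001)
    lp = _loops([
        _loop("chr1", 2, "chr1", 20),    # direct
        _loop("chr1", 2, "chr1", 50),
        _loop("chr1", 50, "chr1", 20),   # also a common contact
    ])
    mode, support = loops.connect_feature_to_gene(feature, gene, lp)
    assert mode == "direct"
    assert len(support) == 1


def _brute_force_mode(feature, gene, lp, extension=2000):
    """Independent connectivity oracle: explicit anchor-overlap search."""
    anchor = loops.gene_anchor(gene, extension)

    def hits_feature(c, s, e):
        return c == feature.chrom and s < feature.end and feature.start < e

    def hits_gene(c, s, e):
        return c == anchor.chrom and s < anchor.end and anchor.start < e

    rows = list(lp.itertuples())
    for r in rows:
        if (hits_feature(r.chrom1, r.start1, r.end1) and hits_gene(r.chrom2, r.start2, r.end2)) or (
            hits_feature(r.chrom2, r.start2, r.end2) and hits_gene(r.chrom1, r.start1, r.end1)
        ):
            return "direct"
    for r1 in rows:
        ends1 = []
        if hits_feature(r1.chrom1, r1.start1, r1.end1):
            ends1.append((r1.chrom2, r1.start2))
        if hits_feature(r1.chrom2, r1.start2, r1.end2):
            ends1.append((r1.chrom1, r1.start1))
        for r2 in rows:
            ends2 = []
            if hits_gene(r2.chrom1, r2.start1, r2.end1):
                ends2.append((r2.chrom2, r2.start2))
            if hits_gene(r2.chrom2, r2.start2, r2.end2):
                ends2.append((r2.chrom1, r2.start1))
            if set(ends1) & set(ends2):
                return "common_contact"
    return "none"


def test_connectivity_matches_brute_force_on_random_sets(rng):
    gene = _gene("g", "chr1", 500_000, 510_000, "+")
    for _ in range(60):
        n = int(rng.integers(1, 25))
        bins = rng.integers(0, 150, size=(n, 2))
        lp = _loops([
            _loop("chr1", int(b1), "chr1", int(b2)) for b1, b2 in bins
        ])
        fbin = int(rng.integers(0, 150))
        feature = GenomicInterval("chr1", fbin * BIN + 100, fbin * BIN + 101)
        mode, _ = loops.connect_feature_to_gene(feature, gene, lp)
        assert mode == _brute_force_mode(feature, gene, lp)


# ---------------------------------------------------------------------------
# dynamics


def _dynamics_oracle(v, d, fold=1.5):
    if v == 0 and d == 0:
        return "absent"
    if v == 0:
        return "induced" if d > 1 else "absent"
    if d == 0:
        return "repressed" if v > 1 else "absent"
    if d / v > fold:
        return "induced"
    if v / d > fold:
        return "repressed"
    return "constitutive"


def test_classify_dynamics_exhaustive_grid():
    for v in range(11):
        for d in range(11):
            assert loops.classify_dynamics(v, d) == _dynamics_oracle(v, d)


def test_classify_dynamics_antisymmetric():
    swap = {"induced": "repressed", "repressed": "induced",
            "constitutive": "constitutive", "absent": "absent"}
    for v in range(11):
        for d in range(11):
            assert loops.classify_dynamics(d, v) == swap[loops.classify_dynamics(v, d)]


def test_classify_dynamics_rejects_negative():
    with pytest.raises(ValueError):
        loops.classify_dynamics(-1, 2)


# ---------------------------------------------------------------------------
# integration helpers


def test_classify_pgx_loops_modes_and_dynamics():
    snp_meta = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [12_001]},  # 0-based 12_000 -> bin 2
        index=pd.Index(["rs1"], name="snp_id"),
    )
    genes = [_gene("g1", "chr1", 100_000, 110_000, "+")]
    pairs = pd.DataFrame({"snp_id": ["rs1"], "gene_id": ["g1"]})
    vehicle = _loops([_loop("chr1", 2, "chr1", 20)])
    drug = _loops([_loop("chr1", 2, "chr1", 20), _loop("chr1", 2, "chr1", 21)])
    out = loops.classify_pgx_loops(
        pairs, snp_meta, genes, {"vehicle": vehicle, "cortisol": drug}
    )
    row = out.iloc[0]
    assert row["mode"] == "direct"
    assert row["n_loops_vehicle"] == 1 and row["n_loops_cortisol"] == 2
    assert row["dynamics"] == "induced"  # 2/1 > 1.5


def test_classify_pgx_loops_none_forces_absent():
    snp_meta = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [12_001]},
        index=pd.Index(["rs1"], name="snp_id"),
    )
    genes = [_gene("g1", "chr1", 100_000, 110_000, "+")]
    pairs = pd.DataFrame({"snp_id": ["rs1"], "gene_id": ["g1"]})
    empty = _loops([])
    out = loops.classify_pgx_loops(
        pairs, snp_meta, genes, {"vehicle": empty, "cortisol": empty}
    )
    assert out.iloc[0]["mode"] == "none"
    assert out.iloc[0]["dynamics"] == "absent"


def test_connect_degs_to_peaks_counts():
    genes = [_gene("g1", "chr1", 100_000, 110_000, "+")]
    peaks = _peaks_covering_bins([2])
    vehicle = _loops([])
    drug = _loops([
        _loop("chr1", 2, "chr1", 20),
        _loop("chr1", 2, "chr1", 21),
    ])
    out = loops.connect_degs_to_peaks(
        genes, peaks, {"vehicle": vehicle, "cortisol": drug}
    )
    row = out.iloc[0]
    assert row["n_loops_vehicle"] == 0 and row["n_loops_cortisol"] == 2
    assert row["dynamics"] == "induced"  # 0 -> 2
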