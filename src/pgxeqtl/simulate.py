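"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a pharmacogenomic-eQTL study in
lymphoblastoid cell lines: a cohort of cell lines genotyped at common SNPs,
RNA-seq under four drug conditions (vehicle, agonist, selective modulator,
agonist+modulator), receptor ChIP-seq peak sets per condition, a 25-state
chromatin segmentation, allele-resolved reporter-assay counts, chromatin
loop lists at 5 kb bins, and LD / GWAS / baseline-eQTL catalog tables.

Ground-truth pharmacogenomic pairs carry a genotype-by-drug interaction
that exists only under the agonist, is nullified by co-treatment with the
antagonist, and is absent at baseline (so true pairs are NOT baseline
eQTLs). Decoy baseline eQTLs carry a genotype main effect in every
condition, which cancels in the drug/vehicle ratio. Fixing the seed fixes
every emitted table byte-for-byte.

The toy genome is 2 chromosomes x 10 Mb, small enough that brute-force
overlap oracles are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, GenotypeMatrix
from .expression import CONDITIONS, DrugExpressionSet

CHROM_LENGTHS = {"chr1": 10_000_000, "chr2": 10_000_000}
BIN_SIZE = 5_000

# 25-state metadata: id -> (label, category, looping_flag)
STATE_CATEGORIES = {
    **{i: (f"Prom{i}", "Promoter", False) for i in range(1, 4)},
    **{i: (f"Enh{i}", "Enhancer", False) for i in range(4, 8)},
    **{i: (f"EnhLoop{i}", "Enhancer", True) for i in range(8, 13)},
    **{i: (f"Tx{i}", "Transcribed", False) for i in range(13, 19)},
    **{i: (f"Repr{i}", "Repressive/Repetitive/Unknown", False) for i in range(19, 26)},
}


def state_metadata() -> pd.DataFrame:
    """State id / label / category / looping_flag table for the toy model."""
    return pd.DataFrame(
        [
            {"state_id": sid, "label": lab, "category": cat, "looping_flag": loop}
            for sid, (lab, cat, loop) in STATE_CATEGORIES.items()
        ]
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    The cohort size (30 cell lines), four drug conditions, the agonist-only
    interaction nullified by the antagonist, and the reporter/loop designs
    mirror the assay designs the pipeline consumes. Effect sizes default to
    values a small (n = 30) response-eQTL study could plausibly detect:
    a 2 log2-unit expression difference between homozygote classes and a
    0.25 allele-fraction shift at ~400x reporter depth.
    """

    seed: int = 0
    n_samples: int = 30
    n_snps: int = 2000
    n_genes: int = 500
    # genotypes
    maf_lo: float = 0.05
    maf_hi: float = 0.5
    true_maf_lo: float = 0.25  # true pairs need populated homozygote classes
    frac_hwe_violation: float = 0.02
    frac_low_call: float = 0.02
    # expression
    # Between-line biological variability is drawn once per (sample, gene)
    # and shared across conditions, so it cancels in the paired
    # drug/vehicle response — that cancellation is the point of the paired
    # design. nb_dispersion is the residual technical (library-level)
    # overdispersion that does NOT cancel.
    sample_gene_sd: float = 0.4
    nb_dispersion: float = 0.01
    baseline_mean_lo: float = 100.0
    baseline_mean_hi: float = 1000.0
    frac_deg: float = 0.3
    drug_effect_lo: float = 1.0  # |delta_g| range, log2 units
    drug_effect_hi: float = 3.0
    modulator_attenuation: float = 0.4  # partial agonism of the modulator
    antagonized_attenuation: float = 0.2  # agonist+antagonist residual
    interaction_beta: float = 2.0  # hom-hom log2-ratio difference, agonist only
    fraction_true_pgx: float = 0.1
    frac_decoy_baseline: float = 0.05
    noise_sd: float = 0.3  # residual sd of per-sample log2 drug/vehicle ratio
    # peaks
    peak_halfwidth: int = 150
    frac_decoy_in_peak: float = 0.15
    n_background_peaks: int = 200
    frac_c297_shared: float = 0.85
    frac_replicated_peaks: float = 0.70
    # chromatin states (placement of true PGx SNPs)
    frac_enhancer: float = 0.81
    frac_looping_enhancer: float = 0.41
    # reporter assay
    starr_depth: float = 400.0
    starr_allele_shift: float = 0.25
    frac_starr_allele_dependent: float = 0.5
    frac_starr_low_depth: float = 0.05
    frac_starr_indel: float = 0.02
    frac_starr_multiallelic: float = 0.02
    n_starr_replicates: int = 2
    starr_locus_mean: float = 10_000.0
    frac_starr_active_loci: float = 0.95
    starr_locus_effect: float = 2.0  # log2 locus-activity drug effect
    # Inactive library fragments. Kept well above the candidate count so
    # the non-responsive majority anchors median-of-ratios normalization
    # (the estimator needs the median locus to sit safely inside the
    # unchanged set, not at its tail).
    n_starr_background_loci: int = 1000
    # loops
    frac_loop_constitutive: float = 0.86
    frac_loop_induced: float = 0.06
    frac_loop_repressed: float = 0.08
    frac_common_contact: float = 0.2
    n_decoy_loops: int = 400
    frac_invalid_anchor: float = 0.1
    loop_count_lo: int = 3
    loop_count_hi: int = 20
    # catalogs
    frac_catalog_overlap: float = 0.25
    frac_hits_via_proxy: float = 0.3
    proxy_r2_lo: float = 0.8
    n_random_ld_pairs: int = 200

    def __post_init__(self) -> None:
        if self.n_samples < 6:
            raise ValueError("n_samples must be >= 6")
        for name in (
            "fraction_true_pgx", "frac_deg", "frac_decoy_baseline",
            "frac_loop_constitutive", "frac_loop_induced", "frac_loop_repressed",
            "frac_catalog_overlap",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery evaluation."""

    pairs: pd.DataFrame  # snp_id, gene_id, is_true_pgx, beta, is_decoy_baseline
    genes: pd.DataFrame  # gene_id, delta (agonist log2 effect; 0 = not a DEG)
    starr: pd.DataFrame  # variant snp_id, locus_id, is_allele_dependent, shift
    loops: pd.DataFrame  # snp_id, gene_id, dynamics, mode


@dataclass
class SimulatedStudy:
    """Everything one pipeline run consumes, plus the truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    genes: list[GeneModel]
    expression: DrugExpressionSet
    peaks: dict[str, pd.DataFrame]  # condition -> peak BED frame
    replicate_peaks: pd.DataFrame  # independent-antibody replicate of agonist set
    segmentation: pd.DataFrame  # chrom, start, end, state_id
    states: pd.DataFrame  # state metadata
    starr_counts: pd.DataFrame
    starr_locus_counts: pd.DataFrame
    loops: dict[str, pd.DataFrame]  # condition -> BEDPE frame
    h3k27ac_peaks: pd.DataFrame
    ld: pd.DataFrame
    gwas: pd.DataFrame
    baseline_pvals: pd.DataFrame
    truth: TruthTable


# ---------------------------------------------------------------------------
# layout


def _toy_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Deterministic gene grid plus randomly offset SNPs.

    Genes are laid on a regular grid (margin 300 kb from chromosome ends);
    each SNP is anchored to one gene with a random offset within +/-180 kb
    so the designated (SNP, gene) pair always survives the +/-200 kb cis
    window. Returns (genes, snp_meta, pair_truth).
    """
    chroms = list(CHROM_LENGTHS)
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    margin = 300_000
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = chroms[i // per_chrom]
        slot = i % per_chrom
        usable = CHROM_LENGTHS[chrom] - 2 * margin
        start = margin + int(slot * usable / per_chrom)
        length = int(rng.integers(8_000, 12_000))
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(f"gene{i:04d}", GenomicInterval(chrom, start, start + length), strand)
        )

    n_true = int(round(cfg.fraction_true_pgx * cfg.n_snps))
    snp_rows = []
    for j in range(cfg.n_snps):
        gene = genes[j % cfg.n_genes]
        # distal regulatory placement: >= 20 kb from the anchor gene start so
        # SNP bins never coincide with promoter-anchor bins
        offset = int(rng.integers(20_000, 180_001)) * int(rng.choice([-1, 1]))
        pos = gene.interval.start + offset
        pos = int(np.clip(pos, 1, CHROM_LENGTHS[gene.interval.chrom] - 1))
        ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        snp_rows.append((f"rs{j:05d}", gene.interval.chrom, pos + 1, ref, alt, gene.gene_id))
    snp_meta = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "anchor_gene"]
    ).set_index("snp_id")
    # avoid two SNPs at the identical coordinate
    snp_meta["pos"] += snp_meta.groupby(["chrom", "pos"]).cumcount()

    true_ids = rng.choice(snp_meta.index.to_numpy(), size=n_true, replace=False)
    is_true = snp_meta.index.isin(true_ids)
    remaining = snp_meta.index[~is_true]
    n_decoy = int(round(cfg.frac_decoy_baseline * cfg.n_snps))
    decoy_ids = rng.choice(remaining.to_numpy(), size=n_decoy, replace=False)
    pairs = pd.DataFrame(
        {
            "snp_id": snp_meta.index,
            "gene_id": snp_meta["anchor_gene"].to_numpy(),
            "is_true_pgx": is_true,
            "beta": np.where(is_true, cfg.interaction_beta, 0.0),
            "is_decoy_baseline": snp_meta.index.isin(decoy_ids),
        }
    ).reset_index(drop=True)
    return genes, snp_meta, pairs


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    snp_meta: pd.DataFrame,
    pair_truth: pd.DataFrame,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """HWE genotypes with configurable QC-violating SNP classes.

    Per SNP the MAF is drawn uniformly; true-pair SNPs draw from the upper
    MAF range so minor-homozygote classes are populated at n = 30. A
    configurable fraction of non-true SNPs violate HWE (complete
    heterozygote deficit, as under full inbreeding) or have a depressed
    call rate, to exercise the QC filters.

    Returns the observed matrix and the latent (unmasked) dosages used by
    the expression generator.
    """
    n, m = cfg.n_samples, cfg.n_snps
    true_set = set(pair_truth.loc[pair_truth["is_true_pgx"], "snp_id"])
    maf = rng.uniform(cfg.maf_lo, cfg.maf_hi, size=m)
    is_true = snp_meta.index.isin(true_set)
    maf[is_true] = rng.uniform(cfg.true_maf_lo, cfg.maf_hi, size=int(is_true.sum()))

    eligible = np.flatnonzero(~is_true)
    n_viol = int(round(cfg.frac_hwe_violation * m))
    n_lowcall = int(round(cfg.frac_low_call * m))
    chosen = rng.choice(eligible, size=n_viol + n_lowcall, replace=False)
    hwe_violators = np.zeros(m, dtype=bool)
    hwe_violators[chosen[:n_viol]] = True
    low_call = np.zeros(m, dtype=bool)
    low_call[chosen[n_viol:]] = True

    latent = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    # heterozygote deficit: both allele copies identical (inbreeding F = 1)
    viol = np.flatnonzero(hwe_violators)
    latent[:, viol] = 2.0 * rng.binomial(1, maf[None, viol], size=(n, len(viol)))

    observed = latent.copy()
    for j in np.flatnonzero(low_call):
        n_missing = max(3, int(np.ceil(0.1 * n)))  # call rate <= 0.9 < 0.95
        miss = rng.choice(n, size=n_missing, replace=False)
        observed[miss, j] = np.nan

    samples = pd.Index([f"LCL{i:02d}" for i in range(n)], name="sample_id")
    meta = snp_meta[["chrom", "pos", "ref_allele", "alt_allele"]].copy()
    meta["true_maf"] = maf
    meta["hwe_violator"] = hwe_violators
    meta["low_call"] = low_call
    gm = GenotypeMatrix(
        dosages=pd.DataFrame(observed, index=samples, columns=snp_meta.index),
        snps=meta,
    )
    return gm, latent


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    latent_dosages: np.ndarray,
    snp_meta: pd.DataFrame,
    pair_truth: pd.DataFrame,
    gene_ids: list[str],
) -> tuple[DrugExpressionSet, pd.DataFrame]:
    """Negative-binomial counts under the four drug conditions.

    log2 mean = log2(baseline_g) + delta_g * condition effect
                + (beta/2) * G * [agonist present and antagonist absent]
                + (beta_base/2) * G   (decoy baseline eQTLs, all conditions)
                + noise.
    The interaction term is zero at vehicle and under agonist+antagonist,
    so true pairs are invisible at baseline and lose their signal under
    antagonism. Counts are NB(mu, phi) with variance mu + phi * mu^2.
    """
    n, g = cfg.n_samples, len(gene_ids)
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    snp_index = {sid: j for j, sid in enumerate(snp_meta.index)}

    log_mu0 = rng.uniform(
        np.log2(cfg.baseline_mean_lo), np.log2(cfg.baseline_mean_hi), size=g
    )
    delta = np.zeros(g)
    deg_mask = rng.random(g) < cfg.frac_deg
    magnitudes = rng.uniform(cfg.drug_effect_lo, cfg.drug_effect_hi, size=g)
    signs = rng.choice([-1.0, 1.0], size=g)
    delta[deg_mask] = (magnitudes * signs)[deg_mask]

    cond_scale = {
        "vehicle": 0.0,
        "cortisol": 1.0,
        "c297": cfg.modulator_attenuation,
        "cortisol_c297": cfg.antagonized_attenuation,
    }

    # per-gene genotype terms (samples x genes)
    interaction = np.zeros((n, g))
    baseline_effect = np.zeros((n, g))
    for _, row in pair_truth.iterrows():
        gi = gene_index[row["gene_id"]]
        G = latent_dosages[:, snp_index[row["snp_id"]]]
        if row["is_true_pgx"]:
            interaction[:, gi] += (row["beta"] / 2.0) * G
        elif row["is_decoy_baseline"]:
            baseline_effect[:, gi] += (cfg.interaction_beta / 2.0) * G

    phi = cfg.nb_dispersion
    eps_sd = cfg.noise_sd / np.sqrt(2.0)  # ratio residual sd == noise_sd
    # shared biological (between-line) effect: cancels in the paired ratio
    line_effect = rng.normal(0.0, cfg.sample_gene_sd, size=(n, g))
    counts = {}
    samples = [f"LCL{i:02d}" for i in range(n)]
    for cond in CONDITIONS:
        log_mu = (
            log_mu0[None, :]
            + delta[None, :] * cond_scale[cond]
            + baseline_effect
            + line_effect
            + rng.normal(0.0, eps_sd, size=(n, g))
        )
        # genotype interaction: full under the agonist, attenuated under
        # the partial agonist alone, absent at vehicle and under
        # antagonist co-treatment (the receptor-mediated association is
        # lost when the agonist is blocked)
        if cond == "cortisol":
            log_mu = log_mu + interaction
        elif cond == "c297":
            log_mu = log_mu + cfg.modulator_attenuation * interaction
        mu = 2.0**log_mu
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts[cond] = pd.DataFrame(
            rng.poisson(lam).T, index=pd.Index(gene_ids, name="gene_id"),
            columns=samples,
        )
    gene_truth = pd.DataFrame({"gene_id": gene_ids, "delta": delta})
    return DrugExpressionSet(counts), gene_truth


# ---------------------------------------------------------------------------
# peaks, states


def simulate_peaks_states(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    snp_meta: pd.DataFrame,
    pair_truth: pd.DataFrame,
):
    """Receptor peak sets per condition, a replicate set, and a 25-state
    segmentation tiling the toy genome.

    Every true-pair SNP sits inside an agonist peak; a configurable decoy
    fraction of other SNPs do too, and the rest are guaranteed > 500 bp
    from any peak. The modulator peak set shares ``frac_c297_shared`` of
    agonist peaks; the replicate set retains ``frac_replicated_peaks`` of
    them with jittered scores.
    """
    true_set = set(pair_truth.loc[pair_truth["is_true_pgx"], "snp_id"])
    is_true = snp_meta.index.isin(true_set)
    decoy_pool = snp_meta.index[~is_true]
    n_decoy = int(round(cfg.frac_decoy_in_peak * len(decoy_pool)))
    decoy_in = set(rng.choice(decoy_pool.to_numpy(), size=n_decoy, replace=False))
    in_peak = is_true | snp_meta.index.isin(decoy_in)

    hw = cfg.peak_halfwidth
    rows = []
    for sid, row in snp_meta[in_peak].iterrows():
        center = int(row["pos"]) - 1
        rows.append(
            (row["chrom"], max(0, center - hw), center + hw,
             f"peak_{sid}", float(rng.uniform(5, 100)), float(rng.uniform(0, 0.009)))
        )
    # background peaks, kept > 700 bp away from any out-of-peak SNP
    out_positions = {
        chrom: np.sort(grp["pos"].to_numpy() - 1)
        for chrom, grp in snp_meta[~in_peak].groupby("chrom")
    }
    placed = 0
    while placed < cfg.n_background_peaks:
        chrom = list(CHROM_LENGTHS)[int(rng.integers(len(CHROM_LENGTHS)))]
        center = int(rng.integers(10_000, CHROM_LENGTHS[chrom] - 10_000))
        pos = out_positions.get(chrom, np.array([]))
        k = np.searchsorted(pos, center)
        near = [pos[i] for i in (k - 1, k) if 0 <= i < len(pos)]
        if any(abs(center - p) < hw + 701 for p in near):
            continue
        rows.append(
            (chrom, center - hw, center + hw, f"bg{placed:04d}",
             float(rng.uniform(5, 100)), float(rng.uniform(0, 0.009)))
        )
        placed += 1
    cortisol = (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "fdr"])
        .sort_values(["chrom", "start", "end"], kind="stable")
        .reset_index(drop=True)
    )

    shared = rng.random(len(cortisol)) < cfg.frac_c297_shared
    c297 = cortisol[shared].reset_index(drop=True)
    replicated = rng.random(len(cortisol)) < cfg.frac_replicated_peaks
    rep = cortisol[replicated].reset_index(drop=True).copy()
    rep["start"] = np.maximum(0, rep["start"] + rng.integers(-50, 51, size=len(rep)))
    rep["end"] = rep["start"] + 2 * hw
    rep["score"] = np.maximum(1.0, rep["score"] + rng.normal(0, 3.0, size=len(rep)))

    segmentation = _simulate_segmentation(cfg, rng, snp_meta, is_true)
    peaks = {"vehicle": cortisol.iloc[:0].copy(), "cortisol": cortisol, "c297": c297}
    return peaks, rep, segmentation, state_metadata()


def _simulate_segmentation(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    snp_meta: pd.DataFrame,
    is_true: np.ndarray,
) -> pd.DataFrame:
    """Tile the genome; SNP-containing segments get class-biased states."""
    looping = [s for s, (_, c, lf) in STATE_CATEGORIES.items() if lf]
    plain_enh = [s for s, (_, c, lf) in STATE_CATEGORIES.items() if c == "Enhancer" and not lf]
    promoter = [s for s, (_, c, _) in STATE_CATEGORIES.items() if c == "Promoter"]
    transcribed = [s for s, (_, c, _) in STATE_CATEGORIES.items() if c == "Transcribed"]
    repressive = [s for s, (_, c, _) in STATE_CATEGORIES.items() if c == "Repressive/Repetitive/Unknown"]

    def draw_state(for_true: bool) -> int:
        u = rng.random()
        if for_true:
            # enhancer fraction frac_enhancer, of which looping fraction
            if u < cfg.frac_looping_enhancer:
                pool = looping
            elif u < cfg.frac_enhancer:
                pool = plain_enh
            elif u < cfg.frac_enhancer + 0.07:
                pool = promoter
            elif u < cfg.frac_enhancer + 0.13:
                pool = transcribed
            else:
                pool = repressive
        else:
            if u < 0.10:
                pool = looping
            elif u < 0.25:
                pool = plain_enh
            elif u < 0.35:
                pool = promoter
            elif u < 0.60:
                pool = transcribed
            else:
                pool = repressive
        return int(pool[int(rng.integers(len(pool)))])

    truth_by_id = dict(zip(snp_meta.index, is_true))
    rows = []
    for chrom, grp in snp_meta.groupby("chrom"):
        grp = grp.sort_values("pos")
        starts0 = grp["pos"].to_numpy() - 1
        ids = grp.index.to_numpy()
        cursor = 0
        for p0, sid in zip(starts0, ids):
            lo, hi = max(cursor, p0 - 100), min(CHROM_LENGTHS[chrom], p0 + 100)
            if lo > cursor:
                rows.append((chrom, cursor, lo, draw_state(False) if rng.random() < 0.3 else int(rng.choice(repressive + transcribed))))
            if hi > lo:
                rows.append((chrom, lo, hi, draw_state(bool(truth_by_id[sid]))))
                cursor = hi
        if cursor < CHROM_LENGTHS[chrom]:
            rows.append((chrom, cursor, CHROM_LENGTHS[chrom], int(rng.choice(repressive + transcribed))))
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "state_id"])
    return seg[seg["end"] > seg["start"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# reporter assay


def simulate_starr(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    pair_truth: pd.DataFrame,
    n_extra_null: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Allele-resolved reporter counts plus locus-level expression counts.

    One locus per true pair; a fraction of loci are allele-dependent (the
    alt-allele read fraction moves from 0.5 at vehicle by ``shift`` under
    the agonist). Depth is Poisson per variant/condition/replicate, alt
    reads binomial. Low-depth, indel, and multi-allelic variants are
    included to exercise the filters. ``n_extra_null`` appends pure-null
    variants (for calibration studies).

    Returns (allele counts, locus counts, variant truth).
    """
    true_pairs = pair_truth[pair_truth["is_true_pgx"]]
    variants = [(f"locus_{r.gene_id}", r.snp_id) for r in true_pairs.itertuples()]
    variants += [(f"nulllocus{j:04d}", f"rsnull{j:05d}") for j in range(n_extra_null)]
    n_var = len(variants)

    n_true_var = len(true_pairs)
    dep = np.zeros(n_var, dtype=bool)
    dep[:n_true_var] = rng.random(n_true_var) < cfg.frac_starr_allele_dependent
    low_depth = rng.random(n_var) < cfg.frac_starr_low_depth
    is_indel = rng.random(n_var) < cfg.frac_starr_indel
    is_multi = rng.random(n_var) < cfg.frac_starr_multiallelic

    conds = ["vehicle", "cortisol", "c297"]
    rows = []
    for i, (locus, snp) in enumerate(variants):
        depth_mean = 10.0 if low_depth[i] else cfg.starr_depth
        for cond in conds:
            pi = 0.5
            if dep[i] and cond == "cortisol":
                pi = min(0.95, 0.5 + cfg.starr_allele_shift)
            for rep in range(1, cfg.n_starr_replicates + 1):
                depth = int(rng.poisson(depth_mean / cfg.n_starr_replicates))
                alt = int(rng.binomial(depth, pi)) if depth else 0
                rows.append(
                    (locus, snp, cond, rep, depth - alt, alt,
                     bool(is_indel[i]), bool(is_multi[i]))
                )
    counts = pd.DataFrame(
        rows,
        columns=["locus_id", "snp_id", "condition", "replicate",
                 "ref_count", "alt_count", "is_indel", "is_multiallelic"],
    )

    # Candidate loci (one per assayed variant) are mostly drug-responsive;
    # the library also carries background genomic fragments with no drug
    # response, as in a real reporter screen. The background anchors the
    # per-library CPM normalization so a shared induction of the candidate
    # set is not absorbed as a library-size change.
    cand_loci = sorted({locus for locus, _ in variants})
    bg_loci = [f"bglocus{j:04d}" for j in range(cfg.n_starr_background_loci)]
    active = np.concatenate(
        [
            rng.random(len(cand_loci)) < cfg.frac_starr_active_loci,
            np.zeros(len(bg_loci), dtype=bool),
        ]
    )
    loci = cand_loci + bg_loci
    locus_rows = []
    for i, locus in enumerate(loci):
        base = cfg.starr_locus_mean * float(rng.uniform(0.5, 2.0))
        for cond in conds:
            mu = base * (2.0**cfg.starr_locus_effect if (active[i] and cond != "vehicle") else 1.0)
            lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion,
                            size=cfg.n_starr_replicates)
            for rep, c in enumerate(rng.poisson(lam), start=1):
                locus_rows.append((locus, cond, rep, int(c)))
    locus_counts = pd.DataFrame(
        locus_rows, columns=["locus_id", "condition", "replicate", "count"]
    )
    truth = pd.DataFrame(
        {
            "snp_id": [s for _, s in variants],
            "locus_id": [l for l, _ in variants],
            "is_allele_dependent": dep,
            "shift": np.where(dep, cfg.starr_allele_shift, 0.0),
        }
    )
    return counts, locus_counts, truth


# ---------------------------------------------------------------------------
# loops


def _bin_of(pos0: int) -> int:
    return (pos0 // BIN_SIZE) * BIN_SIZE


def simulate_loops(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    snp_meta: pd.DataFrame,
    genes: list[GeneModel],
    pair_truth: pd.DataFrame,
):
    """Loop lists (vehicle, agonist) wiring true pairs to their genes.

    Each true pair is wired either directly (SNP bin <-> promoter-side gene
    bins) or through a common contact (two intermediate anchors). The
    dynamics class fixes per-condition loop numbers: constitutive pairs get
    2 loops in both conditions, induced pairs 0 -> 2, repressed pairs
    2 -> 0. Decoy loops include invalid-anchor, over-distance and high-FDR
    rows to exercise validation. H3K27ac peaks covering every valid anchor
    are emitted alongside.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    true_pairs = pair_truth[pair_truth["is_true_pgx"]].reset_index(drop=True)
    classes = np.array(["constitutive", "induced", "repressed"])
    probs = np.array([cfg.frac_loop_constitutive, cfg.frac_loop_induced, cfg.frac_loop_repressed])
    probs = probs / probs.sum()
    dynamics = rng.choice(classes, size=len(true_pairs), p=probs)
    common = rng.random(len(true_pairs)) < cfg.frac_common_contact

    rows = {"vehicle": [], "cortisol": []}
    valid_anchor_bins: set[tuple[str, int]] = set()
    truth_rows = []

    def add_loop(cond, chrom, b1, b2):
        if b1 > b2:
            b1, b2 = b2, b1
        count = int(rng.integers(cfg.loop_count_lo, cfg.loop_count_hi + 1))
        fdr = float(rng.uniform(0, 0.009))
        rows[cond].append((chrom, b1, b1 + BIN_SIZE, chrom, b2, b2 + BIN_SIZE, count, fdr))
        valid_anchor_bins.add((chrom, b1))

    for i, pr in true_pairs.iterrows():
        snp = snp_meta.loc[pr["snp_id"]]
        gene = gene_by_id[pr["gene_id"]]
        chrom = gene.interval.chrom
        snp_bin = _bin_of(int(snp["pos"]) - 1)
        # promoter-extended gene interval spans >= 2 bins (genes are 8-12 kb)
        gstart, gend = gene.interval.start, gene.interval.end
        if gene.strand == "+":
            gstart = max(0, gstart - 2000)
        else:
            gend = gend + 2000
        gene_bins = sorted({_bin_of(gstart), _bin_of(gend - 1)})
        if len(gene_bins) == 1:
            gene_bins.append(gene_bins[0] + BIN_SIZE)
        gene_bins = [b for b in gene_bins if b != snp_bin] or [gene_bins[0]]

        conds = {"constitutive": ("vehicle", "cortisol"),
                 "induced": ("cortisol",),
                 "repressed": ("vehicle",)}[dynamics[i]]
        if common[i]:
            lo, hi = sorted((snp_bin, gene_bins[0]))
            mids = []
            for off in (1, 2):
                mid = lo + ((hi - lo) // BIN_SIZE // 3 * off) * BIN_SIZE
                if mid in (snp_bin, *gene_bins) or mid in mids:
                    mid = hi + (off + 1) * BIN_SIZE
                mids.append(mid)
            for cond in conds:
                for mid in mids:
                    add_loop(cond, chrom, snp_bin, mid)
                    add_loop(cond, chrom, mid, gene_bins[0])
            mode = "common_contact"
        else:
            for cond in conds:
                for gb in gene_bins[:2] if len(gene_bins) >= 2 else gene_bins * 2:
                    add_loop(cond, chrom, snp_bin, gb)
            mode = "direct"
        truth_rows.append((pr["snp_id"], pr["gene_id"], dynamics[i], mode))

    # decoys: valid random loops + invalid-anchor + over-distance + high-FDR
    chroms = list(CHROM_LENGTHS)
    n_invalid = int(round(cfg.frac_invalid_anchor * cfg.n_decoy_loops))
    invalid_rows = {"vehicle": [], "cortisol": []}
    for j in range(cfg.n_decoy_loops):
        chrom = chroms[int(rng.integers(len(chroms)))]
        b1 = _bin_of(int(rng.integers(0, CHROM_LENGTHS[chrom] - 2_100_000)))
        if j % 17 == 0:  # over max distance
            b2 = b1 + _bin_of(int(rng.integers(2_005_000, 2_500_000)))
        else:
            b2 = b1 + BIN_SIZE * int(rng.integers(2, 300))
        cond = "vehicle" if j % 2 == 0 else "cortisol"
        count = int(rng.integers(cfg.loop_count_lo, cfg.loop_count_hi + 1))
        fdr = float(rng.uniform(0.02, 0.5)) if j % 13 == 0 else float(rng.uniform(0, 0.009))
        row = (chrom, b1, b1 + BIN_SIZE, chrom, b2, b2 + BIN_SIZE, count, fdr)
        if j < n_invalid:
            invalid_rows[cond].append(row)
        else:
            rows[cond].append(row)
            valid_anchor_bins.add((chrom, b1))

    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "count", "fdr"]
    loops = {}
    for cond in rows:
        df = pd.DataFrame(rows[cond] + invalid_rows[cond], columns=cols)
        df["trans"] = False
        loops[cond] = df.sort_values(cols[:6], kind="stable").reset_index(drop=True)

    peak_rows = [
        (chrom, b + 1000, b + 2000, f"k27ac_{chrom}_{b}", 50.0, 0.001)
        for chrom, b in sorted(valid_anchor_bins)
    ]
    h3k27ac = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "name", "score", "fdr"]
    )
    loop_truth = pd.DataFrame(
        truth_rows, columns=["snp_id", "gene_id", "dynamics", "mode"]
    )
    return loops, h3k27ac, loop_truth


# ---------------------------------------------------------------------------
# catalogs


def simulate_catalogs(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    snp_meta: pd.DataFrame,
    pair_truth: pd.DataFrame,
):
    """LD, GWAS/PheWAS, and baseline-eQTL p-value tables.

    A known ``frac_catalog_overlap`` of true-pair SNPs carry catalog hits,
    a fraction of them reachable only through an r2 > 0.8 proxy. Baseline
    p-values are uniform on [0.1, 1] for true pairs (baseline-silent by
    construction), near zero for decoy baseline eQTLs, uniform otherwise.
    """
    phenotypes = [
        "asthma", "osteoporosis", "mood_instability", "platelet_count",
        "breast_carcinoma", "multiple_sclerosis", "lupus", "vaccine_response",
    ]
    true_snps = pair_truth.loc[pair_truth["is_true_pgx"], "snp_id"].to_numpy()
    n_hits = int(round(cfg.frac_catalog_overlap * len(true_snps)))
    hit_snps = rng.choice(true_snps, size=n_hits, replace=False)
    via_proxy = rng.random(n_hits) < cfg.frac_hits_via_proxy

    ld_rows, gwas_rows = [], []
    for i, sid in enumerate(hit_snps):
        pheno = phenotypes[int(rng.integers(len(phenotypes)))]
        source = "gwas" if rng.random() < 0.7 else "phewas"
        if via_proxy[i]:
            proxy = f"proxy_{sid}"
            r2 = float(rng.uniform(cfg.proxy_r2_lo + 0.01, 1.0))
            ld_rows.append((sid, proxy, r2))
            gwas_rows.append((proxy, pheno, source, True))
        else:
            gwas_rows.append((sid, pheno, source, True))
    all_snps = snp_meta.index.to_numpy()
    for _ in range(cfg.n_random_ld_pairs):
        a, b = rng.choice(all_snps, size=2, replace=False)
        ld_rows.append((a, b, float(rng.uniform(0, 1))))

    ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"])
    gwas = pd.DataFrame(gwas_rows, columns=["snp_id", "phenotype", "source", "significant"])

    base_rows = []
    for pr in pair_truth.itertuples():
        if pr.is_true_pgx:
            p = float(rng.uniform(0.1, 1.0))
        elif pr.is_decoy_baseline:
            p = float(rng.uniform(0.0, 0.01))
        else:
            p = float(rng.uniform(0.0, 1.0))
        base_rows.append((pr.snp_id, pr.gene_id, p))
    baseline = pd.DataFrame(base_rows, columns=["snp_id", "gene_id", "p"])
    return ld, gwas, baseline


# ---------------------------------------------------------------------------
# orchestrator


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate the full synthetic study from one seed."""
    rng = np.random.default_rng(cfg.seed)
    genes, snp_meta, pair_truth = _toy_layout(cfg, rng)
    gm, latent = simulate_genotypes(cfg, rng, snp_meta, pair_truth)
    expr, gene_truth = simulate_expression(
        cfg, rng, latent, snp_meta, pair_truth, [g.gene_id for g in genes]
    )
    peaks, rep_peaks, segmentation, states = simulate_peaks_states(
        cfg, rng, snp_meta, pair_truth
    )
    starr_counts, locus_counts, starr_truth = simulate_starr(cfg, rng, pair_truth)
    loops, h3k27ac, loop_truth = simulate_loops(cfg, rng, snp_meta, genes, pair_truth)
    ld, gwas, baseline = simulate_catalogs(cfg, rng, snp_meta, pair_truth)
    truth = TruthTable(pairs=pair_truth, genes=gene_truth, starr=starr_truth, loops=loop_truth)
    return SimulatedStudy(
        config=cfg,
        genotypes=gm,
        genes=genes,
        expression=expr,
        peaks=peaks,
        replicate_peaks=rep_peaks,
        segmentation=segmentation,
        states=states,
        starr_counts=starr_counts,
        starr_locus_counts=locus_counts,
        loops=loops,
        h3k27ac_peaks=h3k27ac,
        ld=ld,
        gwas=gwas,
        baseline_pvals=baseline,
        truth=truth,
    )
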