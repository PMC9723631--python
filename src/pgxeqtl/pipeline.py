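"""End-to-end orchestration: simulate (or load) inputs, run every stage,
write TSV/JSON outputs, a truth-aware report, and a reproducibility
manifest.

Stage order: expression filtering and DEG calling; SNP QC, cis pairing,
peak restriction, response construction and the three condition scans;
unmasking classification with post-hoc contrasts; reporter-assay calls;
chromatin-state assignment and enrichment; loop validation, connectivity
and dynamics; LD-expanded catalog overlap. Reruns with the same config and
seed write byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import chromatin, clinical, eqtl, io, loops as loops_mod, starr
from .core import GenomicInterval
from .expression import DrugExpressionSet, differential_expression, filter_genes
from .simulate import SimulatedStudy, SimulationConfig, simulate_study

DEFAULT_THRESHOLDS = {
    "hwe_min_p": 0.001,
    "min_call": 0.95,
    "min_maf": 0.18,
    "cis_window": 200_000,
    "peak_pad": 500,
    "alpha_fdr": 0.05,
    "alpha_baseline": 0.05,
    "alpha_loss": 0.05,
    "min_count": 32,
    "min_samples": 0.5,
    "starr_min_total": 20,
    "starr_min_delta_pct": 10.0,
    "loop_fdr_max": 0.01,
    "loop_max_distance": 2_000_000,
    "loop_fold_min": 1.5,
    "gene_extension": 2000,
    "ld_r2_min": 0.8,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_inputs(study: SimulatedStudy, input_dir: str) -> dict[str, str]:
    """Write every simulated input in its external format; returns paths."""
    os.makedirs(input_dir, exist_ok=True)
    paths = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(input_dir, name)
        return paths[name]

    io.write_genotypes(study.genotypes, p("genotypes.tsv"))
    io.write_genes(study.genes, p("genes.bed"))
    for cond, df in study.expression.counts.items():
        out = df.reset_index()
        io.write_table(out, p(f"counts_{cond}.tsv"))
    for cond, df in study.peaks.items():
        io.write_bed(df, p(f"gr_peaks_{cond}.bed"))
    io.write_bed(study.replicate_peaks, p("gr_peaks_cortisol_replicate.bed"))
    io.write_bed(study.segmentation, p("segmentation.bed"))
    io.write_table(study.states, p("state_metadata.tsv"))
    io.write_table(study.starr_counts, p("starr_counts.tsv"))
    io.write_table(study.starr_locus_counts, p("starr_locus_counts.tsv"))
    for cond, df in study.loops.items():
        io.write_bedpe(df, p(f"loops_{cond}.bedpe"))
    io.write_bed(study.h3k27ac_peaks, p("h3k27ac_peaks.bed"))
    io.write_table(study.ld, p("ld.tsv"))
    io.write_table(study.gwas, p("gwas_catalog.tsv"))
    io.write_table(study.baseline_pvals, p("baseline_pvals.tsv"))
    io.write_table(study.truth.pairs, p("truth_pairs.tsv"))
    io.write_table(study.truth.genes, p("truth_genes.tsv"))
    io.write_table(study.truth.starr, p("truth_starr.tsv"))
    io.write_table(study.truth.loops, p("truth_loops.tsv"))
    return paths


def run_pipeline(
    config: dict, outdir: str, thresholds: dict | None = None
) -> dict:
    """Run every stage; returns the report dict (also written as JSON).

    ``config`` needs ``seed`` and optionally a ``simulate`` mapping of
    :class:`SimulationConfig` overrides. Outputs land under ``outdir``
    (inputs/ for the emitted input files, then one TSV per stage,
    report.json and manifest.json).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    os.makedirs(outdir, exist_ok=True)

    sim_overrides = dict(config.get("simulate") or {})
    sim_overrides.setdefault("seed", int(config.get("seed", 0)))
    try:
        cfg = SimulationConfig(**sim_overrides)
        study = simulate_study(cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc
    input_paths = write_inputs(study, os.path.join(outdir, "inputs"))

    # --- expression ---------------------------------------------------
    try:
        kept_genes = filter_genes(
            study.expression, min_count=thr["min_count"], min_samples=thr["min_samples"]
        )
        expr = study.expression.subset_genes(kept_genes)
        degs = differential_expression(expr, ("vehicle", "cortisol"), alpha=thr["alpha_fdr"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("expression", str(exc)) from exc
    io.write_table(degs, os.path.join(outdir, "degs_cortisol.tsv"))

    # --- eQTL scan ----------------------------------------------------
    try:
        gm = eqtl.filter_snps(
            study.genotypes, hwe_min_p=thr["hwe_min_p"],
            min_call=thr["min_call"], min_maf=thr["min_maf"],
        )
        genes_kept = [g for g in study.genes if g.gene_id in set(kept_genes)]
        pairs = eqtl.pair_cis(gm, genes_kept, window=thr["cis_window"])
        pairs_cort = eqtl.restrict_to_peaks(pairs, gm, study.peaks["cortisol"], pad=thr["peak_pad"])
        pairs_c297 = eqtl.restrict_to_peaks(pairs, gm, study.peaks["c297"], pad=thr["peak_pad"])
        pairs_combo = (
            pd.concat([pairs_cort, pairs_c297])
            .drop_duplicates(["snp_id", "gene_id"])
            .reset_index(drop=True)
        )
        scans = {}
        for name, pr, cond in (
            ("cortisol", pairs_cort, "cortisol"),
            ("c297", pairs_c297, "c297"),
            ("combo", pairs_combo, "cortisol_c297"),
        ):
            response = eqtl.build_response(expr, cond)
            scans[name] = eqtl.eqtl_scan(pr, response, gm)
        records = eqtl.classify_pgx(
            scans["cortisol"], scans["c297"], scans["combo"], study.baseline_pvals,
            alpha_fdr=thr["alpha_fdr"], alpha_baseline=thr["alpha_baseline"],
            alpha_loss=thr["alpha_loss"],
        )
        flagged = records[records["pgx_cortisol"] | records["pgx_c297"]]
        response_cort = eqtl.build_response(expr, "cortisol")
        tukey_rows = []
        for pr in flagged.itertuples():
            tk = eqtl.tukey_posthoc(pr.snp_id, pr.gene_id, response_cort, gm)
            tukey_rows.append({"snp_id": pr.snp_id, "gene_id": pr.gene_id, **tk})
        tukey = pd.DataFrame(
            tukey_rows, columns=["snp_id", "gene_id", "homref_het", "hom_hom", "het_homalt"]
        )
        records = records.merge(tukey, on=["snp_id", "gene_id"], how="left")
    except Exception as exc:  # noqa: BLE001
        raise StageError("pgx_eqtl", str(exc)) from exc
    io.write_table(records, os.path.join(outdir, "pgx_eqtl_records.tsv"))

    # --- reporter assay -----------------------------------------------
    try:
        starr_calls = {}
        for drug in ("cortisol", "c297"):
            contrast = ("vehicle", drug)
            filtered = starr.filter_variants(
                study.starr_counts, contrast, min_total=thr["starr_min_total"]
            )
            starr_calls[drug] = starr.allele_shift_test(
                filtered, contrast, alpha=thr["alpha_fdr"],
                min_delta_pct=thr["starr_min_delta_pct"],
            )
            io.write_table(
                starr_calls[drug], os.path.join(outdir, f"starr_calls_{drug}.tsv")
            )
        locus_activity = starr.locus_activity_test(
            study.starr_locus_counts, ("vehicle", "cortisol"), alpha=thr["alpha_fdr"]
        )
        concordance = starr.replicate_concordance(study.starr_locus_counts)
    except Exception as exc:  # noqa: BLE001
        raise StageError("starr", str(exc)) from exc
    io.write_table(locus_activity, os.path.join(outdir, "starr_locus_activity.tsv"))
    io.write_table(concordance, os.path.join(outdir, "starr_replicate_concordance.tsv"))

    # --- chromatin states ----------------------------------------------
    try:
        chromatin.validate_segmentation(study.segmentation, study.states)
        pgx_cort = records[records["pgx_cortisol"]]
        pgx_snp_ids = sorted(pgx_cort["snp_id"].unique())
        snp_meta = study.genotypes.snps
        assigned = chromatin.assign_states(
            snp_meta.loc[pgx_snp_ids], study.segmentation
        ) if pgx_snp_ids else pd.Series(dtype=float)
        if len(assigned):
            enrichment = chromatin.state_enrichment(
                assigned, study.segmentation, study.states, universe="genome-bp"
            )
            fractions = chromatin.category_fractions(assigned, study.states)
        else:
            enrichment = pd.DataFrame(columns=["state_id", "n_snps", "fold", "p", "q"])
            fractions = pd.Series(dtype=float)
        repro_frac, repro_r = chromatin.peak_reproducibility(
            study.peaks["cortisol"], study.replicate_peaks
        )
        overlap_mat = chromatin.overlap_fraction_conditions(
            {"cortisol": study.peaks["cortisol"], "c297": study.peaks["c297"]}
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("chromatin", str(exc)) from exc
    io.write_table(enrichment, os.path.join(outdir, "state_enrichment.tsv"))
    fractions.rename("fraction").to_frame().reset_index(names="category").to_csv(
        os.path.join(outdir, "category_fractions.tsv"), sep="\t", index=False
    )

    # --- loops ---------------------------------------------------------
    try:
        valid_loops = {
            cond: loops_mod.validate_loops(
                df, study.h3k27ac_peaks,
                max_distance=thr["loop_max_distance"], fdr_max=thr["loop_fdr_max"],
            )
            for cond, df in study.loops.items()
        }
        loop_records = loops_mod.classify_pgx_loops(
            study.truth.pairs[study.truth.pairs["is_true_pgx"]],
            snp_meta, study.genes, valid_loops,
            extension=thr["gene_extension"],
        )
        deg_genes = [
            g for g in genes_kept
            if g.gene_id in set(degs.loc[degs["is_deg"], "gene_id"])
        ]
        deg_connections = loops_mod.connect_degs_to_peaks(
            deg_genes, study.peaks["cortisol"], valid_loops,
            extension=thr["gene_extension"],
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("loops", str(exc)) from exc
    io.write_table(loop_records, os.path.join(outdir, "pgx_loop_dynamics.tsv"))
    io.write_table(deg_connections, os.path.join(outdir, "deg_loop_connections.tsv"))

    # --- clinical overlap ----------------------------------------------
    try:
        pgx_snps_all = sorted(
            records.loc[records["pgx_cortisol"] | records["pgx_c297"], "snp_id"].unique()
        )
        proxies = clinical.ld_expand(pgx_snps_all, study.ld, r2_min=thr["ld_r2_min"])
        hits, overlap_summary = clinical.catalog_overlap(pgx_snps_all, proxies, study.gwas)
    except Exception as exc:  # noqa: BLE001
        raise StageError("clinical", str(exc)) from exc
    io.write_table(hits, os.path.join(outdir, "catalog_hits.tsv"))

    report = make_report(
        study=study,
        kept_genes=kept_genes,
        degs=degs,
        gm=gm,
        pairs=pairs,
        pairs_cort=pairs_cort,
        pairs_c297=pairs_c297,
        records=records,
        starr_calls=starr_calls,
        locus_activity=locus_activity,
        fractions=fractions,
        repro=(repro_frac, repro_r),
        overlap_mat=overlap_mat,
        loop_records=loop_records,
        deg_connections=deg_connections,
        overlap_summary=overlap_summary,
    )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "seed": int(config.get("seed", 0)),
        "simulation_config": dataclasses.asdict(study.config),
        "thresholds": thr,
        "input_digests": {name: _sha256(path) for name, path in sorted(input_paths.items())},
        "row_counts": {
            "snps_post_qc": int(gm.n_snps),
            "cis_pairs": int(len(pairs)),
            "tested_pairs_cortisol": int(len(pairs_cort)),
            "tested_pairs_c297": int(len(pairs_c297)),
            "pgx_records": int(len(records)),
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def make_report(
    *, study, kept_genes, degs, gm, pairs, pairs_cort, pairs_c297, records,
    starr_calls, locus_activity, fractions, repro, overlap_mat, loop_records,
    deg_connections, overlap_summary,
) -> dict:
    """Machine-readable run summary; truth-aware recovery metrics included
    because the study carries its ground truth."""
    truth_pairs = study.truth.pairs
    merged = records.merge(
        truth_pairs[["snp_id", "gene_id", "is_true_pgx"]],
        on=["snp_id", "gene_id"], how="left",
    )
    merged["is_true_pgx"] = merged["is_true_pgx"].eq(True)
    tested = merged[merged["tested_cortisol"].eq(True)]
    tested_true = tested[tested["is_true_pgx"]]
    flagged = tested[tested["pgx_cortisol"]]
    n_flag_true = int((flagged["is_true_pgx"]).sum())
    sensitivity = n_flag_true / len(tested_true) if len(tested_true) else float("nan")
    fdr = (
        (len(flagged) - n_flag_true) / len(flagged) if len(flagged) else 0.0
    )
    flagged_true = flagged[flagged["is_true_pgx"]]
    lost_rate = (
        float(flagged_true["antagonist_lost"].mean()) if len(flagged_true) else float("nan")
    )

    starr_truth = study.truth.starr.set_index("snp_id")["is_allele_dependent"]
    calls_c = starr_calls["cortisol"].copy()
    calls_c["truth"] = calls_c["snp_id"].map(starr_truth).eq(True)
    starr_sens = (
        float(calls_c.loc[calls_c["truth"], "call"].mean())
        if calls_c["truth"].any() else float("nan")
    )
    n_calls = int(calls_c["call"].sum())
    starr_fdr = (
        float((calls_c["call"] & ~calls_c["truth"]).sum() / n_calls) if n_calls else 0.0
    )

    loop_truth = study.truth.loops.set_index(["snp_id", "gene_id"])["dynamics"]
    lr = loop_records.set_index(["snp_id", "gene_id"])
    confusion: dict[str, dict[str, int]] = {}
    for key, true_dyn in loop_truth.items():
        pred = lr.loc[key, "dynamics"] if key in lr.index else "absent"
        confusion.setdefault(true_dyn, {}).setdefault(pred, 0)
        confusion[true_dyn][pred] += 1

    return {
        "n_samples": int(study.config.n_samples),
        "genes_total": int(study.config.n_genes),
        "genes_kept": len(kept_genes),
        "degs_cortisol": int(degs["is_deg"].sum()),
        "snps_total": int(study.config.n_snps),
        "snps_post_qc": int(gm.n_snps),
        "cis_pairs": int(len(pairs)),
        "tested_pairs_cortisol": int(len(pairs_cort)),
        "tested_pairs_c297": int(len(pairs_c297)),
        "pgx_pairs_cortisol": int(records["pgx_cortisol"].sum()),
        "pgx_pairs_c297": int(records["pgx_c297"].sum()),
        "pgx_sensitivity": sensitivity,
        "pgx_empirical_fdr": fdr,
        "antagonist_lost_rate": lost_rate,
        "starr_calls_cortisol": n_calls,
        "starr_sensitivity": starr_sens,
        "starr_empirical_fdr": starr_fdr,
        "starr_active_loci": int(locus_activity["active"].sum()),
        "starr_loci_total": int(len(locus_activity)),
        "category_fractions": {k: float(v) for k, v in fractions.items()},
        "peak_reproducibility_fraction": None if np.isnan(repro[0]) else float(repro[0]),
        "peak_reproducibility_score_r": None if np.isnan(repro[1]) else float(repro[1]),
        "peak_overlap_c297_in_cortisol": float(overlap_mat.loc["c297", "cortisol"]),
        "loop_dynamics_counts": loop_records["dynamics"].value_counts().to_dict(),
        "loop_dynamics_confusion": confusion,
        "deg_loop_connected": int((deg_connections["mode"] != "none").sum()),
        "deg_loop_changed": int(
            deg_connections["dynamics"].isin(["induced", "repressed"]).sum()
        ),
        "catalog_overlap_fraction": float(overlap_summary["fraction_with_hit"]),
    }
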