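"""End-to-end pipeline: reference prep -> deconvolution -> tumor counts ->
spatial modules -> consensus -> benchmark, with a manifest of every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmark as bm
from . import consensus as cons
from . import deconvolution as dc
from . import reference as rp
from . import simulate as sim
from . import spatial as sp
from .io import (
    PipelineConfig,
    load_spot_dataset,
    read_counts_mtx,
    read_tf_list,
    write_counts_mtx,
)

log = logging.getLogger("spotmodules")

__all__ = ["run_pipeline"]


def _safe_log_norm(counts: np.ndarray) -> np.ndarray:
    totals = np.maximum(counts.sum(axis=1, keepdims=True), 1)
    return np.log2(counts / totals * 1e4 + 1.0)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    outdir,
    sim_config: sim.SimConfig | None = None,
):
    """Run every stage and write tables plus a manifest under ``outdir``.

    Inputs come from the paths in ``config`` when set; otherwise a
    synthetic dataset is generated from ``sim_config`` (default study
    conditions) with the config's master seed. Returns the manifest dict.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.master_seed)
    manifest = {"config": dataclasses.asdict(config), "config_hash": _config_hash(config),
                "master_seed": seed, "stages": []}

    def stage(name, **counts):
        log.info("stage %s: %s", name, counts)
        manifest["stages"].append({"name": name, "status": "complete", **counts})

    try:
        # ---- stage 1: inputs -------------------------------------------------
        if config.spatial_dir is not None:
            spots = load_spot_dataset(config.spatial_dir, config.positions_csv,
                                      config.samples_tsv)
            ref_counts, ref_genes, ref_barcodes = read_counts_mtx(config.reference_dir)
            labels = pd.read_csv(config.labels_tsv, sep="\t").set_index("barcode")
            labels = labels.loc[ref_barcodes]
            fine = labels["fine_label"].to_numpy()
            coarse = labels["coarse_label"].to_numpy()
            coarse_of = dict(zip(fine, coarse))
            tumor_states = sorted({f for f, c in coarse_of.items() if c == "tumor"})
            tf_list = read_tf_list(config.tf_list)
        else:
            scfg = sim_config if sim_config is not None else sim.default_config()
            ref_counts, fine, coarse = sim.simulate_reference(scfg, seed)
            ref_genes = sim.gene_ids(scfg)
            profiles = sim.expected_profiles(scfg, seed)
            spots, truth = sim.simulate_tissue(scfg, profiles, seed)
            tf_list = (read_tf_list(config.tf_list) if config.tf_list
                       else sim.tf_gene_ids(scfg))
            coarse_of = scfg.coarse_labels
            tumor_states = [scfg.state_names[k] for k in scfg.tumor_state_ids]
        stage("inputs", n_ref_cells=len(fine), n_ref_genes=len(ref_genes),
              n_spots=spots.n_spots, n_spot_genes=spots.n_genes, n_tf=len(tf_list))

        # ---- stage 2: reference prep ----------------------------------------
        cells0 = ref_counts.shape[0]
        ref_counts, cell_mask = rp.filter_reference_cells(
            ref_counts, None, config.min_genes, config.min_umis, config.max_mito)
        fine, coarse = fine[cell_mask], coarse[cell_mask]
        genes0 = len(ref_genes)
        ref_counts, ref_genes, _ = rp.filter_reference_genes(
            ref_counts, ref_genes, config.gene_min_cells, None)
        norm = rp.normalize_log2_cp10k(ref_counts)
        marker_stats, markers = rp.select_markers(
            norm, ref_genes, fine, coarse_of,
            p_max=config.marker_p_max, lfc_min=config.lfc_min)
        ref = rp.build_reference(ref_counts, ref_genes, fine, coarse_of, markers,
                                 pseudo_min=config.pseudo_min)
        marker_stats.to_csv(outdir / "marker_stats.tsv", sep="\t")
        pd.DataFrame(ref.profile, index=ref.fine_labels, columns=ref.gene_ids).to_csv(
            outdir / "reference_profile.tsv", sep="\t")
        stage("prep-ref", cells_before=cells0, cells_after=int(cell_mask.sum()),
              genes_before=genes0, genes_after=len(ref_genes),
              n_marker_universe=len(ref.gene_ids))

        # ---- stage 3: deconvolution -----------------------------------------
        spots_f = dc.filter_spots_and_genes(
            spots, config.min_spot_genes, config.min_spot_umis,
            config.gene_min_spots_exclusive)
        spot_mask = np.isin(np.asarray(spots.barcodes), np.asarray(spots_f.barcodes))
        result = dc.deconvolve(spots_f, ref, config.em_max_iter, config.em_tol)
        tum = dc.tumor_counts(result, tumor_states)
        theta_df = pd.DataFrame(result.theta, index=spots_f.barcodes,
                                columns=result.state_names)
        theta_df.to_csv(outdir / "theta.tsv", sep="\t")
        write_counts_mtx(outdir / "tumor_counts", tum, result.gene_ids, spots_f.barcodes)
        frac = dc.celltype_fraction_map(result, tumor_states)
        pd.DataFrame({"tumor_fraction": frac}, index=spots_f.barcodes).to_csv(
            outdir / "tumor_fraction.tsv", sep="\t")
        stage("deconvolve", spots_before=spots.n_spots, spots_after=spots_f.n_spots,
              genes_after=len(result.gene_ids), em_iterations=result.n_iter)

        # ---- stage 4: spatial modules on deconvolved tumor counts -----------
        graph = sp.build_knn_graph(spots_f.coords(), spots_f.tissue_ids, config.k)
        expressed = tum.sum(axis=0) > 0
        genes_expr = [g for g, m in zip(result.gene_ids, expressed) if m]
        X = sp.standardized_residuals(tum[:, expressed])
        acorr = sp.autocorrelation(X, graph, config.n_perm, seed + 11,
                                   gene_ids=genes_expr)
        selection = sp.select_module_genes(acorr, tf_list, config.fdr_autocorr,
                                           config.top_n)
        col = {g: i for i, g in enumerate(genes_expr)}
        lc = sp.local_correlation(X, graph, [col[g] for g in selection],
                                  config.n_perm, seed + 12, gene_ids=genes_expr)
        modules = sp.detect_modules(lc, config.min_gene_threshold,
                                    config.module_fdr, config.core_only)
        scores = sp.module_scores(_safe_log_norm(tum[:, expressed]), genes_expr,
                                  modules, graph)
        scores.index = spots_f.barcodes
        acorr.to_csv(outdir / "autocorrelation.tsv", sep="\t")
        lc.z_frame().to_csv(outdir / "local_correlation_z.tsv", sep="\t")
        modules.assignments.to_csv(outdir / "modules.tsv", sep="\t")
        scores.to_csv(outdir / "module_scores.tsv", sep="\t")
        stage("modules", genes_tested=len(genes_expr), genes_selected=len(selection),
              n_modules=modules.n_modules)

        # ---- stage 5: consensus ---------------------------------------------
        consensus = cons.run_consensus(
            tum[:, expressed], spots_f.tissue_ids, graph, genes_expr, selection,
            modules, n_reps=config.n_reps, fraction=config.subsample_fraction,
            threshold=config.consensus_threshold, n_perm=config.n_perm,
            master_seed=seed + 1000, min_gene_threshold=config.min_gene_threshold,
            fdr_threshold=config.module_fdr, core_only=config.core_only)
        cons_df = pd.DataFrame({
            "module": modules.assignments.reindex(consensus.gene_consensus.index),
            "consensus": consensus.gene_consensus,
            "selected": consensus.gene_consensus.index.isin(consensus.selected_genes),
        })
        cons_df.to_csv(outdir / "consensus.tsv", sep="\t")
        if consensus.replicate_assignments is not None:
            consensus.replicate_assignments.to_csv(
                outdir / "consensus_replicates.tsv", sep="\t")
        summary = consensus.per_module_summary(modules)
        summary.to_json(outdir / "consensus_summary.json", orient="records")
        stage("consensus", n_reps=config.n_reps,
              n_selected=len(consensus.selected_genes),
              n_scored=len(consensus.gene_consensus))

        # ---- stage 6: benchmark deconvolved vs raw --------------------------
        marker_sets = bm.benchmark_marker_sets(marker_stats, config.benchmark_top_n)
        raw = spots_f.subset_genes(result.gene_ids).counts
        raw_expr = raw.sum(axis=0) > 0
        both = expressed & raw_expr
        genes_both = [g for g, m in zip(result.gene_ids, both) if m]
        Xd = sp.standardized_residuals(np.asarray(tum)[:, both])
        Xr = sp.standardized_residuals(np.asarray(raw)[:, both])
        acorr_d = sp.autocorrelation(Xd, graph, config.n_perm, seed + 21,
                                     gene_ids=genes_both)
        acorr_r = sp.autocorrelation(Xr, graph, config.n_perm, seed + 21,
                                     gene_ids=genes_both)
        tumor_set = [g for g in marker_sets.get("tumor", []) if g in genes_both]
        nontumor_set = sorted({
            g for c, gs in marker_sets.items() if c != "tumor" for g in gs
            if g in genes_both})
        tests = {}
        for name, gene_set, direction in [
            ("tumor", tumor_set, "greater"),
            ("nontumor", nontumor_set, "less"),
        ]:
            tests[name] = bm.paired_autocorr_test(
                acorr_d.loc[gene_set, "Z"], acorr_r.loc[gene_set, "Z"], direction)
        bench_genes = sorted(set(tumor_set) | set(nontumor_set))
        bidx = [genes_both.index(g) for g in bench_genes]
        lc_d = sp.local_correlation(Xd, graph, bidx, config.n_perm, seed + 22,
                                    gene_ids=genes_both)
        lc_r = sp.local_correlation(Xr, graph, bidx, config.n_perm, seed + 22,
                                    gene_ids=genes_both)
        cat = bm.paircorr_category_test(lc_d.z_frame(), lc_r.z_frame(),
                                        tumor_set, nontumor_set)
        cat.to_csv(outdir / "benchmark_categories.tsv", sep="\t")
        report = {"autocorr_tests": tests,
                  "category_tests": cat.reset_index().to_dict(orient="records")}
        (outdir / "benchmark.json").write_text(json.dumps(report, indent=2, default=float))
        stage("benchmark", n_tumor_markers=len(tumor_set),
              n_nontumor_markers=len(nontumor_set))
    except Exception as exc:
        manifest["stages"].append({"name": "error", "status": "failed",
                                   "error": f"{type(exc).__name__}: {exc}"})
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
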