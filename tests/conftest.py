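"""Shared fixtures: the default synthetic scenario and a 20-seed sweep.

Everything here is generated at test time from the package's own
synthetic-data module; heavy artifacts are session-scoped so the suite
computes them once.
"""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from spotmodules import (
    benchmark as bm,
    consensus as cons,
    deconvolution as dc,
    reference as rp,
    simulate as sim,
    spatial as sp,
)

# synthetic-scale analysis thresholds (tissues have ~400 genes, ~2000 UMIs/spot)
SPOT_MIN_GENES = 100
SPOT_MIN_UMIS = 500
N_PERM = 200


def run_scenario(seed: int, n_perm: int = N_PERM, with_benchmark: bool = False,
                 with_consensus: bool = False, n_reps: int = 20):
    """One full run of the pipeline on a single default synthetic tissue."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = sim.default_config(n_samples=1, n_slides=1)
        ref_counts, fine, coarse = sim.simulate_reference(cfg, seed)
        gids = sim.gene_ids(cfg)
        norm = rp.normalize_log2_cp10k(ref_counts)
        stats_df, markers = rp.select_markers(norm, gids, fine, cfg.coarse_labels)
        ref = rp.build_reference(ref_counts, gids, fine, cfg.coarse_labels, markers)
        spots, truth = sim.simulate_tissue(cfg, sim.expected_profiles(cfg, seed), seed)
        spots_f = dc.filter_spots_and_genes(spots, SPOT_MIN_GENES, SPOT_MIN_UMIS)
        result = dc.deconvolve(spots_f, ref)
        tumor_states = [cfg.state_names[k] for k in cfg.tumor_state_ids]
        tum = dc.tumor_counts(result, tumor_states)
        graph = sp.build_knn_graph(spots_f.coords(), spots_f.tissue_ids, 6)
        expressed = tum.sum(axis=0) > 0
        genes = [g for g, m in zip(result.gene_ids, expressed) if m]
        X = sp.standardized_residuals(tum[:, expressed])
        acorr = sp.autocorrelation(X, graph, n_perm, seed + 11, gene_ids=genes)
        selection = sp.select_module_genes(acorr, sim.tf_gene_ids(cfg), 0.01, 500)
        col = {g: i for i, g in enumerate(genes)}
        lc = sp.local_correlation(X, graph, [col[g] for g in selection],
                                  n_perm, seed + 12, gene_ids=genes)
        modules = sp.detect_modules(lc)
        ns = SimpleNamespace(
            cfg=cfg, seed=seed, ref=ref, stats_df=stats_df, markers=markers,
            spots=spots, spots_f=spots_f, truth=truth, result=result, tum=tum,
            tumor_states=tumor_states, graph=graph, expressed=expressed,
            genes=genes, X=X, acorr=acorr, selection=selection, lc=lc,
            modules=modules,
        )
        if with_benchmark:
            raw = spots_f.subset_genes(result.gene_ids).counts
            both = expressed & (raw.sum(axis=0) > 0)
            genes_b = [g for g, m in zip(result.gene_ids, both) if m]
            Xd = sp.standardized_residuals(tum[:, both])
            Xr = sp.standardized_residuals(np.asarray(raw)[:, both])
            acd = sp.autocorrelation(Xd, graph, n_perm, seed + 21, gene_ids=genes_b)
            acr = sp.autocorrelation(Xr, graph, n_perm, seed + 21, gene_ids=genes_b)
            msets = bm.benchmark_marker_sets(stats_df, 100)
            tset = [g for g in msets.get("tumor", []) if g in genes_b]
            nset = sorted({g for c, gs in msets.items() if c != "tumor"
                           for g in gs if g in genes_b})
            bench = sorted(set(tset) | set(nset))
            bidx = [genes_b.index(g) for g in bench]
            lcd = sp.local_correlation(Xd, graph, bidx, n_perm, seed + 22, gene_ids=genes_b)
            lcr = sp.local_correlation(Xr, graph, bidx, n_perm, seed + 22, gene_ids=genes_b)
            ns.bench = SimpleNamespace(acorr_deconv=acd, acorr_raw=acr,
                                       tumor_set=tset, nontumor_set=nset,
                                       lc_deconv=lcd, lc_raw=lcr)
        if with_consensus:
            ns.consensus = cons.run_consensus(
                tum[:, expressed], spots_f.tissue_ids, graph, genes, selection,
                modules, n_reps=n_reps, n_perm=n_perm, master_seed=seed + 1000)
        return ns


@pytest.fixture(scope="session")
def scenario():
    """The default single-tissue scenario at seed 1."""
    return run_scenario(1)


@pytest.fixture(scope="session")
def sweep():
    """Twenty independent scenario seeds with benchmark and consensus runs."""
    return [run_scenario(seed, with_benchmark=True, with_consensus=True)
            for seed in range(1, 21)]


def make_dataset(counts):
    """Minimal single-tissue SpotDataset around a raw count matrix."""
    import pandas as pd

    from spotmodules.containers import SpotDataset

    counts = np.asarray(counts)
    S = counts.shape[0]
    barcodes = [f"bc{i}" for i in range(S)]
    pos = pd.DataFrame(
        {"in_tissue": 1, "array_row": np.arange(S), "array_col": 0,
         "pxl_row_in_fullres": 0, "pxl_col_in_fullres": 0},
        index=pd.Index(barcodes, name="barcode"))
    return SpotDataset(counts, [f"g{j}" for j in range(counts.shape[1])],
                       barcodes, pos, np.array(["m"] * S), np.array(["s"] * S))


def planted_tumor_genes(truth) -> list:
    out: set = set()
    for comp, genes in truth.planted_modules:
        if comp == "tumor":
            out |= set(genes)
    return sorted(out)


def planted_labels(truth, genes) -> list:
    tumor_sets = [set(g) for c, g in truth.planted_modules if c == "tumor"]
    return [next(i for i, s in enumerate(tumor_sets) if g in s) for g in genes]
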