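"""Module robustness by multinomial read subsampling (consensus scores).

A fixed fraction of each tissue's reads is redrawn multinomially (with
probabilities proportional to the observed spot x gene counts), the
local-correlation -> module-detection stage is re-run on each subsample
over the full-data gene selection, and every gene pair that shared a
module in the full-data run is scored by how often it still shares one
across replicates. Genes whose average co-occurrence with their full-data
module partners reaches the threshold are the module's representative
("high-consensus") genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial import (
    ModuleResult,
    NeighborGraph,
    detect_modules,
    local_correlation,
    standardized_residuals,
)

__all__ = ["ConsensusResult", "subsample_counts", "consensus_scores", "run_consensus"]


@dataclass
class ConsensusResult:
    pair_cooccurrence: pd.Series  # (gene, gene) -> frequency in [0, 1]
    gene_consensus: pd.Series  # gene -> mean frequency over module partners
    selected_genes: list
    threshold: float
    replicate_assignments: pd.DataFrame | None = None  # genes x replicates

    def per_module_summary(self, full_modules: ModuleResult) -> pd.DataFrame:
        rows = []
        for mid, genes in sorted(full_modules.module_genes().items()):
            sel = [g for g in genes if g in self.selected_genes]
            rows.append((mid, len(sel), len(genes)))
        return pd.DataFrame(rows, columns=["module", "n_selected", "n_total"])


def subsample_counts(
    counts: np.ndarray,
    tissue_ids,
    fraction: float = 0.6,
    seed: int | None = None,
) -> np.ndarray:
    """Redraw floor(fraction * total) reads per tissue, multinomially.

    Probabilities are proportional to the tissue's observed (spot, gene)
    counts, so zero cells stay zero and per-tissue totals are exact.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    counts = np.asarray(counts)
    tissue_ids = np.asarray(tissue_ids)
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for t in pd.unique(tissue_ids):
        idx = np.flatnonzero(tissue_ids == t)
        block = counts[idx]
        total = int(block.sum())
        if total == 0:
            raise ValueError(f"tissue {t!r} has zero total counts")
        n = int(np.floor(fraction * total))
        draw = rng.multinomial(n, block.ravel() / total)
        out[idx] = draw.reshape(block.shape)
    return out


def consensus_scores(
    full_modules: ModuleResult,
    replicate_modules: list,
    threshold: float = 0.8,
) -> ConsensusResult:
    """Co-occurrence frequencies of full-data module pairs across replicates.

    A replicate where either gene is unassigned (-1) counts as not
    co-occurring. Genes unassigned in the full-data run get no score.
    """
    if not replicate_modules:
        raise ValueError("need at least one replicate module result")
    full = full_modules.assignments
    module_of = {g: m for g, m in full.items() if m != -1}
    pairs = [
        (g, h)
        for g, h in itertools.combinations(sorted(module_of), 2)
        if module_of[g] == module_of[h]
    ]
    n_rep = len(replicate_modules)
    freq = {}
    rep_assign = [r.assignments for r in replicate_modules]
    for g, h in pairs:
        n_co = sum(
            1
            for a in rep_assign
            if a.get(g, -1) != -1 and a.get(g, -1) == a.get(h, -1)
        )
        freq[(g, h)] = n_co / n_rep
    pair_freq = pd.Series(freq, dtype=float)
    gene_cons = {}
    for g in sorted(module_of):
        partner_freqs = [
            f for (a, b), f in freq.items() if g in (a, b)
        ]
        if partner_freqs:
            gene_cons[g] = float(np.mean(partner_freqs))
    gene_consensus = pd.Series(gene_cons, dtype=float).sort_index()
    selected = sorted(g for g, c in gene_consensus.items() if c >= threshold)
    return ConsensusResult(
        pair_cooccurrence=pair_freq,
        gene_consensus=gene_consensus,
        selected_genes=selected,
        threshold=threshold,
    )


def run_consensus(
    counts: np.ndarray,
    tissue_ids,
    graph: NeighborGraph,
    gene_ids: list,
    module_gene_ids: list,
    full_modules: ModuleResult,
    n_reps: int = 100,
    fraction: float = 0.6,
    threshold: float = 0.8,
    n_perm: int = 1000,
    master_seed: int = 0,
    min_gene_threshold: int = 15,
    fdr_threshold: float = 0.05,
    core_only: bool = True,
) -> ConsensusResult:
    """Full subsampling loop over the fixed full-data gene selection.

    Each replicate subsamples reads, re-standardizes residuals, recomputes
    pairwise local correlations over ``module_gene_ids`` and re-detects
    modules; the gene selection itself is not redone. Replicate r uses
    seed ``master_seed + 1 + r``.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if full_modules.n_modules == 0:
        warnings.warn("full-data run has zero modules; consensus is empty")
        return ConsensusResult(
            pair_cooccurrence=pd.Series(dtype=float),
            gene_consensus=pd.Series(dtype=float),
            selected_genes=[],
            threshold=threshold,
        )
    counts = np.asarray(counts)
    col = {g: i for i, g in enumerate(gene_ids)}
    gidx = np.array([col[g] for g in module_gene_ids])
    replicate_results = []
    for r in range(n_reps):
        seed = int(master_seed) + 1 + r
        sub = subsample_counts(counts, tissue_ids, fraction=fraction, seed=seed)
        keep = sub.sum(axis=0) > 0
        sub_idx = np.array([i for i in gidx if keep[i]])
        X = standardized_residuals(sub[:, keep])
        remap = {orig: new for new, orig in enumerate(np.flatnonzero(keep))}
        lc = local_correlation(
            X,
            graph,
            [remap[i] for i in sub_idx],
            n_perm=n_perm,
            seed=seed,
            gene_ids=[gene_ids[i] for i in np.flatnonzero(keep)],
        )
        modules = detect_modules(
            lc,
            min_gene_threshold=min_gene_threshold,
            fdr_threshold=fdr_threshold,
            core_only=core_only,
        )
        replicate_results.append(modules)
    result = consensus_scores(full_modules, replicate_results, threshold=threshold)
    result.replicate_assignments = pd.DataFrame(
        {f"rep{r:03d}": m.assignments for r, m in enumerate(replicate_results)}
    ).reindex(sorted(module_gene_ids)).fillna(-1).astype(int)
    return result
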