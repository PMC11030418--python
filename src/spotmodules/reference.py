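"""Reference QC, normalization, marker selection and profile construction.

The single-cell (or single-nucleus) reference is quality-filtered, log
normalized, and reduced to a panel of cell-state marker genes selected by
pairwise Welch t-tests. Per-state mean-expression profiles over the marker
union are the input to spot deconvolution. Tumor states are grouped under
one coarse "tumor" label so that tumor-vs-tumor comparisons are skipped
during marker selection, retaining genes shared across tumor states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceProfile",
    "filter_reference_cells",
    "filter_reference_genes",
    "normalize_log2_cp10k",
    "select_markers",
    "build_reference",
]


@dataclass
class ReferenceProfile:
    """Per-state reference over the marker-gene universe.

    ``profile`` rows are probability vectors (mean counts per state,
    floored at ``pseudo_min``, then normalized over the marker union).
    """

    profile: np.ndarray
    gene_ids: list
    fine_labels: list
    coarse_of: dict
    marker_genes: dict = field(default_factory=dict)
    pseudo_min: float = 0.0

    @property
    def n_states(self) -> int:
        return self.profile.shape[0]

    def state_index(self, name: str) -> int:
        return self.fine_labels.index(name)

    def states_of_coarse(self, coarse: str) -> list:
        return [s for s in self.fine_labels if self.coarse_of[s] == coarse]


def filter_reference_cells(
    counts: np.ndarray,
    mito_mask: np.ndarray | None = None,
    min_genes: int = 200,
    min_umis: int = 1000,
    max_mito_frac: float = 0.10,
):
    """Remove low-quality cells.

    Cells are removed when they have fewer than ``min_genes`` detected
    genes, fewer than ``min_umis`` total counts, or a mitochondrial
    fraction strictly above ``max_mito_frac`` (a fraction exactly at the
    threshold is retained). Returns (filtered counts, kept boolean mask).
    """
    counts = np.asarray(counts)
    detected = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    keep = (detected >= min_genes) & (totals >= min_umis)
    if mito_mask is not None and np.asarray(mito_mask).any():
        mito = counts[:, np.asarray(mito_mask)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
        keep &= frac <= max_mito_frac
    if not keep.any():
        failing = []
        if not (detected >= min_genes).any():
            failing.append(f"min_genes={min_genes}")
        if not (totals >= min_umis).any():
            failing.append(f"min_umis={min_umis}")
        raise ValueError(
            "no cells pass the reference QC filters"
            + (f" (all cells fail {', '.join(failing)})" if failing else "")
        )
    return counts[keep], keep


def filter_reference_genes(
    counts: np.ndarray,
    gene_ids: list,
    min_cells: int = 3,
    drop_sets: dict | None = None,
):
    """Remove genes detected in fewer than ``min_cells`` cells or listed in
    any named drop set (e.g. mitochondrial, ribosomal).

    Returns (filtered counts, kept gene ids, kept boolean mask).
    """
    counts = np.asarray(counts)
    detected = (counts > 0).sum(axis=0)
    keep = detected >= min_cells
    drop = set()
    for genes in (drop_sets or {}).values():
        drop |= set(genes)
    keep &= np.array([g not in drop for g in gene_ids])
    kept_ids = [g for g, m in zip(gene_ids, keep) if m]
    return counts[:, keep], kept_ids, keep


def normalize_log2_cp10k(counts: np.ndarray) -> np.ndarray:
    """log2(counts-per-10k + 1) per cell; invariant to per-cell scaling."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("zero-total cell: cannot normalize")
    return np.log2(counts / totals * 1e4 + 1.0)


def _welch_pairwise(norm: np.ndarray, labels: np.ndarray, states: list):
    """Per-state means/vars/counts and pairwise Welch t-test p-values.

    Returns (means, lfc, pvals) where lfc[a][b] and pvals[a][b] are
    per-gene arrays for the comparison state a vs state b. The log2 fold
    change is log2((mean_cp10k_a + 1) / (mean_cp10k_b + 1)) computed on
    the back-transformed (linear cp10k) scale.
    """
    stats_by_state = {}
    for s in states:
        block = norm[labels == s]
        if block.shape[0] < 2:
            raise ValueError(f"state {s!r} has fewer than 2 cells; t-test undefined")
        lin = 2.0**block - 1.0  # back to cp10k scale for fold changes
        stats_by_state[s] = (
            block.mean(axis=0),
            block.var(axis=0, ddof=1),
            block.shape[0],
            lin.mean(axis=0),
        )
    pvals: dict = {s: {} for s in states}
    lfc: dict = {s: {} for s in states}
    for a, b in itertools.combinations(states, 2):
        ma, va, na, la = stats_by_state[a]
        mb, vb, nb, lb = stats_by_state[b]
        se2 = va / na + vb / nb
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (ma - mb) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = np.where(se2 == 0, 0.0, t)
        df = np.where(np.isfinite(df), df, 1.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(se2 == 0, 1.0, p)
        pvals[a][b] = pvals[b][a] = p
        fc = np.log2((la + 1.0) / (lb + 1.0))
        lfc[a][b] = fc
        lfc[b][a] = -fc
    return stats_by_state, lfc, pvals


def select_markers(
    norm_expr: np.ndarray,
    gene_ids: list,
    fine_labels: np.ndarray,
    coarse_of: dict,
    tumor_coarse: str = "tumor",
    p_max: float = 0.01,
    lfc_min: float = 0.1,
):
    """Select per-state marker genes by pairwise differential tests.

    For each fine state the pairwise Welch t-test p-values and log2 fold
    changes against comparison states are summarized by their maximum and
    minimum respectively; a gene is a marker iff max_p < ``p_max`` AND
    min_lfc > ``lfc_min``. Non-tumor states are compared against every
    other state; tumor states (coarse label ``tumor_coarse``) only against
    non-tumor states, so genes shared between tumor states are retained.

    Returns (stats DataFrame indexed by (gene, state) with columns max_p /
    min_lfc / is_marker / coarse, marker dict coarse type -> sorted gene
    list).
    """
    fine_labels = np.asarray(fine_labels)
    states = sorted(set(fine_labels))
    _, lfc, pvals = _welch_pairwise(np.asarray(norm_expr), fine_labels, states)
    rows = []
    markers: dict = {}
    gene_arr = np.asarray(gene_ids)
    for s in states:
        if coarse_of[s] == tumor_coarse:
            cmp_states = [o for o in states if o != s and coarse_of[o] != tumor_coarse]
        else:
            cmp_states = [o for o in states if o != s]
        max_p = np.max([pvals[s][o] for o in cmp_states], axis=0)
        min_lfc = np.min([lfc[s][o] for o in cmp_states], axis=0)
        is_marker = (max_p < p_max) & (min_lfc > lfc_min)
        for g, mp, ml, im in zip(gene_arr, max_p, min_lfc, is_marker):
            rows.append((g, s, coarse_of[s], mp, ml, bool(im)))
        coarse = coarse_of[s]
        markers.setdefault(coarse, set()).update(gene_arr[is_marker])
    stats_df = pd.DataFrame(
        rows, columns=["gene", "state", "coarse", "max_p", "min_lfc", "is_marker"]
    ).set_index(["gene", "state"])
    markers = {c: sorted(gs) for c, gs in markers.items()}
    return stats_df, markers


def marker_universe(markers: dict) -> list:
    """Union of all marker sets, sorted for determinism."""
    u: set = set()
    for gs in markers.values():
        u |= set(gs)
    return sorted(u)


def build_reference(
    counts: np.ndarray,
    gene_ids: list,
    fine_labels: np.ndarray,
    coarse_of: dict,
    markers: dict,
    pseudo_min: float = 0.0,
) -> ReferenceProfile:
    """Per-state mean raw counts over the marker union, floored at
    ``pseudo_min`` and normalized to probability vectors."""
    counts = np.asarray(counts, dtype=float)
    fine_labels = np.asarray(fine_labels)
    universe = marker_universe(markers)
    col = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in universe if g not in col]
    if missing:
        raise ValueError(f"marker genes absent from reference: {missing[:5]}...")
    idx = [col[g] for g in universe]
    states = sorted(set(fine_labels))
    profile = np.empty((len(states), len(universe)))
    for i, s in enumerate(states):
        mean = counts[np.ix_(fine_labels == s, idx)].mean(axis=0)
        mean = np.maximum(mean, pseudo_min)
        tot = mean.sum()
        if tot <= 0:
            raise ValueError(f"state {s!r} has zero expression over the marker universe")
        profile[i] = mean / tot
    return ReferenceProfile(
        profile=profile,
        gene_ids=universe,
        fine_labels=states,
        coarse_of=dict(coarse_of),
        marker_genes={c: sorted(gs) for c, gs in markers.items()},
        pseudo_min=pseudo_min,
    )
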