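"""Spatially coherent genes and gene modules on a kNN spot graph.

Expression residuals are standardized under a depth-dependent negative
binomial null (Poisson limit when no overdispersion is detected). On a
k-nearest-neighbour graph restricted within each tissue section, the
per-gene autocorrelation statistic

    H_g = sum_i sum_{j in N(i) u {i}} x_ig x_jg / (k + 1)

and the pairwise local-correlation statistic

    C_gh = sum_i sum_{j in N(i) u {i}} (x_ig x_jh + x_ih x_jg) / (2 (k+1))

measure spatial coherence and co-expression of standardized residuals x.
Both are calibrated by a within-tissue permutation null: Z-scores come
from the permutation moments, and per-gene/pair p-values for
Benjamini-Hochberg control come from the normal tail of those Z-scores
(the raw empirical permutation p is reported alongside). C_gg equals H_g
identically. Modules are grown by bottom-up average-linkage merging of
the pairwise Z matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NeighborGraph",
    "LocalCorr",
    "ModuleResult",
    "build_knn_graph",
    "standardized_residuals",
    "autocorrelation",
    "select_module_genes",
    "local_correlation",
    "detect_modules",
    "module_scores",
]


@dataclass
class NeighborGraph:
    """Directed kNN lists (each spot contributes its own k neighbours plus
    itself, all with equal weight); no edge crosses a tissue boundary."""

    neighbors: np.ndarray  # (n_spots, k)
    tissue_ids: np.ndarray
    k: int

    @property
    def n_spots(self) -> int:
        return self.neighbors.shape[0]

    def adjacency(self, include_self: bool = True) -> sparse.csr_matrix:
        S, k = self.neighbors.shape
        rows = np.repeat(np.arange(S), k)
        cols = self.neighbors.ravel()
        if include_self:
            rows = np.concatenate([rows, np.arange(S)])
            cols = np.concatenate([cols, np.arange(S)])
        data = np.ones(rows.size)
        return sparse.csr_matrix((data, (rows, cols)), shape=(S, S))

    def tissue_groups(self) -> list:
        tissues = np.asarray(self.tissue_ids)
        return [np.flatnonzero(tissues == t) for t in pd.unique(tissues)]


def build_knn_graph(positions: np.ndarray, tissue_ids, k: int = 6) -> NeighborGraph:
    """k nearest neighbours by Euclidean distance, computed per tissue.

    Partitioning by tissue is equivalent to shifting each tissue's
    coordinates by any offset exceeding the tissue diameter (no cross-
    tissue pair can then enter a neighbour list) but avoids the magic
    constant. Distance ties are broken by spot index (stable sort).
    """
    positions = np.asarray(positions, dtype=float)
    tissue_ids = np.asarray(tissue_ids)
    S = positions.shape[0]
    neighbors = np.empty((S, k), dtype=np.int64)
    for t in pd.unique(tissue_ids):
        idx = np.flatnonzero(tissue_ids == t)
        if idx.size <= k:
            raise ValueError(f"tissue {t!r} has {idx.size} spots; need > k={k}")
        pts = positions[idx]
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, -1.0)  # self sorts first, then dropped
        order = np.argsort(d, axis=1, kind="stable")
        neighbors[idx] = idx[order[:, 1 : k + 1]]
    return NeighborGraph(neighbors=neighbors, tissue_ids=tissue_ids, k=k)


def standardized_residuals(counts: np.ndarray, spot_totals=None) -> np.ndarray:
    """Depth-standardized residuals under a per-gene NB null.

    x_sg = (c_sg - d_s p_g) / sqrt(d_s p_g (1 + d_s p_g / alpha_g)) with
    p_g the pooled gene frequency and alpha_g a method-of-moments
    dispersion (alpha -> inf, i.e. Poisson, when no excess variance).
    """
    counts = np.asarray(counts, dtype=float)
    d = counts.sum(axis=1) if spot_totals is None else np.asarray(spot_totals, float)
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError("zero-total genes must be excluded before standardization")
    p = counts.sum(axis=0) / d.sum()
    mu = d[:, None] * p[None, :]
    resid = counts - mu
    excess = (resid**2).sum(axis=0) - mu.sum(axis=0)
    mu2 = (mu**2).sum(axis=0)
    inv_alpha = np.where(excess > 0, excess / np.maximum(mu2, 1e-300), 0.0)
    var = mu * (1.0 + mu * inv_alpha[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(var > 0, resid / np.sqrt(var), 0.0)
    return x


def _tissue_permutation(rng, groups, S: int) -> np.ndarray:
    perm = np.arange(S)
    for idx in groups:
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def _self_cross(X: np.ndarray, AX: np.ndarray, kp1: int) -> np.ndarray:
    """sum_i x_ig (A x)_ig / (k+1), one value per gene."""
    return np.einsum("ig,ig->g", X, AX) / kp1


def autocorrelation(
    residuals: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 1000,
    seed: int | None = None,
    min_tissue_spots: int = 20,
    gene_ids=None,
) -> pd.DataFrame:
    """Per-gene spatial autocorrelation with a within-tissue permutation null.

    Returns a DataFrame (indexed by gene) with the statistic H, the
    permutation Z-score, the one-sided normal-tail p-value used for BH-FDR
    (``p``), the empirical permutation p-value (``p_perm``) and ``fdr``.
    """
    X = np.asarray(residuals, dtype=float)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation null")
    groups = graph.tissue_groups()
    small = [g.size for g in groups if g.size < min_tissue_spots]
    if small:
        raise ValueError(
            f"tissues with fewer than {min_tissue_spots} spots: {small}; "
            "lower min_tissue_spots only for toy data"
        )
    A = graph.adjacency()
    kp1 = graph.k + 1
    H = _self_cross(X, A @ X, kp1)

    rng = np.random.default_rng(seed)
    S, G = X.shape
    perm_sum = np.zeros(G)
    perm_sq = np.zeros(G)
    ge_count = np.zeros(G)
    for _ in range(n_perm):
        perm = _tissue_permutation(rng, groups, S)
        Xp = X[perm]
        Hp = _self_cross(Xp, A @ Xp, kp1)
        perm_sum += Hp
        perm_sq += Hp**2
        ge_count += Hp >= H
    mean = perm_sum / n_perm
    var = np.maximum(perm_sq / n_perm - mean**2, 0.0) * n_perm / max(n_perm - 1, 1)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (H - mean) / sd, 0.0)
    p = stats.norm.sf(Z)
    p_perm = (1.0 + ge_count) / (n_perm + 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    index = pd.Index(gene_ids if gene_ids is not None else np.arange(G), name="gene")
    return pd.DataFrame({"H": H, "Z": Z, "p": p, "p_perm": p_perm, "fdr": fdr}, index=index)


def select_module_genes(
    acorr: pd.DataFrame,
    tf_list,
    fdr_max: float = 0.01,
    top_n: int = 500,
) -> list:
    """Genes with autocorrelation FDR < ``fdr_max``, restricted to the
    transcription-factor list, then to the ``top_n`` by Z-score.

    Returned in descending-Z order (ties by gene id)."""
    tf = set(tf_list)
    cand = acorr[(acorr["fdr"] < fdr_max) & acorr.index.isin(tf)]
    if cand.empty:
        warnings.warn("no genes pass the autocorrelation/TF selection")
        return []
    cand = cand.iloc[np.lexsort((cand.index.to_numpy(), -cand["Z"].to_numpy()))]
    return list(cand.index[:top_n])


@dataclass
class LocalCorr:
    """Pairwise local-correlation statistics over a gene subset."""

    genes: list
    C: np.ndarray
    Z: np.ndarray
    p: np.ndarray  # one-sided normal tail of Z

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.genes, columns=self.genes)


def local_correlation(
    residuals: np.ndarray,
    graph: NeighborGraph,
    gene_idx,
    n_perm: int = 1000,
    seed: int | None = None,
    gene_ids=None,
) -> LocalCorr:
    """Pairwise graph-weighted co-expression of standardized residuals.

    The null permutes one gene of each pair within tissues (implemented as
    a shared permutation applied to the second argument); permutation
    moments are symmetrized so Z is exactly symmetric, and the diagonal of
    C is written from the autocorrelation statistic (the algebraic
    identity C_gg = H_g then holds bit-exactly).
    """
    gene_idx = np.asarray(gene_idx)
    if gene_idx.size < 2:
        raise ValueError("need at least 2 genes for local correlation")
    X = np.asarray(residuals, dtype=float)[:, gene_idx]
    A = graph.adjacency()
    B = (A + A.T).tocsr()
    kp1 = graph.k + 1
    AX = A @ X
    M1 = X.T @ AX
    C = (M1 + M1.T) / (2.0 * kp1)
    H = _self_cross(X, AX, kp1)
    np.fill_diagonal(C, H)

    rng = np.random.default_rng(seed)
    S, G = X.shape
    groups = graph.tissue_groups()
    psum = np.zeros((G, G))
    psq = np.zeros((G, G))
    for _ in range(n_perm):
        perm = _tissue_permutation(rng, groups, S)
        Cp = (X.T @ (B @ X[perm])) / (2.0 * kp1)
        psum += Cp
        psq += Cp**2
    mean = psum / n_perm
    var = np.maximum(psq / n_perm - mean**2, 0.0) * n_perm / max(n_perm - 1, 1)
    mean = (mean + mean.T) / 2.0
    sd = np.sqrt((var + var.T) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (C - mean) / sd, 0.0)
    Z = (Z + Z.T) / 2.0
    p = stats.norm.sf(Z)
    if gene_ids is not None:
        genes = [gene_ids[i] for i in gene_idx]
    else:
        genes = list(gene_idx)
    return LocalCorr(genes=genes, C=C, Z=Z, p=p)


@dataclass
class ModuleResult:
    """Gene -> module assignment (ids 1..M; unassigned = -1)."""

    assignments: pd.Series
    scores: pd.DataFrame | None = None

    @property
    def n_modules(self) -> int:
        return int((pd.unique(self.assignments) != -1).sum())

    def module_genes(self) -> dict:
        out: dict = {}
        for g, m in self.assignments.items():
            if m != -1:
                out.setdefault(int(m), []).append(g)
        return {m: sorted(gs) for m, gs in out.items()}


def detect_modules(
    localcorr: LocalCorr,
    min_gene_threshold: int = 15,
    fdr_threshold: float = 0.05,
    core_only: bool = True,
) -> ModuleResult:
    """Bottom-up average-linkage merging of the pairwise Z matrix.

    Gene pairs significant at BH-FDR < ``fdr_threshold`` (one-sided p from
    Z) define the significance level; clusters are merged greedily by
    highest average cross-pair Z while that linkage stays at or above the
    weakest significant pairwise Z. With ``core_only``, final clusters
    smaller than ``min_gene_threshold`` are dissolved to unassigned (-1).
    Merge ties break lexicographically on the smallest gene id.
    """
    genes = list(localcorr.genes)
    G = len(genes)
    Z = np.asarray(localcorr.Z, dtype=float)
    p = np.asarray(localcorr.p, dtype=float)
    iu = np.triu_indices(G, k=1)
    if iu[0].size == 0:
        return ModuleResult(pd.Series(-1, index=genes, name="module"))
    rej = multipletests(p[iu], alpha=fdr_threshold, method="fdr_bh")[0]
    if not rej.any():
        return ModuleResult(pd.Series(-1, index=genes, name="module"))
    z_crit = float(np.min(Z[iu][rej]))

    # average-linkage agglomeration (Lance-Williams update)
    L = Z.copy().astype(float)
    np.fill_diagonal(L, -np.inf)
    active = list(range(G))
    members = {i: [i] for i in range(G)}
    while len(active) > 1:
        sub = L[np.ix_(active, active)]
        best = np.max(sub)
        if best < z_crit:
            break
        cand = np.argwhere(sub >= best - 1e-12)
        cand = [(active[i], active[j]) for i, j in cand if i < j]
        a, b = min(
            cand,
            key=lambda ab: (
                min(str(genes[i]) for i in members[ab[0]]),
                min(str(genes[i]) for i in members[ab[1]]),
            ),
        )
        na, nb = len(members[a]), len(members[b])
        for c in active:
            if c not in (a, b):
                L[a, c] = L[c, a] = (na * L[a, c] + nb * L[b, c]) / (na + nb)
        members[a] = sorted(members[a] + members[b])
        del members[b]
        active.remove(b)

    clusters = sorted(
        (m for m in members.values() if len(m) >= (min_gene_threshold if core_only else 2)),
        key=lambda m: min(str(genes[i]) for i in m),
    )
    assign = pd.Series(-1, index=genes, name="module", dtype=int)
    for mid, m in enumerate(clusters, start=1):
        assign.iloc[m] = mid
    return ModuleResult(assign)


def module_scores(
    norm_expr: np.ndarray,
    gene_ids: list,
    modules: ModuleResult,
    graph: NeighborGraph,
) -> pd.DataFrame:
    """Per-spot smoothed summary score per module.

    Genes are z-scored across spots, averaged within each module, then
    smoothed by one round of neighbour averaging (self included).
    """
    expr = np.asarray(norm_expr, dtype=float)
    col = {g: i for i, g in enumerate(gene_ids)}
    A = graph.adjacency()
    kp1 = graph.k + 1
    out = {}
    for mid, genes in sorted(modules.module_genes().items()):
        idx = [col[g] for g in genes if g in col]
        if not idx:
            continue
        block = expr[:, idx]
        mu, sd = block.mean(axis=0), block.std(axis=0)
        # constant genes (sd at floating-point noise level) score zero
        sd_safe = np.where(sd > 1e-12 * np.maximum(np.abs(mu), 1.0), sd, np.inf)
        score = ((block - mu) / sd_safe).mean(axis=1)
        out[mid] = (A @ score) / kp1
    return pd.DataFrame(out)
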