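"""Benchmarks: deconvolved vs raw workflows, and bulk signature contrasts.

The headline comparison asks whether restricting spatial statistics to
deconvolved tumor counts raises the spatial signal of tumor markers and
suppresses the signal of non-tumor markers (including spatially smooth
stromal confounders), relative to running the same statistics on raw
spot counts. Marker sets come from the reference's differential tests;
one-sided paired t-tests compare autocorrelation Z-scores per cell type
and |local-correlation Z| across marker-pair categories.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "benchmark_marker_sets",
    "paired_autocorr_test",
    "paircorr_category_test",
    "bulk_signature_contrast",
]


def benchmark_marker_sets(marker_stats: pd.DataFrame, top_n: int = 100) -> dict:
    """Top markers per coarse cell type, ranked by log2 fold change.

    ``marker_stats`` is the per-(gene, state) table from marker selection.
    A gene qualifies for a coarse type when it is a marker of any member
    state; its ranking fold change is the largest qualifying min_lfc.
    Returns {coarse type: gene list} truncated to ``top_n`` (descending
    min_lfc, ties broken by gene id). Raises when a type has fewer than 2
    qualifying genes (the paired test downstream would be undefined).
    """
    df = marker_stats.reset_index()
    hits = df[df["is_marker"]]
    out = {}
    for coarse, grp in hits.groupby("coarse"):
        per_gene = grp.groupby("gene")["min_lfc"].max().reset_index()
        if len(per_gene) < 2:
            raise ValueError(f"coarse type {coarse!r} has <2 marker genes")
        if len(per_gene) < top_n:
            warnings.warn(
                f"coarse type {coarse!r}: only {len(per_gene)} markers pass "
                f"(requested top {top_n}); using all"
            )
        order = per_gene.sort_values(
            ["min_lfc", "gene"], ascending=[False, True], kind="stable"
        )
        out[coarse] = list(order["gene"].iloc[:top_n])
    return out


def paired_autocorr_test(z_deconv: pd.Series, z_raw: pd.Series, direction: str = "greater"):
    """One-sided paired t-test on autocorrelation Z-scores.

    ``direction`` is the alternative for (deconvolved - raw): "greater"
    for tumor markers (deconvolution expected to raise Z), "less" for
    non-tumor markers. Returns dict with t, one-sided p, mean difference
    and n. Zero-variance differences are reported as p = 0 or 1 by sign.
    """
    common = z_deconv.index.intersection(z_raw.index)
    d = (z_deconv.loc[common] - z_raw.loc[common]).to_numpy(dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired genes")
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences; degenerate paired t-test")
        mean = float(d.mean())
        if mean == 0:
            p = 1.0
        else:
            better = (mean > 0) if direction == "greater" else (mean < 0)
            p = 0.0 if better else 1.0
        return {"t": 0.0 if mean == 0 else np.sign(mean) * np.inf,
                "p": p, "mean_diff": mean, "n": int(d.size), "direction": direction}
    t, p = stats.ttest_1samp(d, 0.0, alternative=direction)
    return {"t": float(t), "p": float(p), "mean_diff": float(d.mean()),
            "n": int(d.size), "direction": direction}


def paircorr_category_test(
    z_deconv: pd.DataFrame,
    z_raw: pd.DataFrame,
    tumor_markers,
    nontumor_markers,
) -> pd.DataFrame:
    """Paired one-sided t-tests on |local-correlation Z| by pair category.

    Categories: tumor-tumor (alternative: deconvolved |Z| greater),
    tumor-nontumor and nontumor-nontumor (alternative: deconvolved |Z|
    smaller). Pairs exclude self-pairs; both matrices must cover the
    marker genes.
    """
    genes = set(z_deconv.index) & set(z_raw.index)
    tum = sorted(set(tumor_markers) & genes)
    non = sorted(set(nontumor_markers) & genes)
    cats = {
        "tumor-tumor": (list(itertools.combinations(tum, 2)), "greater"),
        "tumor-nontumor": ([(a, b) for a in tum for b in non], "less"),
        "nontumor-nontumor": (list(itertools.combinations(non, 2)), "less"),
    }
    rows = []
    for name, (pairs, direction) in cats.items():
        if len(pairs) < 2:
            warnings.warn(f"category {name!r} has <2 pairs; skipped")
            rows.append((name, len(pairs), np.nan, np.nan, np.nan, direction, True))
            continue
        dd = np.array(
            [abs(z_deconv.at[a, b]) - abs(z_raw.at[a, b]) for a, b in pairs], dtype=float
        )
        if np.allclose(dd.std(ddof=1), 0.0):
            rows.append((name, len(pairs), float(dd.mean()), 0.0, 1.0, direction, False))
            continue
        t, p = stats.ttest_1samp(dd, 0.0, alternative=direction)
        rows.append((name, len(pairs), float(dd.mean()), float(t), float(p), direction, False))
    return pd.DataFrame(
        rows,
        columns=["category", "n_pairs", "mean_abs_dz", "t", "p", "direction", "skipped"],
    ).set_index("category")


def bulk_signature_contrast(
    bulk_expr: pd.DataFrame,
    group_labels: pd.Series,
    gene_sets: dict,
    positive_group: str | None = None,
):
    """Signature contrast on bulk expression (e.g. FPKM) between two groups.

    Per gene: log2((mean_pos + 1) / (mean_neg + 1)) plus a two-sided
    rank-sum p across samples (exact for <= 10 samples per group). Per
    gene set: the same rank-sum test on per-sample set scores (mean of
    log2(expr + 1) over the set's genes present in the matrix; absent
    genes are dropped).

    ``bulk_expr`` is genes x samples. Returns (per-gene DataFrame with
    lfc and p, per-set DataFrame).
    """
    labels = pd.Series(group_labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    pos = positive_group if positive_group is not None else groups[0]
    neg = [g for g in groups if g != pos][0]
    pos_samples = labels.index[labels == pos]
    neg_samples = labels.index[labels == neg]
    if min(len(pos_samples), len(neg_samples)) < 5:
        warnings.warn("fewer than 5 samples in a group; rank-sum p is coarse")
    method = "exact" if max(len(pos_samples), len(neg_samples)) <= 10 else "asymptotic"

    a = bulk_expr[pos_samples].to_numpy(dtype=float)
    b = bulk_expr[neg_samples].to_numpy(dtype=float)
    lfc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
    pvals = np.array(
        [
            stats.mannwhitneyu(ra, rb, alternative="two-sided", method=method).pvalue
            for ra, rb in zip(a, b)
        ]
    )
    per_gene = pd.DataFrame({"lfc": lfc, "p": pvals}, index=bulk_expr.index)

    set_rows = []
    logx = np.log2(bulk_expr + 1.0)
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in bulk_expr.index]
        dropped = len(list(genes)) - len(present)
        if not present:
            set_rows.append((name, 0, dropped, np.nan, np.nan))
            continue
        score = logx.loc[present].mean(axis=0)
        res = stats.mannwhitneyu(
            score[pos_samples], score[neg_samples], alternative="two-sided", method=method
        )
        mean_lfc = float(per_gene.loc[present, "lfc"].mean())
        set_rows.append((name, len(present), dropped, mean_lfc, float(res.pvalue)))
    per_set = pd.DataFrame(
        set_rows, columns=["set", "n_genes", "n_dropped", "mean_lfc", "p"]
    ).set_index("set")
    return per_gene, per_set
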