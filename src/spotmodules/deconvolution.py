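"""Spot deconvolution: cell-state fractions and state-specific counts.

Each spot's counts are modelled as a multinomial mixture over reference
state profiles, p_g(theta) = sum_k theta_k phi_kg. Maximum-likelihood
fractions theta are fitted per spot by EM (the per-spot log-likelihood is
concave in theta, so a uniform start suffices), and reads are allocated
to states by posterior responsibility:

    z[s, k, g] = c[s, g] * theta_sk phi_kg / sum_k' theta_sk' phi_k'g.

Summing z over the tumor states and rounding up yields the tumor-specific
count matrix used for spatial module detection downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpotDataset

__all__ = [
    "DeconvolutionResult",
    "filter_spots_and_genes",
    "deconvolve",
    "tumor_counts",
    "celltype_fraction_map",
    "replicate_concordance",
]

PHI_FLOOR = 1e-12  # guard when a positive count hits a zero-probability gene


@dataclass
class DeconvolutionResult:
    """Per-spot fractions (theta) plus everything needed to materialize
    the posterior state-specific expected counts (Z)."""

    theta: np.ndarray
    phi: np.ndarray
    counts: np.ndarray
    state_names: list
    gene_ids: list
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0

    @property
    def n_spots(self) -> int:
        return self.theta.shape[0]

    def _responsibilities(self, state_idx) -> np.ndarray:
        """Share of each (spot, gene) count attributable to the states."""
        phi = np.maximum(self.phi, PHI_FLOOR)
        denom = self.theta @ phi
        num = self.theta[:, state_idx] @ phi[state_idx]
        return num / denom

    def expected_counts(self, states=None) -> np.ndarray:
        """Posterior expected counts summed over ``states`` (default all)."""
        if states is None:
            idx = np.arange(len(self.state_names))
        else:
            idx = np.asarray([self.state_names.index(s) if isinstance(s, str) else s
                              for s in states])
        return self.counts * self._responsibilities(idx)

    @property
    def z(self) -> np.ndarray:
        """Full spot x state x gene posterior allocation."""
        phi = np.maximum(self.phi, PHI_FLOOR)
        denom = self.theta @ phi  # (S, G)
        return (
            self.counts[:, None, :]
            * (self.theta[:, :, None] * phi[None, :, :])
            / denom[:, None, :]
        )


def filter_spots_and_genes(
    spots: SpotDataset,
    min_spot_genes: int = 1000,
    min_spot_umis: int = 1000,
    min_gene_spots_exclusive: int = 3,
) -> SpotDataset:
    """Remove sparse genes and low-coverage spots.

    Genes expressed in <= ``min_gene_spots_exclusive`` spots are removed;
    spots with fewer than ``min_spot_genes`` detected genes or fewer than
    ``min_spot_umis`` total counts are removed (spot metrics are computed
    on the full gene set, before the gene filter).
    """
    counts = spots.counts
    detected_genes = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    spot_keep = (detected_genes >= min_spot_genes) & (totals >= min_spot_umis)
    gene_keep = (counts > 0).sum(axis=0) > min_gene_spots_exclusive
    if not spot_keep.any():
        raise ValueError(
            f"no spots pass filters (min_spot_genes={min_spot_genes}, "
            f"min_spot_umis={min_spot_umis})"
        )
    if not gene_keep.any():
        raise ValueError(
            f"no genes expressed in more than {min_gene_spots_exclusive} spots"
        )
    out = spots.subset_spots(spot_keep)
    return out.subset_genes([g for g, m in zip(spots.gene_ids, gene_keep) if m])


def deconvolve(
    spots,
    ref,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = None,
) -> DeconvolutionResult:
    """Fit per-spot mixture fractions by EM and allocate counts to states.

    ``spots`` may be a SpotDataset or a raw (spot x gene) count matrix; in
    the former case columns are restricted and ordered to the reference's
    marker-gene universe. EM starts from uniform theta (the per-spot
    log-likelihood is concave, so no multi-start is needed; ``seed`` is
    accepted for interface stability) and stops when the relative
    improvement of the total log-likelihood drops below ``tol``.
    """
    if isinstance(spots, SpotDataset):
        missing = [g for g in ref.gene_ids if g not in set(spots.gene_ids)]
        if missing:
            raise ValueError(f"spot matrix lacks reference genes: {missing[:5]}...")
        counts = spots.subset_genes(ref.gene_ids).counts.astype(float)
    else:
        counts = np.asarray(spots, dtype=float)
        if counts.shape[1] != len(ref.gene_ids):
            raise ValueError("count columns do not match the reference gene universe")
    phi = np.asarray(ref.profile, dtype=float)
    K = phi.shape[0]
    if np.any((phi.sum(axis=0) <= 0) & (counts.sum(axis=0) > 0)):
        warnings.warn(
            "positive counts on genes with zero probability under every state; "
            f"flooring profiles at {PHI_FLOOR}"
        )
    phi = np.maximum(phi, PHI_FLOOR)

    S = counts.shape[0]
    theta = np.full((S, K), 1.0 / K)
    totals = counts.sum(axis=1, keepdims=True)
    trace = []
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mix = theta @ phi  # (S, G)
        ll = float(np.sum(counts * np.log(mix)))
        trace.append(ll)
        # EM update: theta_k <- sum_g c_g r_kg / total, r = responsibility
        theta = theta * ((counts / mix) @ phi.T) / np.maximum(totals, 1.0)
        rowsum = theta.sum(axis=1, keepdims=True)
        theta = np.where(rowsum > 0, theta / np.maximum(rowsum, 1e-300), 1.0 / K)
        if prev > -np.inf and (ll - prev) <= tol * abs(prev):
            break
        prev = ll
    return DeconvolutionResult(
        theta=theta,
        phi=np.asarray(ref.profile, dtype=float),
        counts=counts,
        state_names=list(ref.fine_labels),
        gene_ids=list(ref.gene_ids),
        loglik_trace=np.asarray(trace),
        n_iter=it,
    )


def tumor_counts(result: DeconvolutionResult, tumor_states) -> np.ndarray:
    """Ceiling of the posterior expected counts summed over tumor states.

    Values that are integral up to floating-point noise are snapped to the
    nearest integer before taking the ceiling, so that e.g. pure-tumor
    spots conserve their totals exactly.
    """
    tumor_states = list(tumor_states)
    if not tumor_states:
        raise ValueError("tumor_states must be non-empty")
    z = result.expected_counts(tumor_states)
    near = np.round(z)
    z = np.where(np.abs(z - near) < 1e-9, near, z)
    return np.ceil(z).astype(np.int64)


def celltype_fraction_map(result: DeconvolutionResult, state_group) -> np.ndarray:
    """Per-spot summed fraction over a group of states (e.g. all NE states)."""
    idx = [result.state_names.index(s) if isinstance(s, str) else s for s in state_group]
    if not idx:
        return np.zeros(result.n_spots)
    return result.theta[:, idx].sum(axis=1)


def replicate_concordance(
    theta_a: np.ndarray,
    theta_b: np.ndarray,
    regions_a: np.ndarray,
    regions_b: np.ndarray,
    state_names: list,
):
    """Region-averaged fraction concordance between technical replicates.

    For each replicate the per-region mean fraction of each state is
    computed; Pearson r is then reported per state (across regions) and
    per region (across states). Regions are an input (e.g. histologically
    defined), shared between the replicates.
    """
    regions = sorted(set(np.asarray(regions_a)) & set(np.asarray(regions_b)))
    if len(regions) < 2:
        raise ValueError("need at least 2 shared regions for concordance")

    def region_means(theta, labels):
        labels = np.asarray(labels)
        return pd.DataFrame(
            [theta[labels == r].mean(axis=0) for r in regions],
            index=regions,
            columns=state_names,
        )

    ma, mb = region_means(np.asarray(theta_a), regions_a), region_means(
        np.asarray(theta_b), regions_b
    )
    per_state = {
        s: float(stats.pearsonr(ma[s], mb[s])[0]) for s in state_names
    }
    per_region = {
        r: float(stats.pearsonr(ma.loc[r], mb.loc[r])[0]) for r in regions
    }
    return {"region_means_a": ma, "region_means_b": mb,
            "per_state_r": per_state, "per_region_r": per_region}
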