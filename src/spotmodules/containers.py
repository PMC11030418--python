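"""Shared in-memory containers for spot-level spatial expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpotDataset:
    """Spot x gene counts with spatial coordinates and tissue identity.

    Attributes
    ----------
    counts : ndarray of shape (n_spots, n_genes), integer
        Raw UMI counts per spot.
    gene_ids : list of str
        Gene identifiers (column order of ``counts``).
    barcodes : list of str
        Spot barcodes (row order of ``counts``).
    positions : DataFrame indexed by barcode
        Columns ``array_row``, ``array_col``, ``pxl_row_in_fullres``,
        ``pxl_col_in_fullres``, ``in_tissue``.
    sample_id, slide_id : ndarray of str, per spot
        A tissue is one sample on one slide; neighbourhoods never cross
        tissue boundaries.
    """

    counts: np.ndarray
    gene_ids: list
    barcodes: list
    positions: pd.DataFrame
    sample_id: np.ndarray
    slide_id: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_ids)} genes"
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def tissue_ids(self) -> np.ndarray:
        """Per-spot tissue label combining sample and slide identity."""
        return np.char.add(
            np.char.add(np.asarray(self.sample_id, dtype=str), "::"),
            np.asarray(self.slide_id, dtype=str),
        )

    def coords(self) -> np.ndarray:
        """(n_spots, 2) array of (array_row, array_col) in barcode order."""
        pos = self.positions.loc[self.barcodes]
        return pos[["array_row", "array_col"]].to_numpy(dtype=float)

    def subset_spots(self, mask: np.ndarray) -> "SpotDataset":
        mask = np.asarray(mask)
        barcodes = [b for b, m in zip(self.barcodes, mask) if m]
        return SpotDataset(
            counts=self.counts[mask],
            gene_ids=list(self.gene_ids),
            barcodes=barcodes,
            positions=self.positions.loc[barcodes],
            sample_id=np.asarray(self.sample_id)[mask],
            slide_id=np.asarray(self.slide_id)[mask],
        )

    def subset_genes(self, genes) -> "SpotDataset":
        idx = [self.gene_ids.index(g) for g in genes]
        return SpotDataset(
            counts=self.counts[:, idx],
            gene_ids=list(genes),
            barcodes=list(self.barcodes),
            positions=self.positions,
            sample_id=self.sample_id,
            slide_id=self.slide_id,
        )


@dataclass
class GroundTruth:
    """Known simulation state for scoring recovery downstream.

    ``true_fractions`` rows live on the simplex; ``planted_modules`` holds
    (component, gene-id list) pairs; ``module_field_values`` is the spot x
    module matrix of spatial field intensities actually applied.
    """

    true_fractions: np.ndarray
    region_label: np.ndarray
    planted_modules: list = field(default_factory=list)
    module_field_values: np.ndarray | None = None
    state_names: list = field(default_factory=list)
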