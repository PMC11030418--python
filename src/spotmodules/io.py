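"""Readers and writers for the 10x MTX triplet, Visium positions tables,
sample sheets, TF lists, and the pipeline configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy import sparse

from .containers import SpotDataset

__all__ = [
    "read_counts_mtx",
    "write_counts_mtx",
    "read_positions",
    "write_positions",
    "read_samples",
    "write_samples",
    "read_tf_list",
    "write_tf_list",
    "load_spot_dataset",
    "PipelineConfig",
]

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_counts_mtx(directory):
    """Read a 10x-style MTX triplet; returns (spot x gene counts, gene ids,
    barcodes). The matrix file stores genes x barcodes; it is transposed
    on the way in."""
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    feats = directory / "features.tsv"
    bcs = directory / "barcodes.tsv"
    for f in (mtx, feats, bcs):
        if not f.exists():
            raise FileNotFoundError(f"missing {f}")
    try:
        mat = sio.mmread(mtx)
    except Exception as exc:  # noqa: BLE001 - annotate with file name
        raise ValueError(f"cannot parse {mtx}: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{mtx}: non-integer entries in count matrix")
    features = pd.read_csv(feats, sep="\t", header=None)
    barcodes = pd.read_csv(bcs, sep="\t", header=None)[0].tolist()
    gene_ids = features[0].tolist()
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise ValueError(
            f"{mtx}: header {mat.shape} does not match {len(gene_ids)} features "
            f"x {len(barcodes)} barcodes"
        )
    counts = np.asarray(mat.T.todense()).astype(np.int64)
    return counts, gene_ids, barcodes


def write_counts_mtx(directory, counts: np.ndarray, gene_ids, barcodes) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(np.asarray(counts).T)
    sio.mmwrite(directory / "matrix.mtx", mat, field="integer")
    pd.DataFrame({0: gene_ids, 1: gene_ids, 2: "Gene Expression"}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(barcodes).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)


def read_positions(path) -> pd.DataFrame:
    """Visium positions table, headered or legacy headerless (6 columns)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    headered = "barcode" in first.lower()
    df = pd.read_csv(path, header=0 if headered else None)
    if not headered:
        if df.shape[1] != len(POSITION_COLUMNS):
            raise ValueError(
                f"{path}: headerless positions file must have "
                f"{len(POSITION_COLUMNS)} columns, found {df.shape[1]}"
            )
        df.columns = POSITION_COLUMNS
    missing = set(POSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate barcodes {dup[:5]}")
    return df.set_index("barcode")


def write_positions(path, positions: pd.DataFrame) -> None:
    positions.reset_index().to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"barcode", "sample_id", "slide_id"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: samples table needs columns {sorted(need)}")
    return df.set_index("barcode")


def write_samples(path, barcodes, sample_id, slide_id) -> None:
    pd.DataFrame(
        {"barcode": barcodes, "sample_id": sample_id, "slide_id": slide_id}
    ).to_csv(path, sep="\t", index=False)


def read_tf_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_tf_list(path, genes) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def load_spot_dataset(counts_dir, positions_csv, samples_tsv) -> SpotDataset:
    """Assemble a SpotDataset; out-of-tissue spots are dropped and every
    counted barcode must appear in the positions table."""
    counts, gene_ids, barcodes = read_counts_mtx(counts_dir)
    positions = read_positions(positions_csv)
    samples = read_samples(samples_tsv)
    missing = [b for b in barcodes if b not in positions.index]
    if missing:
        raise ValueError(f"barcodes missing from positions: {missing[:5]}")
    missing = [b for b in barcodes if b not in samples.index]
    if missing:
        raise ValueError(f"barcodes missing from samples table: {missing[:5]}")
    ds = SpotDataset(
        counts=counts,
        gene_ids=gene_ids,
        barcodes=barcodes,
        positions=positions,
        sample_id=samples.loc[barcodes, "sample_id"].to_numpy(),
        slide_id=samples.loc[barcodes, "slide_id"].to_numpy(),
    )
    in_tissue = positions.loc[barcodes, "in_tissue"].to_numpy().astype(bool)
    return ds.subset_spots(in_tissue)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, with real-Visium-scale defaults."""

    reference_dir: str | None = None
    labels_tsv: str | None = None
    spatial_dir: str | None = None
    positions_csv: str | None = None
    samples_tsv: str | None = None
    tf_list: str | None = None

    min_genes: int = 200
    min_umis: int = 1000
    max_mito: float = 0.10
    gene_min_cells: int = 3
    marker_p_max: float = 0.01
    lfc_min: float = 0.1
    pseudo_min: float = 0.0
    min_spot_genes: int = 1000
    min_spot_umis: int = 1000
    gene_min_spots_exclusive: int = 3
    k: int = 6
    fdr_autocorr: float = 0.01
    top_n: int = 500
    min_gene_threshold: int = 15
    module_fdr: float = 0.05
    core_only: bool = True
    subsample_fraction: float = 0.6
    n_reps: int = 100
    consensus_threshold: float = 0.8
    benchmark_top_n: int = 100
    n_perm: int = 1000
    em_max_iter: int = 1000
    em_tol: float = 1e-8
    master_seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 < self.subsample_fraction < 1, "subsample_fraction in (0,1)"),
            (0 <= self.consensus_threshold <= 1, "consensus_threshold in [0,1]"),
            (0 < self.fdr_autocorr < 1, "fdr_autocorr in (0,1)"),
            (0 < self.module_fdr < 1, "module_fdr in (0,1)"),
            (0 <= self.max_mito <= 1, "max_mito in [0,1]"),
            (self.k >= 1, "k >= 1"),
            (self.n_reps >= 1, "n_reps >= 1"),
            (self.n_perm >= 1, "n_perm >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @classmethod
    def synthetic_scale(cls, master_seed: int = 0, **overrides) -> "PipelineConfig":
        """Thresholds and replicate counts sized for the bundled synthetic
        tissues (~400 genes, ~2000 UMIs/spot) rather than full Visium."""
        base = dict(
            min_genes=50,
            min_umis=200,
            min_spot_genes=100,
            min_spot_umis=500,
            n_perm=300,
            n_reps=20,
            master_seed=master_seed,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
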