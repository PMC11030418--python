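"""Synthetic reference and spatial datasets with known ground truth.

The generator emulates the design of a spot-based (Visium-style) tumor
study: a single-cell reference with several tumor and non-tumor cell
states, spot counts drawn as multinomial mixtures of state expression
profiles with spatially structured cell-state fractions, spatially smooth
gene modules expressed only in the tumor component, a smooth confounder
module expressed only in a stromal component, and a replicate layout of
two tissues per slide on two slides ("adjacent section" technical
replicates share region geometry but not reads).

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GroundTruth, SpotDataset

__all__ = [
    "ModuleSpec",
    "SimConfig",
    "default_config",
    "default_region_map",
    "gene_ids",
    "tf_gene_ids",
    "expected_profiles",
    "simulate_reference",
    "plant_module_fields",
    "simulate_tissue",
    "lattice_lag1_autocorr",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted spatial co-expression module.

    component: which mixture component the module modulates ("tumor" or
    "stromal"); genes: indices into the gene universe (>= 15 so the
    detection stage's module-size threshold is exercisable); field_type:
    "patch" (raised-cosine disc, zero outside ``radius``) or "gradient"
    (linear ramp along ``axis``); amplitude: multiplicative strength a,
    rates are scaled by (1 + a * field).
    """

    component: str
    genes: tuple
    field_type: str = "patch"
    amplitude: float = 3.0
    center: tuple = (10.0, 10.0)
    radius: float = 5.5
    axis: str = "col"


@dataclass
class SimConfig:
    n_genes: int = 400
    n_states: int = 4
    state_names: tuple = ("NE", "TumorLB", "Mes", "Endo")
    tumor_state_ids: tuple = (0, 1)
    stromal_state_ids: tuple = (2,)
    markers_per_state: int = 30
    marker_fold: float = 8.0
    grid_rows: int = 20
    grid_cols: int = 20
    region_map: np.ndarray | None = None
    fraction_params: dict = field(default_factory=dict)
    depth_mean: float = 2000.0
    depth_dispersion: float = 0.3
    module_specs: list = field(default_factory=list)
    n_samples: int = 2
    n_slides: int = 2
    cells_per_state: int = 200
    cell_depth_mean: float = 3000.0
    cell_depth_dispersion: float = 0.3
    tf_genes: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if set(self.tumor_state_ids) & set(self.stromal_state_ids):
            raise ValueError("tumor_state_ids and stromal_state_ids overlap")
        if self.markers_per_state * self.n_states > self.n_genes:
            raise ValueError("not enough genes for the requested marker blocks")
        for name, val in [
            ("marker_fold", self.marker_fold),
            ("depth_mean", self.depth_mean),
            ("depth_dispersion", self.depth_dispersion),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        marker_blocks = [set(self.marker_gene_indices(k)) for k in range(self.n_states)]
        for i in range(self.n_states):
            for j in range(i + 1, self.n_states):
                if marker_blocks[i] & marker_blocks[j]:
                    raise ValueError("marker sets must be state-exclusive")
        all_markers = set().union(*marker_blocks) if marker_blocks else set()
        seen: set = set()
        for spec in self.module_specs:
            gset = set(spec.genes)
            if len(gset) < 15:
                raise ValueError("every module gene set needs >= 15 genes")
            if spec.amplitude < 0:
                raise ValueError("module amplitude must be >= 0")
            if spec.component not in ("tumor", "stromal"):
                raise ValueError(f"unknown module component {spec.component!r}")
            if gset & all_markers or gset & seen:
                raise ValueError("module gene sets must not overlap markers or each other")
            if max(gset) >= self.n_genes:
                raise ValueError("module gene index out of range")
            seen |= gset
        if self.region_map is not None:
            rm = np.asarray(self.region_map)
            if rm.shape != (self.grid_rows, self.grid_cols):
                raise ValueError(
                    f"region_map shape {rm.shape} != lattice "
                    f"({self.grid_rows}, {self.grid_cols})"
                )
            missing = set(rm.ravel()) - set(self.fraction_params)
            if missing:
                raise ValueError(f"regions without fraction_params: {sorted(missing)}")
            for alpha in self.fraction_params.values():
                a = np.asarray(alpha, dtype=float)
                if a.shape != (self.n_states,) or np.any(a <= 0):
                    raise ValueError("fraction_params must be positive, one per state")

    def marker_gene_indices(self, state: int) -> np.ndarray:
        lo = state * self.markers_per_state
        return np.arange(lo, lo + self.markers_per_state)

    @property
    def n_spots_per_tissue(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def coarse_labels(self) -> dict:
        return {
            name: ("tumor" if k in self.tumor_state_ids else name)
            for k, name in enumerate(self.state_names)
        }


def gene_ids(config: SimConfig) -> list:
    return [f"g{i:04d}" for i in range(config.n_genes)]


def tf_gene_ids(config: SimConfig) -> list:
    """Transcription-factor universe: module genes plus designated noise TFs."""
    gid = gene_ids(config)
    idx = sorted({g for spec in config.module_specs for g in spec.genes} | set(config.tf_genes))
    return [gid[i] for i in idx]


STROMA_POCKET_CENTERS = (
    (3, 3), (3, 16), (9, 7), (9, 13), (16, 3),
    (16, 16), (12, 18), (18, 10), (6, 10), (13, 0),
)


def default_region_map(rows: int = 20, cols: int = 20) -> np.ndarray:
    """NE-rich left half, nonNE right half, small stroma-enriched pockets.

    Stromal content is modelled as spot-scale infiltration noise plus small
    coherent pockets (fibrovascular tracks), not as large stroma-only
    regions: the smooth stromal structure under study is the planted
    confounder module, while gross tumor density varies only at spot scale.
    """
    rm = np.empty((rows, cols), dtype=object)
    rm[:, : cols // 2] = "NE"
    rm[:, cols // 2:] = "nonNE"
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for a, b in STROMA_POCKET_CENTERS:
        rm[np.hypot(rr - a * rows / 20.0, cc - b * cols / 20.0) < 0.09 * rows] = "stroma_pocket"
    return rm


def default_config(**overrides) -> SimConfig:
    """The canonical study conditions for the synthetic benchmark.

    Four cell states (two tumor: NE and TumorLB; stromal Mes; Endo), 30
    state-exclusive markers each at 8-fold elevation, three 20-gene
    tumor-component modules planted as raised-cosine patches, one 20-gene
    stromal confounder patch, 40 extra noise transcription factors, a
    20x20 spot lattice per tissue at ~2000 UMIs/spot, two tissues per
    slide on two slides.
    """
    tumor_modules = [
        ModuleSpec("tumor", tuple(range(120, 140)), "patch", 3.0, (5.0, 5.0), 5.5),
        ModuleSpec("tumor", tuple(range(140, 160)), "patch", 3.0, (5.0, 14.0), 5.5),
        ModuleSpec("tumor", tuple(range(160, 180)), "patch", 3.0, (14.0, 5.0), 5.5),
    ]
    confounder = ModuleSpec("stromal", tuple(range(180, 200)), "patch", 3.0, (14.0, 14.0), 5.5)
    cfg = SimConfig(
        region_map=default_region_map(20, 20),
        fraction_params={
            "NE": np.array([10.0, 1.5, 3.0, 1.5]),
            "nonNE": np.array([1.5, 10.0, 3.0, 1.5]),
            "stroma_pocket": np.array([4.0, 4.0, 7.0, 2.0]),
        },
        module_specs=tumor_modules + [confounder],
        tf_genes=tuple(range(200, 240)),
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def _gene_weights(config: SimConfig, seed: int) -> np.ndarray:
    """State x gene expression weights implied by (config, seed).

    A shared gamma-distributed baseline per gene; each state's markers are
    elevated marker_fold-fold in that state only; tumor-component module
    genes are elevated in every tumor state (so they behave like shared
    tumor markers), stromal-module genes in every stromal state.
    """
    rng = np.random.default_rng([int(seed), 7001])
    base = rng.gamma(shape=2.0, scale=1.0, size=config.n_genes) + 0.05
    W = np.tile(base, (config.n_states, 1))
    for k in range(config.n_states):
        W[k, config.marker_gene_indices(k)] *= config.marker_fold
    for spec in config.module_specs:
        states = config.tumor_state_ids if spec.component == "tumor" else config.stromal_state_ids
        for k in states:
            W[k, list(spec.genes)] *= config.marker_fold
    return W


def expected_profiles(config: SimConfig, seed: int | None = None) -> np.ndarray:
    """True per-state gene probability vectors (rows sum to 1)."""
    seed = config.seed if seed is None else seed
    W = _gene_weights(config, seed)
    return W / W.sum(axis=1, keepdims=True)


def _lognormal_depths(rng, mean: float, dispersion: float, n: int) -> np.ndarray:
    mu = np.log(mean) - 0.5 * dispersion**2
    return np.maximum(1, np.round(rng.lognormal(mu, dispersion, size=n))).astype(np.int64)


def simulate_reference(config: SimConfig, seed: int | None = None):
    """Draw the single-cell reference: counts, fine and coarse labels.

    Returns (cell x gene integer counts, fine label array, coarse label
    array). Coarse labels collapse every tumor state to "tumor".
    """
    config.validate()
    seed = config.seed if seed is None else seed
    phi = expected_profiles(config, seed)
    rng = np.random.default_rng([int(seed), 7002])
    blocks, fine, coarse = [], [], []
    coarse_map = config.coarse_labels
    for k, name in enumerate(config.state_names):
        depths = _lognormal_depths(
            rng, config.cell_depth_mean, config.cell_depth_dispersion, config.cells_per_state
        )
        blocks.append(rng.multinomial(depths, phi[k]))
        fine += [name] * config.cells_per_state
        coarse += [coarse_map[name]] * config.cells_per_state
    counts = np.vstack(blocks)
    return counts, np.array(fine), np.array(coarse)


def plant_module_fields(lattice, module_specs, seed: int | None = None) -> np.ndarray:
    """Spatial field value per spot for each module, flattened row-major.

    Fields are deterministic functions of the lattice; ``seed`` is accepted
    for interface symmetry. "patch" is a raised cosine inside ``radius``
    (strictly positive inside, exactly zero outside); "gradient" ramps
    linearly from 0 to 1 along the chosen axis.
    """
    rows, cols = lattice
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    fields = np.zeros((rows * cols, len(module_specs)))
    for m, spec in enumerate(module_specs):
        if spec.field_type == "patch":
            d = np.hypot(rr - spec.center[0], cc - spec.center[1])
            f = np.where(d < spec.radius, 0.5 * (1.0 + np.cos(np.pi * d / spec.radius)), 0.0)
        elif spec.field_type == "gradient":
            coord = rr if spec.axis == "row" else cc
            f = coord / max(coord.max(), 1)
        else:
            raise ValueError(f"unknown field type {spec.field_type!r}")
        fields[:, m] = f.ravel()
    return fields


def _component_modulation(config: SimConfig, fields: np.ndarray):
    """Per-spot multiplicative rate modulation matrices for each component."""
    S = fields.shape[0]
    mod = {"tumor": np.ones((S, config.n_genes)), "stromal": np.ones((S, config.n_genes))}
    for m, spec in enumerate(config.module_specs):
        mod[spec.component][:, list(spec.genes)] *= (
            1.0 + spec.amplitude * fields[:, m]
        )[:, None]
    return mod


def simulate_tissue(config: SimConfig, profiles, seed: int | None = None):
    """Draw the spatial dataset: multinomial spot counts over the lattice.

    ``profiles`` is a state x gene matrix of probability vectors (or any
    object with a ``profile`` attribute holding one). Tissues are laid out
    as n_samples x n_slides; replicate sections of the same sample share
    region geometry and module fields but redraw fractions and counts.

    Returns (SpotDataset, GroundTruth).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    phi = np.asarray(getattr(profiles, "profile", profiles), dtype=float)
    if phi.shape != (config.n_states, config.n_genes):
        raise ValueError(f"profiles shape {phi.shape} != states x genes")
    if not np.allclose(phi.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("profile rows must be probability vectors")

    region_map = (
        np.asarray(config.region_map)
        if config.region_map is not None
        else default_region_map(config.grid_rows, config.grid_cols)
    )
    if region_map.shape != (config.grid_rows, config.grid_cols):
        raise ValueError(
            f"region_map shape {region_map.shape} != lattice "
            f"({config.grid_rows}, {config.grid_cols})"
        )
    regions = region_map.ravel()
    fields = plant_module_fields((config.grid_rows, config.grid_cols), config.module_specs)
    mod = _component_modulation(config, fields)
    component_of = {
        k: ("tumor" if k in config.tumor_state_ids
            else "stromal" if k in config.stromal_state_ids
            else None)
        for k in range(config.n_states)
    }

    S = config.n_spots_per_tissue
    rr, cc = np.meshgrid(
        np.arange(config.grid_rows), np.arange(config.grid_cols), indexing="ij"
    )
    rr, cc = rr.ravel(), cc.ravel()

    all_counts, all_theta, barcodes, samples, slides = [], [], [], [], []
    pos_rows = []
    t = 0
    for sample in range(config.n_samples):
        for slide in range(config.n_slides):
            rng = np.random.default_rng([int(seed), 7100 + t])
            theta = np.zeros((S, config.n_states))
            for region, alpha in config.fraction_params.items():
                m = regions == region
                if m.any():
                    theta[m] = rng.dirichlet(np.asarray(alpha, float), size=int(m.sum()))
            # per-spot mixed gene probabilities with module modulation
            p = np.zeros((S, config.n_genes))
            for k in range(config.n_states):
                comp = component_of[k]
                rate = phi[k][None, :] * (mod[comp] if comp else 1.0)
                rate = rate / rate.sum(axis=1, keepdims=True)
                p += theta[:, [k]] * rate
            depths = _lognormal_depths(rng, config.depth_mean, config.depth_dispersion, S)
            counts = rng.multinomial(depths, p / p.sum(axis=1, keepdims=True))
            all_counts.append(counts)
            all_theta.append(theta)
            sid, lid = f"mouse{sample + 1}", f"slide{slide + 1}"
            for i in range(S):
                bc = f"{sid}-{lid}-{rr[i]:02d}x{cc[i]:02d}"
                barcodes.append(bc)
                pos_rows.append((bc, 1, int(rr[i]), int(cc[i]), int(100 * rr[i]), int(100 * cc[i])))
            samples += [sid] * S
            slides += [lid] * S
            t += 1

    positions = pd.DataFrame(
        pos_rows,
        columns=["barcode", "in_tissue", "array_row", "array_col",
                 "pxl_row_in_fullres", "pxl_col_in_fullres"],
    ).set_index("barcode")
    gid = gene_ids(config)
    dataset = SpotDataset(
        counts=np.vstack(all_counts),
        gene_ids=gid,
        barcodes=barcodes,
        positions=positions,
        sample_id=np.array(samples),
        slide_id=np.array(slides),
    )
    n_tissues = config.n_samples * config.n_slides
    truth = GroundTruth(
        true_fractions=np.vstack(all_theta),
        region_label=np.tile(regions, n_tissues),
        planted_modules=[
            (spec.component, [gid[g] for g in spec.genes]) for spec in config.module_specs
        ],
        module_field_values=np.tile(fields, (n_tissues, 1)),
        state_names=list(config.state_names),
    )
    return dataset, truth


def lattice_lag1_autocorr(field2d: np.ndarray) -> float:
    """Moran-style lag-1 autocorrelation on a rook-adjacency lattice.

    I = (n / W) * sum_ij w_ij (x_i - m)(x_j - m) / sum_i (x_i - m)^2 with
    w_ij = 1 for horizontally/vertically adjacent lattice cells.
    """
    x = np.asarray(field2d, dtype=float)
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        return 0.0
    cross = 2.0 * ((z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum())
    n_edges = 2 * (x.shape[0] - 1) * x.shape[1] + 2 * x.shape[0] * (x.shape[1] - 1)
    return float(x.size / n_edges * cross / denom)
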