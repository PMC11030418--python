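# Methods

## Scope and design

`spotmodules` composes five stages behind one library surface: reference
preparation, spot deconvolution, spatial module detection, subsampling
consensus, and benchmarking, plus a synthetic-data generator that plants
known ground truth through all of them. The package is organized as an
analysis project: the numbered scripts under `analysis/` are thin drivers
over `src/spotmodules/`, where all computation lives.

## Synthetic study conditions

The generator emulates a spot-based tumor study with technical-replicate
sections. Defaults (in `simulate.default_config`):

- **Reference**: 4 cell states — NE and TumorLB (tumor), Mes (stromal),
  Endo — with 200 cells/state at ~3000 UMIs/cell. Gene baseline weights
  are gamma(2, 1) + 0.05 shared across states; each state has 30
  exclusive markers elevated 8-fold. 8-fold marker contrast is typical of
  the top discriminative genes in single-cell references; 30 markers per
  state keeps the deconvolution universe in the few-hundred-gene range of
  a marker-restricted panel.
- **Lattice**: a 20x20 square grid per tissue (unit spacing on
  `array_row`/`array_col`), two tissues per slide x two slides. A square
  grid rather than hex-offset geometry: the neighbour graph is kNN-based,
  so k = 6 exercises the identical code path.
- **Fractions**: per-spot Dirichlet draws with region-specific
  concentrations — NE-rich left half (10, 1.5, 3, 1.5), TumorLB-rich
  right half (mirrored), and ten small stroma-enriched pockets (radius
  1.8 spots, concentration (4, 4, 7, 2)). Stroma is deliberately modelled
  as spot-scale infiltration noise plus small coherent pockets
  (fibrovascular-track scale), not as large stroma-only regions: the
  smooth stromal structure whose confounding effect the benchmark
  measures is the planted confounder *module*, while gross tumor density
  varies only at spot scale. With one large stroma-rich region, raw-count
  autocorrelation of tumor markers would legitimately reflect tumor
  density and the deconvolved-vs-raw comparison would measure geometry,
  not contamination removal.
- **Depth**: lognormal per-spot totals (mean 2000, sigma 0.3), then
  multinomial allocation — the simplest law giving realistic
  overdispersion in totals while keeping the multinomial generative form
  the deconvolution assumes.
- **Planted modules**: three 20-gene tumor-component modules as
  raised-cosine patches (radius 5.5, amplitude 3), one 20-gene stromal
  confounder patch. Module genes are elevated 8-fold in *all* states of
  their component (so tumor-module genes behave like shared tumor markers
  and survive marker selection, whose tumor-vs-tumor comparisons are
  skipped). Module action is multiplicative on component-specific rates,
  renormalized per state — the mixture stays exactly multinomial.
  Amplitude 3 (up to 4-fold local elevation) is a strong but plausible
  spatial program.
- **Replicates**: adjacent sections share region geometry and module
  fields but redraw fractions and counts independently; no section
  registration is modelled.
- **TF list**: the 80 module/confounder genes plus 40 noise TFs.

What the generator does *not* emulate: ambient RNA, doublets, hex
geometry, segmentation artifacts, probe-set chemistry, or spatial
correlation in the Dirichlet noise itself. Passing tests therefore show
that the statistics behave correctly under the stated mixture model, not
that they are robust to every artifact of real slides.

## Reference preparation

Cell QC keeps cells with >= 200 detected genes, >= 1000 UMIs and
mitochondrial fraction <= 0.10; gene QC drops genes detected in < 3 cells
and any gene in the configured drop sets (mitochondrial, ribosomal).
Threshold boundaries are implemented strictly as worded (a cell at
exactly 1000 UMIs or exactly 10% mito is retained). Normalization is
log2(counts-per-10k + 1).

Marker selection runs pairwise Welch t-tests on normalized expression
between every pair of fine states. For each non-tumor state the per-gene
p-values and log2 fold changes are summarized over all other states; for
tumor states only over non-tumor states. A gene is a marker iff
max p < 0.01 AND min log2FC > 0.1. The fold change is computed on
back-transformed (linear cp10k) means as log2((mean_A + 1)/(mean_B + 1)),
matching the package's bulk-contrast formula; the Welch variant is used
because pairwise marker tests in the single-cell ecosystem default to
unequal-variance t-tests. Profiles are per-state mean raw counts over the
marker union, floored at `pseudo_min` (default 0 — zeros stay exact
zeros, maximizing reference contrast) and normalized to probability
vectors.

## Deconvolution

Each spot is an independent multinomial mixture; EM from a uniform start
maximizes the concave per-spot log-likelihood (tolerance 1e-8 relative,
max 1000 iterations; both conservative). Profiles are floored at 1e-12
only inside the likelihood so that a positive count on a zero-probability
gene cannot produce -inf. Responsibility allocation conserves counts
exactly at every iteration (`sum_k z = c`). The tumor count matrix is the
ceiling of the tumor-state allocation; values integral up to 1e-9 are
snapped first so that boundary cases (pure-tumor spots) conserve totals
exactly. This EM is a deliberately simple back-end exposing the
(theta, Z) contract; no claim is made that it reproduces a full Bayesian
deconvolution posterior beyond the synthetic-recovery properties the
tests measure (fraction r >= 0.9 under well-separated profiles).

## Spatial statistics

Residuals: `x = (c - d p) / sqrt(d p (1 + d p / alpha))` with pooled gene
frequency `p`, spot depth `d`, and per-gene dispersion `alpha` by method
of moments (Poisson limit when no excess variance). The autocorrelation
statistic sums self-plus-neighbour cross-products over the directed kNN
graph, divided by (k+1); the pairwise local correlation symmetrizes the
same cross-product between two genes. `C_gg = H_g` holds algebraically
and is enforced bit-exactly by writing the autocorrelation values onto
the local-correlation diagonal (floating-point reduction order would
otherwise differ in the last ulp).

The null permutes residuals within each tissue — exact under
exchangeability, validated against exhaustive enumeration on a 5-spot
toy. Z-scores use the permutation moments; the p-values fed to
Benjamini-Hochberg are the one-sided normal tail of Z, because the
empirical permutation p has granularity 1/(n_perm+1) and cannot resolve
FDR < 0.01 across hundreds of genes at practical permutation counts. The
empirical permutation p is reported alongside (`p_perm`). Tissues with
fewer than 20 spots are rejected by default (`min_tissue_spots`), since
their permutation nulls are too coarse; toy analyses may lower the bound
explicitly.

Gene selection applies the FDR < 0.01 filter first, then intersects with
the TF list, then keeps the top 500 by Z (ties broken by gene id).
Module detection merges genes/modules bottom-up by the highest pairwise Z
with average linkage (Lance-Williams update), stopping when the best
remaining linkage falls below the weakest BH-significant pairwise Z at
FDR 0.05; with `core_only`, final clusters under 15 genes dissolve to
unassigned. Merge ties break lexicographically on the smallest gene id.
Module scores are per-gene z-scored normalized expression averaged over
the module, then one round of neighbour averaging (self included);
constant genes (sd at floating-point noise) score zero.

## Consensus robustness

Each replicate redraws floor(0.6 x total) reads per tissue multinomially
with probabilities proportional to the observed spot x gene counts (zero
cells stay zero; per-tissue totals exact), re-standardizes residuals,
recomputes local correlation over the *fixed* full-data gene selection,
and re-detects modules — gene selection is not redone, keeping replicates
comparable. A pair co-occurs in a replicate only if both genes are
assigned to the same module there; a gene's consensus is the mean
co-occurrence with its full-data module partners (full-data partners, not
per-replicate partners — the stabler of the two readings), and
representatives require consensus >= 0.8 (inclusive). Replicate r uses
seed master_seed + 1 + r.

## Benchmarking

Marker sets per coarse cell type take the genes passing the marker
thresholds ranked by fold change, truncated to the top 100 (all genes
with a warning when fewer pass — the synthetic reference yields 50–155
markers per type). One-sided paired t-tests compare autocorrelation Z
between the deconvolved-tumor and raw workflows: alternative "greater"
for tumor markers, "less" for non-tumor markers; the same machinery tests
|local-correlation Z| over the three pair categories (tumor–tumor:
greater; tumor–non-tumor and non-tumor–non-tumor: less). The tests are
implemented as standard one-sided alternatives in the expected direction,
with the direction recorded in the report. The bulk signature contrast
computes per-gene log2((mean_pos + 1)/(mean_neg + 1)) between two sample
groups with a two-sided rank-sum test per gene across samples (exact for
<= 10 samples/group, normal approximation otherwise) and per gene set on
per-sample mean log expression.

## Problem sizes and numerical choices

The bundled study runs at 400 genes, 400-1600 spots, 200-300
permutations, and 20 subsampling replicates — sizes chosen so the full
analysis and test suite complete in minutes while every statistic retains
comfortable resolution (the detection Z-scores of planted modules exceed
20). The spot filters default to the real-Visium scale (1000 genes / 1000
UMIs per spot); `PipelineConfig.synthetic_scale` substitutes thresholds
matched to the synthetic depth (100 genes / 500 UMIs), since a 400-gene
panel cannot contain 1000 detected genes. Degenerate inputs are handled
explicitly: zero-total spots keep uniform fractions, zero-variance paired
differences report p in {0, 1} by sign with a warning, empty benchmark
categories are flagged and skipped, and an empty full-data module run
yields an empty consensus with a warning.

## Known limitations

- The EM back-end has no spatial prior, no cross-spot pooling, and no
  batch-effect correction between reference and spots.
- The permutation null assumes within-tissue exchangeability of
  residuals; strong global depth gradients would violate it.
- Average linkage on Z matrices has no uniqueness guarantee under heavy
  ties; determinism is provided by explicit tie-breaking, not by the
  statistic itself.
- Consensus scores are computed against full-data partners only, so a
  module that is wrong at full data cannot be rescued by subsampling —
  only pruned.
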