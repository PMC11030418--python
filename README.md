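# spotmodules

Cell-type-specific spatial gene-module detection for spot-based spatial
transcriptomics (Visium-style), built around deconvolution into per-state
expression.

## The problem

A spatial transcriptomics spot covers several cells, so its counts mix
tumor and non-tumor transcripts. Spatially coherent gene modules detected
directly on raw spot counts therefore confound tumor programs with the
spatial organization of the microenvironment: a smooth stromal expression
program looks exactly like a tumor-intrinsic module. `spotmodules`
implements a workflow that (1) deconvolves each spot into cell-state
fractions and state-specific expected counts, (2) detects spatially
coherent transcription-factor modules on the *tumor-specific* counts with
permutation-calibrated graph statistics, (3) scores module robustness by
multinomial read subsampling, and (4) benchmarks the deconvolved workflow
against the naive raw-count workflow. A synthetic-data generator with
planted ground truth (fractions, modules, confounders, replicate layout)
exercises every stage.

## The model

**Deconvolution.** Spot counts `c_s` follow a multinomial mixture over
reference state profiles `phi_k` (per-state mean expression over a
marker-gene universe, floored at `pseudo.min = 0` and normalized):
`p_g(theta) = sum_k theta_k phi_kg`. Per-spot fractions `theta` are the
maximum-likelihood mixture weights (EM; the per-spot log-likelihood is
concave). Reads are allocated to states by posterior responsibility,
`z_skg = c_sg * theta_k phi_kg / sum_k' theta_k' phi_k'g`, and the
tumor-specific count matrix is `ceil(sum_{k in tumor} z_skg)`. Marker
genes come from pairwise Welch t-tests (max p < 0.01 AND min log2FC >
0.1 over comparison states; tumor-vs-tumor comparisons are skipped so
shared tumor genes survive).

**Spatial statistics.** On a directed k-nearest-neighbour graph (k = 6,
self included, uniform weights, no edges across tissue sections),
depth-standardized NB residuals `x` give the autocorrelation statistic
`H_g = sum_i sum_{j in N(i) u {i}} x_ig x_jg / (k+1)` and the pairwise
local correlation
`C_gh = sum_i sum_j (x_ig x_jh + x_ih x_jg) / (2(k+1))`, with
`C_gg = H_g` identically. Both are calibrated by within-tissue
permutation; modules are grown by average-linkage merging of the pairwise
Z matrix until no pair is significant at BH-FDR 0.05, keeping clusters of
at least 15 genes.

**Consensus.** 60% of each tissue's reads are redrawn multinomially,
local correlation and module detection are re-run per replicate, and each
gene is scored by how often it stays co-moduled with its full-data
partners; representatives require consensus >= 0.8.

## Worked example

The numbered scripts under `analysis/` run the whole study on the bundled
synthetic conditions (4 cell states of which 2 tumor, 30 markers/state at
8-fold, four 20x20 tissues at ~2000 UMIs/spot, three planted 20-gene
tumor modules plus one 20-gene stromal confounder):

```sh
python analysis/01_simulate.py
python analysis/02_prepare_reference.py
python analysis/03_deconvolve.py
python analysis/04_detect_modules.py
python analysis/05_consensus.py
python analysis/06_benchmark.py
```

Output (abridged) from a run at seed 1:

```
fraction recovery r per state: {'Endo': 0.971, 'Mes': 0.982, 'NE': 0.995, 'TumorLB': 0.993}
mouse1 slide concordance: state-level r 0.999, region-level r 0.998
4 modules detected {1: 20, 2: 20, 3: 20, 4: 19}; ARI vs planted tumor modules = 1.000
60/79 module genes selected at consensus >= 0.8 (20 subsampling replicates)
  module 4: 0/19 representative genes
autocorr tumor markers (n=100): mean dZ=+1.84, one-sided p=3.50e-15 (greater)
autocorr nontumor markers (n=150): mean dZ=-2.61, one-sided p=1.57e-12 (less)
|Z| tumor-tumor (4950 pairs): mean d|Z|=+0.98, p=2.83e-195 (greater)
|Z| nontumor-nontumor (11175 pairs): mean d|Z|=-2.11, p=0.00e+00 (less)
```

Reading: deconvolution recovers the planted fractions (r >= 0.97 per
state) and the three planted tumor modules exactly (ARI 1.0). A fourth,
spurious module assembles at full data but is eliminated by the consensus
filter (0/19 representative genes, against 20/20 for each planted
module). Deconvolution raises the spatial signal of tumor markers (mean
dZ +1.84) while suppressing non-tumor and confounder signal (mean dZ
-2.61), in the expected directions for all three marker-pair categories.

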