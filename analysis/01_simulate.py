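"""Generate the synthetic study dataset and write it in exchange formats.

Produces the default study conditions: a 4-state reference (two tumor
states NE / TumorLB, stromal Mes, endothelial Endo; 30 exclusive markers
per state at 8-fold), and spatial data for two mice on two slides (four
20x20 tissues, ~2000 UMIs/spot) with three planted tumor modules, one
stromal confounder module, and stroma organized as infiltration noise
plus small coherent pockets.

Outputs under results/data/: 10x-style MTX triplets for the reference and
spots, Visium positions CSV, samples TSV, TF list, and ground truth.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from spotmodules import io as smio
from spotmodules import simulate as sim

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sim.default_config()

    ref_counts, fine, coarse = sim.simulate_reference(cfg, SEED)
    gids = sim.gene_ids(cfg)
    cells = [f"cell{i:05d}" for i in range(ref_counts.shape[0])]
    smio.write_counts_mtx(OUT / "reference", ref_counts, gids, cells)
    pd.DataFrame({"barcode": cells, "fine_label": fine, "coarse_label": coarse}
                 ).to_csv(OUT / "reference_labels.tsv", sep="\t", index=False)

    spots, truth = sim.simulate_tissue(cfg, sim.expected_profiles(cfg, SEED), SEED)
    smio.write_counts_mtx(OUT / "spatial", spots.counts, gids, spots.barcodes)
    smio.write_positions(OUT / "tissue_positions.csv", spots.positions)
    smio.write_samples(OUT / "samples.tsv", spots.barcodes,
                       spots.sample_id, spots.slide_id)
    smio.write_tf_list(OUT / "tf_list.txt", sim.tf_gene_ids(cfg))

    pd.DataFrame(truth.true_fractions, index=spots.barcodes,
                 columns=truth.state_names).to_csv(
        OUT / "true_fractions.tsv", sep="\t")
    pd.DataFrame({"barcode": spots.barcodes, "region": truth.region_label}
                 ).to_csv(OUT / "regions.tsv", sep="\t", index=False)
    (OUT / "ground_truth.json").write_text(json.dumps({
        "seed": SEED,
        "planted_modules": [
            {"component": c, "genes": g} for c, g in truth.planted_modules],
        "tumor_states": [cfg.state_names[k] for k in cfg.tumor_state_ids],
    }, indent=2))

    depth = spots.counts.sum(axis=1)
    print(f"reference: {ref_counts.shape[0]} cells x {len(gids)} genes, "
          f"{len(set(fine))} states")
    print(f"spatial: {spots.n_spots} spots over "
          f"{len(set(spots.tissue_ids))} tissues, "
          f"median depth {np.median(depth):.0f} UMIs/spot")
    print(f"planted: {sum(c == 'tumor' for c, _ in truth.planted_modules)} tumor "
          f"modules + {sum(c == 'stromal' for c, _ in truth.planted_modules)} "
          f"stromal confounder, 20 genes each")


if __name__ == "__main__":
    main()
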