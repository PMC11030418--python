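"""Deconvolve the spatial data and score recovery + replicate concordance.

Fits per-spot multinomial-mixture fractions against the reference profile,
extracts the tumor-specific count matrix (posterior allocation summed over
tumor states, rounded up), scores fraction recovery against the simulation
ground truth, and computes region-averaged concordance between the two
technical-replicate slides of each mouse.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from spotmodules import deconvolution as dc
from spotmodules import io as smio
from spotmodules.reference import ReferenceProfile

DATA = Path("results/data")
REF = Path("results/reference")
OUT = Path("results/deconvolution")


def load_reference() -> ReferenceProfile:
    profile = pd.read_csv(REF / "profile.tsv", sep="\t", index_col=0)
    meta = json.loads((REF / "reference_meta.json").read_text())
    return ReferenceProfile(
        profile=profile.to_numpy(),
        gene_ids=list(profile.columns),
        fine_labels=meta["fine_labels"],
        coarse_of=meta["coarse_of"],
        marker_genes=meta["marker_genes"],
        pseudo_min=meta["pseudo_min"],
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spots = smio.load_spot_dataset(DATA / "spatial", DATA / "tissue_positions.csv",
                                   DATA / "samples.tsv")
    ref = load_reference()
    truth_frac = pd.read_csv(DATA / "true_fractions.tsv", sep="\t", index_col=0)
    regions = pd.read_csv(DATA / "regions.tsv", sep="\t").set_index("barcode")
    gt = json.loads((DATA / "ground_truth.json").read_text())
    tumor_states = gt["tumor_states"]

    spots_f = dc.filter_spots_and_genes(spots, min_spot_genes=100, min_spot_umis=500)
    print(f"spots {spots.n_spots} -> {spots_f.n_spots}, "
          f"genes -> {spots_f.n_genes} (deconvolved over {len(ref.gene_ids)})")
    res = dc.deconvolve(spots_f, ref)
    print(f"EM converged in {res.n_iter} iterations")

    theta = pd.DataFrame(res.theta, index=spots_f.barcodes, columns=res.state_names)
    theta.to_csv(OUT / "theta.tsv", sep="\t")
    tum = dc.tumor_counts(res, tumor_states)
    smio.write_counts_mtx(OUT / "tumor_counts", tum, res.gene_ids, spots_f.barcodes)
    pd.DataFrame({"tumor_fraction": dc.celltype_fraction_map(res, tumor_states)},
                 index=spots_f.barcodes).to_csv(OUT / "tumor_fraction.tsv", sep="\t")

    # recovery against ground truth
    tf = truth_frac.loc[spots_f.barcodes]
    rec = {s: float(stats.pearsonr(tf[s], theta[s])[0]) for s in res.state_names}
    print("fraction recovery r per state:",
          {k: round(v, 3) for k, v in rec.items()})

    # replicate concordance between the two slides of each mouse
    conc = {}
    for mouse in sorted(set(spots_f.sample_id)):
        sel = {s: (spots_f.sample_id == mouse) & (spots_f.slide_id == s)
               for s in sorted(set(spots_f.slide_id))}
        (sa, ma), (sb, mb) = sorted(sel.items())
        rep = dc.replicate_concordance(
            res.theta[ma], res.theta[mb],
            regions.loc[np.array(spots_f.barcodes)[ma], "region"],
            regions.loc[np.array(spots_f.barcodes)[mb], "region"],
            res.state_names)
        conc[mouse] = {"per_state_r": rep["per_state_r"],
                       "per_region_r": rep["per_region_r"]}
        print(f"{mouse} slide concordance: "
              f"state-level r {np.mean(list(rep['per_state_r'].values())):.3f}, "
              f"region-level r {np.mean(list(rep['per_region_r'].values())):.3f}")
    (OUT / "recovery.json").write_text(json.dumps(
        {"fraction_recovery_r": rec, "replicate_concordance": conc}, indent=2))


if __name__ == "__main__":
    main()
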