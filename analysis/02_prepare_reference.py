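"""Reference QC, marker selection and per-state profiles.

Reads the simulated single-cell reference from results/data/, applies the
cell/gene quality filters (scaled to the synthetic depth), selects
deconvolution markers by pairwise Welch t-tests (max p < 0.01 AND min
log2FC > 0.1, tumor-vs-tumor comparisons skipped) and writes the
normalized per-state profile over the marker union.
"""

import json
from pathlib import Path

import pandas as pd

from spotmodules import io as smio
from spotmodules import reference as rp

DATA = Path("results/data")
OUT = Path("results/reference")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, gids, cells = smio.read_counts_mtx(DATA / "reference")
    labels = pd.read_csv(DATA / "reference_labels.tsv", sep="\t").set_index("barcode")
    fine = labels.loc[cells, "fine_label"].to_numpy()
    coarse_of = dict(zip(labels["fine_label"], labels["coarse_label"]))

    n0 = counts.shape[0]
    counts, keep = rp.filter_reference_cells(counts, None, min_genes=50, min_umis=200)
    fine = fine[keep]
    counts, gids, _ = rp.filter_reference_genes(counts, gids, min_cells=3)
    print(f"cells {n0} -> {counts.shape[0]}, genes -> {len(gids)}")

    norm = rp.normalize_log2_cp10k(counts)
    stats_df, markers = rp.select_markers(norm, gids, fine, coarse_of)
    ref = rp.build_reference(counts, gids, fine, coarse_of, markers, pseudo_min=0.0)

    stats_df.to_csv(OUT / "marker_stats.tsv", sep="\t")
    pd.DataFrame(ref.profile, index=ref.fine_labels, columns=ref.gene_ids
                 ).to_csv(OUT / "profile.tsv", sep="\t")
    (OUT / "reference_meta.json").write_text(json.dumps({
        "fine_labels": ref.fine_labels,
        "coarse_of": ref.coarse_of,
        "marker_genes": ref.marker_genes,
        "pseudo_min": ref.pseudo_min,
    }, indent=2))

    for c, gs in sorted(markers.items()):
        print(f"  markers[{c}]: {len(gs)} genes")
    print(f"deconvolution universe: {len(ref.gene_ids)} genes")


if __name__ == "__main__":
    main()
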