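"""Reference QC filters, normalization, marker selection, profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spotmodules import reference as rp
from spotmodules import simulate as sim


class TestCellFilter:
    def test_boundary_cells(self):
        """199 detected genes -> removed; exactly 1000 UMIs and exactly 10%
        mito -> retained (strict-inequality reading of the thresholds)."""
        n_genes = 250
        mito = np.zeros(n_genes, dtype=bool)
        mito[0] = True
        cells = np.zeros((3, n_genes), dtype=int)
        cells[0, :199] = 6  # 199 genes, 1194 UMIs -> fails min_genes
        cells[1, :250] = 4  # 250 genes, 1000 UMIs -> retained
        cells[2, 1:226] = 4  # 225 genes, mito 100/1000 = 0.10 -> retained
        cells[2, 0] = 100
        filtered, keep = rp.filter_reference_cells(cells, mito)
        assert keep.tolist() == [False, True, True]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(50, 300))
        once, keep = rp.filter_reference_cells(counts, None, 100, 500)
        twice, keep2 = rp.filter_reference_cells(once, None, 100, 500)
        assert np.array_equal(once, twice) and keep2.all()

    def test_empty_result_names_filter(self):
        counts = np.ones((4, 50), dtype=int)
        with pytest.raises(ValueError, match="min_genes"):
            rp.filter_reference_cells(counts, None, min_genes=100, min_umis=1)


class TestGeneFilter:
    def test_detection_boundary_and_drop_sets(self):
        counts = np.zeros((10, 4), dtype=int)
        counts[:3, 0] = 1  # exactly 3 cells -> retained
        counts[:2, 1] = 1  # 2 cells -> removed
        counts[:, 2] = 5  # in drop set -> removed despite 10 cells
        gene_ids = ["keep3", "only2", "ribo1", "zero"]
        _, kept, _ = rp.filter_reference_genes(
            counts, gene_ids, min_cells=3, drop_sets={"ribo": {"ribo1"}}
        )
        assert kept == ["keep3"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.3, size=(30, 100))
        ids = [f"g{i}" for i in range(100)]
        c1, ids1, _ = rp.filter_reference_genes(counts, ids)
        c2, ids2, _ = rp.filter_reference_genes(c1, ids1)
        assert ids1 == ids2 and np.array_equal(c1, c2)


class TestNormalization:
    def test_closed_form(self):
        counts = np.zeros((1, 100), dtype=int)
        counts[0, 0] = 10
        counts[0, 1:] = 9990 // 99  # total lands on 10,000 exactly?
        counts[0, 1] += 10000 - counts.sum()
        norm = rp.normalize_log2_cp10k(counts)
        assert counts.sum() == 10000
        assert norm[0, 0] == pytest.approx(np.log2(11.0), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        counts = np.array([[0, 5, 5]])
        assert rp.normalize_log2_cp10k(counts)[0, 0] == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=3, max_size=12).filter(lambda v: sum(v) > 0),
           st.integers(2, 7))
    def test_scale_invariance(self, row, mult):
        a = np.array([row])
        b = a * mult
        assert np.allclose(rp.normalize_log2_cp10k(a), rp.normalize_log2_cp10k(b))

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValueError, match="zero-total"):
            rp.normalize_log2_cp10k(np.zeros((2, 5)))


def _planted_reference(seed=0, n_per=100, fold=10.0):
    """Three states, disjoint 10x markers, for marker-recovery checks."""
    rng = np.random.default_rng(seed)
    n_genes = 60
    base = rng.gamma(2.0, 1.0, n_genes) + 0.1
    labels = np.repeat(["A", "B", "C"], n_per)
    counts = np.empty((3 * n_per, n_genes), dtype=int)
    planted = {"A": range(0, 10), "B": range(10, 20), "C": range(20, 30)}
    for i, s in enumerate(["A", "B", "C"]):
        w = base.copy()
        w[list(planted[s])] *= fold
        p = w / w.sum()
        counts[i * n_per:(i + 1) * n_per] = rng.multinomial(2000, p, size=n_per)
    ids = [f"g{i:03d}" for i in range(n_genes)]
    return counts, ids, labels, planted


class TestMarkerSelection:
    def test_planted_markers_recovered_against_direct_welch(self):
        """All planted markers are found for their own state and agree with
        an independent scipy-based Welch t-test / fold-change computation."""
        counts, ids, labels, planted = _planted_reference()
        norm = rp.normalize_log2_cp10k(counts)
        coarse = {"A": "A", "B": "B", "C": "C"}
        stats_df, markers = rp.select_markers(norm, ids, labels, coarse)
        for s, genes in planted.items():
            expect = {ids[g] for g in genes}
            assert expect <= set(markers[s])
            for other in set("ABC") - {s}:
                assert not expect & set(markers[other])
        # oracle: direct Welch test + lfc for one state pair, one gene
        g = 0  # planted A marker
        a = norm[labels == "A", g]
        b = norm[labels == "B", g]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        lin = lambda x: 2.0**x - 1.0
        lfc = np.log2((lin(a).mean() + 1) / (lin(b).mean() + 1))
        row = stats_df.loc[(ids[g], "A")]
        assert row["max_p"] >= p - 1e-12  # max over pairs dominates single pair
        assert row["min_lfc"] <= lfc + 1e-12

    def test_and_rule_excludes_low_lfc(self):
        """A gene failing min_lfc against a single state is never a marker,
        however small its p-values."""
        counts, ids, labels, _ = _planted_reference()
        norm = rp.normalize_log2_cp10k(counts)
        stats_df, markers = rp.select_markers(
            norm, ids, labels, {"A": "A", "B": "B", "C": "C"}, lfc_min=np.inf
        )
        assert all(len(v) == 0 for v in markers.values())

    def test_tumor_states_skip_tumor_comparisons(self):
        """A gene elevated in both tumor states vs all others becomes a
        marker of BOTH tumor states."""
        rng = np.random.default_rng(3)
        n_per, n_genes = 80, 40
        labels = np.repeat(["T1", "T2", "N1", "N2"], n_per)
        base = np.ones(n_genes)
        counts = np.empty((4 * n_per, n_genes), dtype=int)
        shared = list(range(5))
        for i, s in enumerate(["T1", "T2", "N1", "N2"]):
            w = base.copy()
            if s.startswith("T"):
                w[shared] *= 10
            counts[i * n_per:(i + 1) * n_per] = rng.multinomial(
                1500, w / w.sum(), size=n_per)
        norm = rp.normalize_log2_cp10k(counts)
        coarse = {"T1": "tumor", "T2": "tumor", "N1": "N1", "N2": "N2"}
        stats_df, markers = rp.select_markers(norm, [f"g{i}" for i in range(n_genes)],
                                              labels, coarse)
        for g in shared:
            assert stats_df.loc[(f"g{g}", "T1"), "is_marker"]
            assert stats_df.loc[(f"g{g}", "T2"), "is_marker"]

    def test_relabeling_symmetry(self):
        counts, ids, labels, _ = _planted_reference()
        norm = rp.normalize_log2_cp10k(counts)
        coarse = {"A": "A", "B": "B", "C": "C"}
        _, m1 = rp.select_markers(norm, ids, labels, coarse)
        swap = {"A": "B", "B": "A", "C": "C"}
        labels2 = np.array([swap[s] for s in labels])
        _, m2 = rp.select_markers(norm, ids, labels2, coarse)
        assert m1["A"] == m2["B"] and m1["B"] == m2["A"] and m1["C"] == m2["C"]

    def test_no_signal_yields_under_one_percent(self):
        """marker_fold=1: the AND-rule's false-positive rate keeps selected
        markers below 1% of genes (10 seeds)."""
        rates = []
        for seed in range(10):
            counts, ids, labels, _ = _planted_reference(seed=seed, fold=1.0)
            norm = rp.normalize_log2_cp10k(counts)
            _, markers = rp.select_markers(norm, ids, labels,
                                           {"A": "A", "B": "B", "C": "C"})
            rates.append(sum(len(v) for v in markers.values()) / (3 * len(ids)))
        assert np.mean(rates) < 0.01

    def test_single_cell_state_errors(self):
        norm = rp.normalize_log2_cp10k(np.ones((3, 5), dtype=int))
        with pytest.raises(ValueError, match="fewer than 2"):
            rp.select_markers(norm, list("abcde"),
                              np.array(["A", "A", "B"]), {"A": "A", "B": "B"})


class TestBuildReference:
    def test_mean_floor_and_normalization(self):
        counts = np.array([[2, 0, 4], [4, 0, 0], [1, 3, 1], [1, 5, 1]])
        labels = np.array(["A", "A", "B", "B"])
        markers = {"A": ["g0", "g2"], "B": ["g1"]}
        ref = rp.build_reference(counts, ["g0", "g1", "g2"], labels,
                                 {"A": "A", "B": "B"}, markers, pseudo_min=0.0)
        # state A means over universe [g0, g1, g2] = [3, 0, 2] -> normalized
        a = ref.profile[ref.fine_labels.index("A")]
        assert np.allclose(a, [3 / 5, 0.0, 2 / 5])
        assert a[1] == 0.0  # pseudo_min=0 keeps exact zeros
        assert np.allclose(ref.profile.sum(axis=1), 1.0)

    def test_zero_state_errors(self):
        counts = np.array([[5, 0], [0, 0]])
        with pytest.raises(ValueError, match="zero expression"):
            rp.build_reference(counts, ["g0", "g1"], np.array(["A", "B"]),
                               {"A": "A", "B": "B"}, {"A": ["g0"]})
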