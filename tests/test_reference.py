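import numpy as np
import pandas as pd
import pytest

import sizedeconv as sd
from sizedeconv.datamodel import ValidationError


def _sc(counts, types, batches=None, hierarchy=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return sd.SingleCellDataset(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        cell_type=list(types),
        sample_id=["d1"] * n_cells,
        batch_id=list(batches) if batches else ["b1"] * n_cells,
        hierarchy=hierarchy or {},
    )


class TestBuildSignature:
    def test_arithmetic_mean(self):
        sc = _sc([[2, 4]], ["A", "A"])
        # only one type present: add a second so the signature is usable later
        sc2 = _sc([[2, 4, 6], [0, 0, 9]], ["A", "A", "B"])
        Z = sd.build_signature(sc2)
        assert Z.to_frame().loc["g0", "A"] == 3.0
        assert Z.to_frame().loc["g1", "B"] == 9.0

    def test_hierarchy_pools_fine_types(self):
        sc = _sc(
            [[2, 4, 6, 8]],
            ["Excit", "Inhib", "Astro", "Astro"],
            hierarchy={"Excit": "neuron", "Inhib": "neuron", "Astro": "glial"},
        )
        Z = sd.build_signature(sc)
        assert Z.to_frame().loc["g0", "neuron"] == 3.0  # mean over Excit u Inhib
        assert Z.to_frame().loc["g0", "glial"] == 7.0

    def test_single_cell_per_type_is_that_profile(self):
        sc = _sc([[5, 1], [2, 7]], ["A", "B"])
        Z = sd.build_signature(sc)
        np.testing.assert_array_equal(Z.values, [[5, 1], [2, 7]])

    def test_empty_type_named_in_error(self):
        sc = _sc([[1, 2]], ["A", "B"])
        with pytest.raises(ValidationError, match="C"):
            sd.build_signature(sc, level={"A": "A", "B": "B", "C": "C"})


class TestMeanRatioMarkers:
    @pytest.fixture()
    def means(self):
        return pd.DataFrame(
            {"A": [10.0, 1.0, 6.0], "B": [2.0, 4.0, 0.0], "C": [5.0, 2.0, 0.0]},
            index=["g1", "g2", "g3"],
        )

    def test_ratio_is_target_over_max_offtarget(self, means):
        table = sd.mean_ratio_markers(means, n_per_type=3)
        a = table.for_type("A").set_index("gene_id")
        assert a.loc["g1", "mean_ratio"] == pytest.approx(10 / 5)
        assert a.loc["g2", "mean_ratio"] == pytest.approx(1 / 4)

    def test_exclusive_gene_is_infinite_and_ranks_first(self, means):
        table = sd.mean_ratio_markers(means, n_per_type=3)
        a = table.for_type("A")
        assert a.iloc[0]["gene_id"] == "g3"
        assert np.isinf(a.iloc[0]["mean_ratio"])
        assert list(a["gene_id"]) == ["g3", "g1", "g2"]  # inf, then 2.0, then 0.25

    def test_infinite_tie_broken_by_target_mean_then_id(self):
        means = pd.DataFrame(
            {"A": [3.0, 7.0, 3.0], "B": [0.0, 0.0, 0.0]}, index=["gb", "gc", "ga"]
        )
        table = sd.mean_ratio_markers(means, n_per_type=3)
        assert list(table.for_type("A")["gene_id"]) == ["gc", "ga", "gb"]

    def test_rescaling_counts_leaves_selection_unchanged(self, synth_default):
        sc, _, _ = synth_default
        base = sd.mean_ratio_markers(sc, 10)
        scaled = _rescaled(sc, 7)
        again = sd.mean_ratio_markers(scaled, 10)
        pd.testing.assert_frame_equal(
            base.table.assign(mean_ratio=base.table.mean_ratio.round(9)),
            again.table.assign(mean_ratio=again.table.mean_ratio.round(9)),
        )

    def test_exclusive_gene_always_selected(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3, size=(30, 40))
        types = ["A"] * 20 + ["B"] * 20
        counts[4, :20] = 9  # expressed only in A
        counts[4, 20:] = 0
        sc = _sc(counts, types)
        table = sd.mean_ratio_markers(sc, n_per_type=1)
        assert "g4" in list(table.for_type("A")["gene_id"])

    def test_excess_request_warns_and_returns_all(self, means):
        with pytest.warns(UserWarning, match="available genes"):
            table = sd.mean_ratio_markers(means, n_per_type=10)
        assert len(table.for_type("A")) == 3


def _rescaled(sc, factor):
    return sd.SingleCellDataset(
        counts=np.asarray(sc.dense_counts() * factor, dtype=np.int64),
        gene_ids=list(sc.gene_ids), cell_ids=list(sc.cell_ids),
        cell_type=list(sc.cell_type), sample_id=list(sc.sample_id),
        batch_id=list(sc.batch_id), hierarchy=dict(sc.hierarchy),
    )


class TestConcordantMarkers:
    def test_m_of_n_rule(self):
        t1 = sd.mean_ratio_markers(
            pd.DataFrame({"A": [9.0, 1.0], "B": [1.0, 9.0]}, index=["g1", "g2"]), 1
        )
        t2 = sd.mean_ratio_markers(
            pd.DataFrame({"A": [9.0, 1.0], "B": [1.0, 9.0]}, index=["g1", "g2"]), 1
        )
        t3 = sd.mean_ratio_markers(
            pd.DataFrame({"A": [1.0, 9.0], "B": [9.0, 1.0]}, index=["g1", "g2"]), 1
        )
        out = sd.concordant_markers([t1, t2, t3], min_runs=2)
        assert {("g1", "A"), ("g2", "B")} == set(
            map(tuple, out[["gene_id", "target_type"]].to_numpy())
        )


class TestDownsampleBatches:
    def _two_batch(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 150
        # batch b2 has ~2x the library size of b1, one cell type
        counts = np.hstack([rng.poisson(2.0, (50, n)), rng.poisson(4.0, (50, n))])
        return _sc(counts, ["A"] * (2 * n), batches=["b1"] * n + ["b2"] * n)

    def test_never_increases_counts_and_deterministic(self):
        sc = self._two_batch()
        out1 = sd.downsample_batches(sc, seed=3)
        out2 = sd.downsample_batches(sc, seed=3)
        assert np.all(out1.dense_counts() <= sc.dense_counts())
        np.testing.assert_array_equal(out1.dense_counts(), out2.dense_counts())

    def test_equalizes_batch_library_sizes(self):
        sc = self._two_batch(seed=1)
        out = sd.downsample_batches(sc, seed=2)
        totals = out.dense_counts().sum(axis=0)
        batch = np.asarray(sc.batch_id)
        m1, m2 = totals[batch == "b1"].mean(), totals[batch == "b2"].mean()
        # binomial thinning: means should agree within 3 standard errors
        se = np.sqrt(totals[batch == "b1"].var() / 150 + totals[batch == "b2"].var() / 150)
        assert abs(m1 - m2) < 3 * se

    def test_single_batch_unchanged(self):
        sc = _sc(np.arange(12).reshape(3, 4), ["A"] * 4)
        out = sd.downsample_batches(sc, seed=0)
        np.testing.assert_array_equal(out.dense_counts(), sc.dense_counts())


class TestQCFilter:
    def _bulk(self, totals, zeros, n_markers=40):
        """One sample per (total, zeros) spec, counts spread over markers."""
        cols = []
        for total, nz in zip(totals, zeros):
            col = np.zeros(n_markers)
            nonzero = n_markers - nz
            col[:nonzero] = np.diff(np.linspace(0, total, nonzero + 1)).round()
            col[0] += total - col.sum()
            cols.append(col)
        vals = np.column_stack(cols)
        return sd.BulkMatrix(vals, [f"m{i}" for i in range(n_markers)],
                             [f"s{i}" for i in range(len(totals))])

    def test_count_threshold_is_inclusive(self):
        Y = self._bulk([38_749, 38_750], [0, 0])
        filtered, report = sd.qc_filter_bulk(Y, Y.gene_ids)
        assert report.failed == ["s0"] and report.passed == ["s1"]
        assert filtered.sample_ids == ["s1"]

    def test_zero_marker_threshold(self):
        Y = self._bulk([50_000, 50_000], [31, 30])
        filtered, report = sd.qc_filter_bulk(Y, Y.gene_ids)
        assert report.failed == ["s0"]
        assert filtered.sample_ids == ["s1"]

    def test_all_passing_identity(self):
        Y = self._bulk([100_000, 90_000], [0, 1])
        filtered, _ = sd.qc_filter_bulk(Y, Y.gene_ids)
        np.testing.assert_array_equal(filtered.values, Y.values)

    def test_absent_markers_count_as_zeros(self):
        Y = self._bulk([100_000], [0], n_markers=40)
        markers = list(Y.gene_ids) + [f"absent{i}" for i in range(31)]
        _, report = sd.qc_filter_bulk(Y, markers)
        assert report.failed == ["s0"]


class TestNormalizeBulk:
    def test_rpkm_by_hand(self):
        Y = sd.BulkMatrix(np.array([[10.0], [999_990.0]]), ["g1", "g2"], ["s1"])
        out = sd.normalize_bulk(Y, {"g1": 1000, "g2": 500}, method="rpkm")
        assert out.values[0, 0] == pytest.approx(10.0)
        logged = sd.normalize_bulk(Y, {"g1": 1000, "g2": 500}, method="rpkm", log2=True)
        assert logged.values[0, 0] == pytest.approx(np.log2(11), abs=1e-4)

    def test_cpm_and_zero_count_pseudocount(self):
        Y = sd.BulkMatrix(np.array([[100.0], [999_900.0]]), ["g1", "g2"], ["s1"])
        out = sd.normalize_bulk(Y, method="cpm")
        assert out.values[0, 0] == pytest.approx(100.0)
        Y0 = sd.BulkMatrix(np.array([[0.0], [10.0]]), ["g1", "g2"], ["s1"])
        logged = sd.normalize_bulk(Y0, method="cpm", log2=True)
        assert logged.values[0, 0] == 0.0

    def test_missing_length_names_gene(self):
        Y = sd.BulkMatrix(np.ones((2, 1)), ["g1", "g2"], ["s1"])
        with pytest.raises(ValidationError, match="g2"):
            sd.normalize_bulk(Y, {"g1": 100}, method="rpkm")
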