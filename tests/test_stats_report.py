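import math

import numpy as np
import pandas as pd
import pytest

from adipometry.stats_report import (
    BinnedTable,
    HistogramSpec,
    compare_methods,
    export_table,
    histogram,
    percent_difference,
    read_binned_csv,
    totals,
)

from test_filters import fabricate

# Two published 8-bin method-comparison tables used as shared reference data.
BINS_A = BinnedTable(
    labels=("b1", "b2", "b3", "b4", "b5", "b6", "b7", "b8"),
    counts=(34, 12, 14, 22, 18, 15, 7, 13),
    areas=(5897.6, 7938.6, 20291.5, 64989, 84622.5, 104020.6, 59847.7, 182616.7),
)
BINS_B = BinnedTable(
    labels=BINS_A.labels,
    counts=(36, 14, 16, 24, 20, 16, 8, 10),
    areas=(7577.2, 9496.3, 22828.2, 70088.1, 96894.5, 110982.7, 69011.4, 131721.0),
)


class TestTotals:
    def test_empty(self):
        pop = fabricate([])
        assert totals(pop) == (0, 0.0)

    def test_excluded_not_counted(self):
        from adipometry.filters import filter_by_area

        pop = fabricate([100, 100, 100, 9000])
        pop = filter_by_area(pop, 0, 1000)
        assert totals(pop) == (3, 300.0)

    def test_fixture_ground_truth(self, voronoi_population, voronoi_fixture):
        _, gt = voronoi_fixture
        n, _ = totals(voronoi_population)
        assert n == gt.n_cells


class TestHistogramSpec:
    def test_requires_ascending(self):
        with pytest.raises(ValueError):
            HistogramSpec((10, 10, 20))

    def test_requires_an_edge(self):
        with pytest.raises(ValueError):
            HistogramSpec(())

    def test_labels(self):
        spec = HistogramSpec((10, 251, 501))
        assert spec.labels == ("10-251", "251-501", "501+")


class TestHistogram:
    def test_cell_on_interior_edge_goes_up(self):
        pop = fabricate([251.0])
        table = histogram(pop, HistogramSpec((10, 251, 501)))
        assert table.counts == (0, 1, 0)

    def test_underflow_row(self):
        pop = fabricate([5, 5, 100])
        table = histogram(pop, HistogramSpec((10, 251)))
        assert table.underflow_count == 2
        assert table.underflow_area == 10.0
        assert table.counts == (1, 0)

    def test_final_bin_open_ended(self):
        pop = fabricate([1e9])
        table = histogram(pop, HistogramSpec((10, 251)))
        assert table.counts == (0, 1)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        areas = rng.uniform(0, 5000, size=200).tolist()
        edges = (10.0, 251.0, 501.0, 1001.0, 2001.0, 3001.0)
        pop = fabricate([1] * len(areas))
        for cell, a in zip(pop.cells, areas):
            cell.area_um2 = a
        table = histogram(pop, HistogramSpec(edges))
        # independent brute-force loop
        exp_counts = [0] * len(edges)
        exp_areas = [0.0] * len(edges)
        under_n, under_a = 0, 0.0
        for a in areas:
            if a < edges[0]:
                under_n += 1
                under_a += a
                continue
            for i in range(len(edges) - 1, -1, -1):
                if a >= edges[i]:
                    exp_counts[i] += 1
                    exp_areas[i] += a
                    break
        assert table.counts == tuple(exp_counts)
        assert table.areas == pytest.approx(tuple(exp_areas))
        assert table.underflow_count == under_n

    def test_conservation(self, voronoi_population):
        spec = HistogramSpec((0, 500, 1000, 2000, 4000))
        table = histogram(voronoi_population, spec)
        n, area = totals(voronoi_population)
        assert table.total_count + table.underflow_count == n
        assert table.total_area + table.underflow_area == pytest.approx(area, rel=1e-12)


class TestPercentDifference:
    def test_total_area_example(self):
        assert round(percent_difference(475217.7, 490921.3), 1) == 3.3

    def test_identical_zero(self):
        assert percent_difference(42.0, 42.0) == 0.0

    def test_count_increase_example(self):
        assert round(percent_difference(133, 179)) == 35

    def test_zero_reference_nan(self):
        assert math.isnan(percent_difference(0, 5))

    def test_not_symmetric(self):
        assert percent_difference(100, 150) != percent_difference(150, 100)


class TestCompareMethods:
    def test_count_correlation_nine_decimals(self):
        stats = compare_methods(BINS_A, BINS_B)
        assert round(stats.r_count, 9) == 0.982815341
        assert round(stats.p_count, 7) == round(1.25e-05, 7)

    def test_area_correlation(self):
        stats = compare_methods(BINS_A, BINS_B)
        assert round(stats.r_area, 9) == 0.950701594

    def test_identical_tables(self):
        stats = compare_methods(BINS_A, BINS_A)
        assert stats.r_count == 1.0
        assert stats.r_area == 1.0
        assert stats.p_count == 0.0
        assert all(d == 0.0 for d in stats.per_bin_area_pct_diff)
        assert stats.total_area_pct_diff == 0.0

    def test_r_symmetric_pct_diff_not(self):
        ab = compare_methods(BINS_A, BINS_B)
        ba = compare_methods(BINS_B, BINS_A)
        assert ab.r_count == pytest.approx(ba.r_count, abs=1e-15)
        assert ab.r_area == pytest.approx(ba.r_area, abs=1e-15)
        assert ab.total_area_pct_diff != ba.total_area_pct_diff

    def test_matches_scipy_oracle(self):
        from scipy import stats as sps

        mine = compare_methods(BINS_A, BINS_B)
        r, p = sps.pearsonr(BINS_A.counts, BINS_B.counts)
        assert mine.r_count == pytest.approx(r, abs=1e-12)
        assert mine.p_count == pytest.approx(p, rel=1e-9)

    def test_r_squared_equals_regression_r2(self):
        stats = compare_methods(BINS_A, BINS_B)
        for x, y, r in ((BINS_A.counts, BINS_B.counts, stats.r_count),
                        (BINS_A.areas, BINS_B.areas, stats.r_area)):
            slope, intercept = np.polyfit(x, y, 1)
            resid = np.asarray(y) - (slope * np.asarray(x) + intercept)
            ss_res = float(resid @ resid)
            yd = np.asarray(y, dtype=float) - np.mean(y)
            r2 = 1.0 - ss_res / float(yd @ yd)
            assert r * r == pytest.approx(r2, rel=1e-9)
            assert math.copysign(1, r) == math.copysign(1, slope)

    def test_mismatched_bins_raise(self):
        other = BinnedTable(labels=("x", "y", "z"), counts=(1, 2, 3), areas=(1.0, 2.0, 3.0))
        with pytest.raises(ValueError, match="bin structures"):
            compare_methods(BINS_A, other)

    def test_two_bins_rejected(self):
        small = BinnedTable(labels=("a", "b"), counts=(1, 2), areas=(1.0, 2.0))
        with pytest.raises(ValueError, match="at least 3"):
            compare_methods(small, small)

    def test_zero_variance_nan(self):
        flat = BinnedTable(labels=("a", "b", "c"), counts=(5, 5, 5), areas=(1.0, 2.0, 3.0))
        varying = BinnedTable(labels=("a", "b", "c"), counts=(1, 2, 3), areas=(1.0, 2.0, 3.0))
        stats = compare_methods(flat, varying)
        assert math.isnan(stats.r_count)
        assert not math.isnan(stats.r_area)


class TestExportTable:
    def test_csv_round_trip_binned(self, tmp_path):
        p = export_table(BINS_A, tmp_path / "bins.csv")
        back = read_binned_csv(p)
        assert back.labels == BINS_A.labels
        assert back.counts == BINS_A.counts
        assert back.areas == pytest.approx(BINS_A.areas)

    def test_population_csv(self, tmp_path):
        pop = fabricate([100, 200, 300])
        p = export_table(pop, tmp_path / "cells.csv")
        frame = pd.read_csv(p)
        assert len(frame) == 3
        assert list(frame.columns) == ["id", "area_px", "area_um2", "included", "exclusion_reason"]

    def test_empty_population_header_only(self, tmp_path):
        p = export_table(fabricate([]), tmp_path / "cells.csv")
        frame = pd.read_csv(p)
        assert len(frame) == 0
        assert "area_um2" in frame.columns

    def test_xlsx_mirror(self, tmp_path):
        p = export_table(BINS_A, tmp_path / "bins.xlsx", format="xlsx")
        frame = pd.read_excel(p)
        assert frame["count"].iloc[:8].tolist() == list(BINS_A.counts)

    def test_comparison_stats_export(self, tmp_path):
        stats = compare_methods(BINS_A, BINS_B)
        p = export_table(stats, tmp_path / "cmp.csv")
        frame = pd.read_csv(p).set_index("statistic")
        assert frame.loc["r_count", "value"] == pytest.approx(stats.r_count)

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_table(BINS_A, tmp_path / "bins.bin", format="bin")

    def test_histogram_png(self, tmp_path):
        from adipometry.stats_report import save_histogram_png

        out = save_histogram_png(BINS_A, tmp_path / "hist.png")
        assert out.stat().st_size > 0
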