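"""Localization table I/O, histogram rendering, and dataset splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from densestorm.localization_io import (
    FormatError,
    LocalizationTable,
    read_localizations,
    remove_isolated,
    render_histogram,
    split_by_frame_window,
    split_half,
    write_localizations,
)


class TestReadWrite:
    def test_csv_camera_pixel_conversion(self, tmp_path):
        path = tmp_path / "locs.csv"
        pd.DataFrame({"x": [1.0, 2.0, 3.5], "y": [0.5, 1.5, 2.0], "frame": [0, 1, 2]}).to_csv(
            path, index=False
        )
        table = read_localizations(path, units="px", camera_pixel_nm=108.0)
        assert len(table) == 3
        np.testing.assert_allclose(table.x, [108.0, 216.0, 378.0])
        np.testing.assert_allclose(table.y, [54.0, 162.0, 216.0])

    def test_header_only_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("x,y,frame\n")
        table = read_localizations(path)
        assert len(table) == 0

    def test_missing_frame_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"x": [1.0], "y": [2.0]}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="frame"):
            read_localizations(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,frame\n1.0,2.0,0\noops,3.0,1\n")
        with pytest.raises(FormatError, match="row 1"):
            read_localizations(path)

    def test_hdf5_roundtrip(self, tmp_path, random_table):
        path = tmp_path / "locs.hdf5"
        write_localizations(random_table, path)
        back = read_localizations(path, units="nm")
        np.testing.assert_allclose(np.sort(back.x), np.sort(random_table.x))
        np.testing.assert_array_equal(np.sort(back.frame), np.sort(random_table.frame))

    def test_column_aliases_resolve(self, tmp_path):
        path = tmp_path / "alias.csv"
        path.write_text("x [nm],y [nm],frames\n10,20,0\n")
        table = read_localizations(path, units="nm")
        assert table.x[0] == 10.0


class TestRenderHistogram:
    def test_empty_table_renders_zeros(self):
        table = LocalizationTable(x=np.empty(0), y=np.empty(0), frame=np.empty(0, int))
        hist = render_histogram(table, 5.0, (0, 50, 0, 50))
        assert hist.counts.sum() == 0
        assert hist.shape == (10, 10)

    def test_coincident_localizations_share_one_pixel(self):
        table = LocalizationTable(x=[12.0] * 3, y=[7.0] * 3, frame=[0, 1, 2])
        hist = render_histogram(table, 5.0, (0, 50, 0, 50))
        assert hist.counts.sum() == 3
        assert hist.counts.max() == 3

    def test_boundary_goes_to_higher_pixel(self):
        # x exactly on the bin edge between pixels 1 and 2
        table = LocalizationTable(x=[10.0], y=[2.0], frame=[0])
        hist = render_histogram(table, 5.0, (0, 50, 0, 50))
        assert hist.counts[0, 2] == 1

    def test_outside_extent_dropped_and_counted(self):
        table = LocalizationTable(x=[10.0, 999.0], y=[10.0, 10.0], frame=[0, 0])
        hist = render_histogram(table, 5.0, (0, 50, 0, 50))
        assert hist.counts.sum() == 1
        assert hist.n_dropped == 1

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 300))
        table = LocalizationTable(
            x=rng.uniform(0, 500, n), y=rng.uniform(0, 500, n), frame=np.zeros(n, int)
        )
        hist = render_histogram(table, 5.0, (0, 500, 0, 500))
        assert hist.counts.sum() == n

    def test_integer_pixel_shift_commutes(self, random_table):
        pixel = 5.0
        hist = render_histogram(random_table, pixel, (0, 1000, 0, 1000))
        shifted_table = LocalizationTable(
            x=random_table.x + 3 * pixel, y=random_table.y, frame=random_table.frame
        )
        shifted = render_histogram(shifted_table, pixel, (0, 1000 + 3 * pixel, 0, 1000))
        np.testing.assert_array_equal(shifted.counts[:, 3:], hist.counts)


class TestRemoveIsolated:
    def test_single_localization_removed(self):
        table = LocalizationTable(x=[0.0], y=[0.0], frame=[0])
        assert len(remove_isolated(table, 50.0, 1)) == 0

    def test_dense_cluster_fully_retained(self, rng):
        n = 10
        table = LocalizationTable(
            x=rng.uniform(0, 10, n), y=rng.uniform(0, 10, n), frame=np.zeros(n, int)
        )
        assert len(remove_isolated(table, 50.0, 3)) == n

    def test_matches_bruteforce_pairwise_filter(self, rng):
        n, radius, k = 100, 60.0, 2
        table = LocalizationTable(
            x=rng.uniform(0, 800, n), y=rng.uniform(0, 800, n), frame=np.zeros(n, int)
        )
        dist = np.hypot(table.x[:, None] - table.x, table.y[:, None] - table.y)
        neighbor_counts = (dist <= radius).sum(axis=1) - 1
        expected = neighbor_counts >= k
        kept = remove_isolated(table, radius, k)
        np.testing.assert_array_equal(np.sort(kept.x), np.sort(table.x[expected]))


class TestFrameWindowSplit:
    def test_fraction_one_returns_everything(self, random_table, rng):
        sub, window = split_by_frame_window(random_table, 1.0, rng)
        assert len(sub) == len(random_table)

    def test_uniform_rate_hits_target_exactly(self, rng):
        table = LocalizationTable(
            x=np.arange(1000, dtype=float), y=np.zeros(1000), frame=np.arange(1000)
        )
        sub, (first, last) = split_by_frame_window(table, 0.1, rng)
        assert len(sub) == 100
        assert last - first + 1 == 100

    def test_window_count_matches_exhaustive_scan(self, rng):
        # nonuniform frame occupancy
        frames = np.repeat(np.arange(50), np.concatenate([np.arange(1, 26), np.arange(25, 0, -1)]))
        table = LocalizationTable(
            x=np.zeros(len(frames), dtype=float), y=np.zeros(len(frames)), frame=frames
        )
        fraction = 0.25
        sub, (first, last) = split_by_frame_window(table, fraction, rng)
        target = fraction * len(table)
        counts = np.bincount(frames, minlength=50)
        cum = np.concatenate([[0], np.cumsum(counts)])
        best = min(abs(cum[e + 1] - cum[first] - target) for e in range(first, 50))
        assert abs(len(sub) - target) == pytest.approx(best)

    def test_empty_table_raises(self, rng):
        empty = LocalizationTable(x=np.empty(0), y=np.empty(0), frame=np.empty(0, int))
        with pytest.raises(ValueError):
            split_by_frame_window(empty, 0.5, rng)

    def test_contiguity_of_selected_frames(self, random_table, rng):
        sub, (first, last) = split_by_frame_window(random_table, 0.3, rng)
        assert sub.frame.min() >= first and sub.frame.max() <= last
        mask = (random_table.frame >= first) & (random_table.frame <= last)
        assert len(sub) == mask.sum()


class TestSplitHalf:
    @given(n=st.integers(2, 200), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_partition_property(self, n, seed):
        rng = np.random.default_rng(seed)
        table = LocalizationTable(
            x=np.arange(n, dtype=float), y=np.zeros(n), frame=np.zeros(n, int)
        )
        a, b = split_half(table, rng)
        assert abs(len(a) - len(b)) <= 1
        merged = np.sort(np.concatenate([a.x, b.x]))
        np.testing.assert_array_equal(merged, table.x)
        assert set(a.x).isdisjoint(b.x)

    def test_deterministic_for_fixed_seed(self, random_table):
        a1, _ = split_half(random_table, np.random.default_rng(3))
        a2, _ = split_half(random_table, np.random.default_rng(3))
        np.testing.assert_array_equal(a1.x, a2.x)

    def test_too_few_localizations_raises(self):
        table = LocalizationTable(x=[1.0], y=[1.0], frame=[0])
        with pytest.raises(ValueError):
            split_half(table, np.random.default_rng(0))
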