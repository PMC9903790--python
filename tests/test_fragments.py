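"""Fragment parsing, binning, count-matrix construction and filtering."""

import gzip

import numpy as np
import pandas as pd
import pytest

import scregseg as sg
from scregseg.fragments import write_fragments


def _write(tmp_path, text, name="frags.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFragments:
    def test_default_count_is_one(self, tmp_path):
        fs = sg.read_fragments(_write(tmp_path, "chr1\t100\t300\tAAAC\n"))
        assert fs.records == [("chr1", 100, 300, "AAAC", 1)]

    def test_explicit_count_with_five_columns(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\t300\tAAAC\t3\n")
        fs = sg.read_fragments(p, dialect="5-column")
        assert fs.records == [("chr1", 100, 300, "AAAC", 3)]

    def test_four_column_dialect_ignores_count_field(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\t300\tAAAC\t3\n")
        assert sg.read_fragments(p, dialect="4-column").records[0][4] == 1

    def test_end_not_after_start_errors_with_line_number(self, tmp_path):
        p = _write(tmp_path, "chr1\t300\t100\tAAAC\n")
        with pytest.raises(ValueError, match="line 1"):
            sg.read_fragments(p)

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = _write(tmp_path, "# header\n\nchr1\t0\t10\tA\n")
        assert len(sg.read_fragments(p)) == 1

    def test_unknown_dialect(self, tmp_path):
        p = _write(tmp_path, "chr1\t0\t10\tA\n")
        with pytest.raises(ValueError, match="dialect"):
            sg.read_fragments(p, dialect="6-column")

    def test_gzip_roundtrip(self, tmp_path):
        p = tmp_path / "frags.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t5\t25\tB\t2\n")
        assert sg.read_fragments(p).records == [("chr1", 5, 25, "B", 2)]

    def test_write_then_read(self, tmp_path, small_sim):
        p = tmp_path / "rt.tsv"
        write_fragments(small_sim["frags"], p)
        again = sg.read_fragments(p)
        pd.testing.assert_frame_equal(
            again.data, small_sim["frags"].data.reset_index(drop=True)
        )


class TestMakeBins:
    def test_ceiling_partition(self):
        bins = sg.make_bins({"chrA": 2500}, 1000)
        df = bins.to_dataframe()
        assert list(df["start"]) == [0, 1000, 2000]
        assert list(df["end"]) == [1000, 2000, 2500]

    def test_exact_fit(self):
        assert sg.make_bins({"chrA": 1000}, 1000).n_bins == 1

    def test_offsets_follow_input_order(self):
        bins = sg.make_bins({"chrA": 1000, "chrB": 1000}, 500)
        assert bins.n_bins == 4
        assert bins.offsets == {"chrA": 0, "chrB": 2}

    def test_duplicate_chromosome_errors(self):
        df = pd.DataFrame({"chrom": ["c", "c"], "size": [10, 20]})
        with pytest.raises(ValueError, match="duplicate"):
            sg.make_bins(df, 5)

    def test_bed_round_trip(self, tmp_path):
        bins = sg.make_bins({"chr1": 2500, "chr2": 999}, 1000)
        path = tmp_path / "bins.bed"
        bins.to_bed(path)
        assert sg.BinIndex.from_bed(path) == bins


class TestCountMatrix:
    def _frags(self, rows):
        return sg.FragmentSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
        )

    def test_midpoint_assignment(self):
        bins = sg.make_bins({"chr1": 3000}, 1000)
        cm = sg.count_matrix(self._frags([("chr1", 100, 300, "A", 1)]), bins)
        assert cm.values[0, 0] == 1

    def test_midpoint_on_boundary_goes_to_next_bin(self):
        bins = sg.make_bins({"chr1": 3000}, 1000)
        cm = sg.count_matrix(self._frags([("chr1", 900, 1100, "A", 1)]), bins)
        assert cm.values[1, 0] == 1 and cm.values[0, 0] == 0

    def test_cap_trims_entries(self):
        bins = sg.make_bins({"chr1": 1000}, 1000)
        rows = [("chr1", 100, 300, "A", 1)] * 5
        cm = sg.count_matrix(self._frags(rows), bins, cap=4)
        assert cm.values[0, 0] == 4
        assert cm.track_totals[0] == 5  # uncapped totals carried alongside

    def test_unknown_chromosome_dropped_and_tallied(self):
        bins = sg.make_bins({"chr1": 1000}, 1000)
        rows = [("chr1", 0, 10, "A", 1), ("chrZ", 0, 10, "A", 1)]
        cm = sg.count_matrix(self._frags(rows), bins)
        assert cm.n_dropped == 1
        assert cm.values.sum() == 1

    def test_record_order_invariance(self, small_sim):
        frags = small_sim["frags"]
        shuffled = sg.FragmentSet(
            frags.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        bins = sg.make_bins(small_sim["chrom_sizes"], 1000)
        a = sg.count_matrix(frags, bins, cap=4)
        b = sg.count_matrix(shuffled, bins, cap=4)
        assert a.tracks == b.tracks
        assert (a.values != b.values).nnz == 0

    def test_total_counts_conserved(self, small_sim):
        bins = sg.make_bins(small_sim["chrom_sizes"], 1000)
        cm = sg.count_matrix(small_sim["frags"], bins, cap=None)
        assert cm.values.sum() == small_sim["frags"].total_count - cm.n_dropped

    def test_save_load_round_trip(self, tmp_path, small_sim):
        cm = small_sim["cm"]
        sg.save_counts(cm, tmp_path / "counts")
        back = sg.load_counts(tmp_path / "counts")
        assert back.tracks == cm.tracks
        assert back.cap == cm.cap
        assert (back.values != cm.values).nnz == 0
        assert np.array_equal(back.track_totals, cm.track_totals)


class TestFilters:
    def _cm(self, dense, totals=None, cap=None):
        dense = np.asarray(dense)
        bins = sg.make_bins({"chr1": 1000 * dense.shape[0]}, 1000)
        return sg.CountMatrix(
            values=dense,
            bins=bins,
            tracks=[f"bc{j}" for j in range(dense.shape[1])],
            track_totals=np.asarray(
                totals if totals is not None else dense.sum(axis=0)
            ),
            cap=cap,
        )

    def test_barcode_bounds_are_inclusive(self):
        cm = self._cm([[999, 1000, 30000, 30001]])
        out = sg.filter_barcodes(cm, 1000, 30000)
        assert out.tracks == ["bc1", "bc2"]

    def test_barcode_filter_uses_uncapped_totals(self):
        # capped entries sum to 4 but the true fragment total is 1200
        cm = self._cm([[4]], totals=[1200], cap=4)
        assert sg.filter_barcodes(cm, 1000, 30000).tracks == ["bc0"]

    def test_barcode_filter_identity(self):
        cm = self._cm([[5, 7]])
        assert sg.filter_barcodes(cm, 0, 10**9).tracks == cm.tracks

    def test_all_barcodes_removed_errors(self):
        with pytest.raises(ValueError, match="no barcodes"):
            sg.filter_barcodes(self._cm([[1, 2]]), 100, 200)

    def test_region_and_cell_filter(self):
        dense = [[0, 0], [1, 0], [250, 150]]
        out = sg.filter_regions_and_cells(self._cm(dense), 1, 200)
        assert out.values.shape == (2, 1)
        assert list(out.bin_ids) == [1, 2]

    def test_cell_below_threshold_removed(self):
        out = sg.filter_regions_and_cells(self._cm([[199, 200]]), 1, 200)
        assert out.tracks == ["bc1"]

    def test_zero_thresholds_identity(self):
        cm = self._cm([[1, 0], [0, 2]])
        out = sg.filter_regions_and_cells(cm, 0, 0)
        assert out.values.shape == cm.values.shape


class TestCollapse:
    def _cm(self, dense, tracks):
        dense = np.asarray(dense)
        bins = sg.make_bins({"chr1": 1000 * dense.shape[0]}, 1000)
        return sg.CountMatrix(
            values=dense,
            bins=bins,
            tracks=tracks,
            track_totals=dense.sum(axis=0),
        )

    def test_group_sums(self):
        cm = self._cm([[1, 2]], ["a", "b"])
        out = sg.collapse_by_group(cm, {"a": "g", "b": "g"})
        assert out.values[0, 0] == 3

    def test_identity_grouping_permutes_columns(self):
        cm = self._cm([[1, 2], [3, 4]], ["b", "a"])
        out = sg.collapse_by_group(cm, {"a": "a", "b": "b"})
        assert out.tracks == ["a", "b"]
        assert out.values.toarray().tolist() == [[2, 1], [4, 3]]

    def test_unlabeled_dropped_with_warning(self):
        cm = self._cm([[1, 2]], ["a", "b"])
        with pytest.warns(UserWarning, match="unlabeled"):
            out = sg.collapse_by_group(cm, {"a": "g"})
        assert out.values[0, 0] == 1

    def test_counts_conserved_over_labeled_barcodes(self, small_sim):
        bins = sg.make_bins(small_sim["chrom_sizes"], 1000)
        cm = sg.count_matrix(small_sim["frags"], bins, cap=None)
        out = sg.collapse_by_group(cm, small_sim["labels"])
        assert out.values.sum() == cm.values.sum()
        assert out.track_totals.sum() == cm.track_totals.sum()

    def test_empty_label_map_errors(self):
        with pytest.raises(ValueError, match="empty label map"):
            sg.collapse_by_group(self._cm([[1]], ["a"]), {})

    def test_group_without_members_dropped_with_warning(self):
        cm = self._cm([[1]], ["a"])
        with pytest.warns(UserWarning, match="no member"):
            out = sg.collapse_by_group(cm, {"a": "g1", "zz": "g2"})
        assert out.tracks == ["g1"]
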