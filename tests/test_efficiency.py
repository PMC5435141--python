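"""Window construction, the efficiency statistic, binning and correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronseek.efficiency import (
    TableCoverage,
    alignment_window_counts,
    bin_and_correlate,
    compute_efficiencies,
    efficiency_windows,
    splicing_efficiency,
)
from intronseek.records import IntronRecord


class TestWindows:
    def test_windows_for_26nt_intron(self):
        w = efficiency_windows("c", 101, 126)
        assert w.flank5 == (85, 95)
        assert w.mid == (108, 118)
        assert w.flank3 == (131, 141)
        for lo, hi in (w.flank5, w.mid, w.flank3):
            assert hi - lo == 10

    def test_mid_window_spans_whole_10nt_intron(self):
        w = efficiency_windows("c", 101, 110)
        assert w.mid == (100, 110)

    def test_out_of_chromosome_errors(self):
        with pytest.raises(ValueError):
            efficiency_windows("c", 8, 30)
        with pytest.raises(ValueError):
            efficiency_windows("c", 101, 126, chrom_length=130)

    def test_too_short_intron_errors(self):
        with pytest.raises(ValueError):
            efficiency_windows("c", 101, 105)


class TestSplicingEfficiency:
    def test_basic_value(self):
        assert splicing_efficiency(100, 9, 80) == 90.0

    def test_negative_clamped_to_zero(self):
        assert splicing_efficiency(50, 200, 50) == 0.0

    def test_zero_flanks_undefined(self):
        assert splicing_efficiency(0, 5, 0) is None

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            splicing_efficiency(-1, 0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(r5=st.integers(0, 500), rm=st.integers(0, 500),
           r3=st.integers(0, 500), scale=st.integers(2, 9))
    def test_range_and_scale_invariance(self, r5, rm, r3, scale):
        eff = splicing_efficiency(r5, rm, r3)
        if eff is None:
            assert r5 + r3 == 0
            return
        assert 0.0 <= eff <= 100.0
        assert splicing_efficiency(
            r5 * scale, rm * scale, r3 * scale
        ) == pytest.approx(eff)

    @pytest.mark.parametrize("planted", [0.0, 3.7, 25.0, 50.0, 90.0, 100.0])
    def test_recovers_planted_efficiency_from_exact_counts(self, planted):
        depth = 1000
        mid = round(depth * (100 - planted) / 100)
        est = splicing_efficiency(depth, mid, depth)
        assert abs(est - planted) <= 0.05  # rounding of the mid count only


class TestTableCoverage:
    def test_lookup_and_missing(self):
        frame = pd.DataFrame(
            [("i1", "s1", 100, 9, 80)], columns=TableCoverage.COLUMNS
        )
        cov = TableCoverage(frame)
        assert cov.window_counts("i1", "s1") == (100, 9, 80)
        assert cov.window_counts("i1", "s2") is None

    def test_negative_counts_rejected(self):
        frame = pd.DataFrame(
            [("i1", "s1", -1, 9, 80)], columns=TableCoverage.COLUMNS
        )
        with pytest.raises(ValueError):
            TableCoverage(frame)

    def test_compute_efficiencies_avg_and_max(self):
        frame = pd.DataFrame(
            [("c:101-126:+", "s1", 100, 50, 100),
             ("c:101-126:+", "s2", 100, 10, 100),
             ("c:101-126:+", "s3", 0, 10, 0)],  # undefined, excluded
            columns=TableCoverage.COLUMNS,
        )
        rec = IntronRecord("c", 101, 126, "+")
        table = compute_efficiencies([rec], TableCoverage(frame))
        assert rec.avg_efficiency == pytest.approx(70.0)
        assert rec.max_efficiency == pytest.approx(90.0)
        assert rec.max_efficiency >= rec.avg_efficiency
        assert math.isnan(
            table.loc[table.sample_id == "s3", "efficiency"].iloc[0]
        )


class TestBinAndCorrelate:
    def test_partition_with_undersized_last_bin(self):
        keys = list(range(45))
        effs = [k * 2.0 for k in keys]
        table, r, p = bin_and_correlate(keys, effs, bin_size=20)
        assert list(table["n"]) == [20, 20, 5]
        assert table["n"].sum() == 45
        assert r == pytest.approx(1.0)

    def test_monotone_signal_gives_signed_correlation(self):
        rng = np.random.default_rng(0)
        keys = rng.uniform(0, 100, 200)
        effs = 50 + 0.4 * keys + rng.normal(0, 2, 200)
        _, r, p = bin_and_correlate(keys, effs)
        assert r > 0.9 and p < 0.01
        _, r2, _ = bin_and_correlate(-keys, effs)
        assert r2 < -0.9

    def test_constant_efficiency_undefined(self):
        _, r, p = bin_and_correlate(list(range(60)), [5.0] * 60)
        assert math.isnan(r) and math.isnan(p)

    def test_fewer_than_two_bins_errors(self):
        with pytest.raises(ValueError):
            bin_and_correlate([1, 2, 3], [1.0, 2.0, 3.0], bin_size=20)


class TestAlignmentCoverage:
    def _write_sam(self, path, reads):
        lines = ["@HD\tVN:1.6\tSO:unsorted", "@SQ\tSN:c\tLN:1000"]
        for i, (pos1, cigar) in enumerate(reads):
            lines.append(
                f"r{i}\t0\tc\t{pos1}\t255\t{cigar}\t*\t0\t0\t*\t*"
            )
        path.write_text("\n".join(lines) + "\n")

    def test_block_overlap_counting(self, tmp_path):
        # intron [101,126]: windows flank5 [85,95) mid [108,118) flank3 [131,141)
        sam = tmp_path / "a.sam"
        self._write_sam(
            sam,
            [
                (81, "20M"),        # covers [80,100): flank5 only
                (109, "10M"),       # inside mid
                (86, "10M26N10M"),  # junction-spanning: blocks [85,95)+[121,131)
                (132, "5M"),        # flank3
                (96, "10M"),        # [95,105): touches nothing
            ],
        )
        w = efficiency_windows("c", 101, 126)
        counts = alignment_window_counts(sam, {"i1": w})
        # the spliced read counts toward flank5 (block overlap) but not mid
        assert counts["i1"] == (2, 1, 1)

    def test_synthetic_sam_matches_table(self, tmp_path, small_dataset):
        from intronseek.simulate import emit_sam_coverage

        ds = small_dataset
        sample = sorted(ds.junctions)[0]
        sam = tmp_path / "cov.sam"
        emit_sam_coverage(ds, sample, sam, depth_scale=0.01)
        frame = ds.coverage.frame
        rows = frame[frame.sample_id == sample].head(5)
        windows = {}
        for row in rows.itertuples(index=False):
            c, span, strand = row.intron_id.split(":")
            s, e = (int(x) for x in span.split("-"))
            windows[row.intron_id] = efficiency_windows(c, s, e)
        counts = alignment_window_counts(sam, windows)
        for row in rows.itertuples(index=False):
            got = counts[row.intron_id]
            want = (round(row.reads_5flank * 0.01), round(row.reads_mid * 0.01),
                    round(row.reads_3flank * 0.01))
            assert got == want
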