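"""Genome-window polymorphism counting, flagging and derivation calls."""

import numpy as np
import pandas as pd
import pytest

from gemmascope.ril import (Derivation, WindowCounts, call_windows,
                            classify_derivation, count_window_polymorphisms,
                            calls_to_bed, flag_significant,
                            read_variant_table, simulate_variant_table,
                            summarize_derivation)


def _wc(counts, width=100_000, chrom="chr1", start=0):
    return WindowCounts(chrom=chrom, start=start, end=start + width - 1,
                        window_size=100_000, counts=counts, intersection=0)


class TestCounting:
    def test_no_variants_all_zero(self):
        out = count_window_polymorphisms(
            pd.DataFrame(columns=["chrom", "pos", "line"]),
            100_000, {"chr1": 250_000})
        assert len(out) == 3
        assert all(sum(w.counts.values()) == 0 for w in out)

    def test_single_window_concentration(self):
        pos = np.arange(100_000, 100_150)
        v = pd.DataFrame(dict(chrom="chr1", pos=pos, line="tak2"))
        out = count_window_polymorphisms(v, 100_000, {"chr1": 399_999})
        assert out[1].counts["tak2"] == 150
        assert out[0].counts["tak2"] == 0
        assert out[2].counts["tak2"] == 0

    def test_position_equal_to_window_size_falls_in_second_window(self):
        v = pd.DataFrame(dict(chrom="chr1", pos=[100_000], line="rit1"))
        out = count_window_polymorphisms(v, 100_000, {"chr1": 399_999})
        assert out[1].counts["rit1"] == 1
        assert out[0].counts["rit1"] == 0

    def test_position_out_of_range_names_record(self):
        v = pd.DataFrame(dict(chrom="chr1", pos=[500_000], line="rit1"))
        with pytest.raises(ValueError, match="chr1:500000"):
            count_window_polymorphisms(v, 100_000, {"chr1": 250_000})

    def test_intersection_counts_shared_positions(self):
        rows = [("chr1", p, line) for p in (10, 20, 30)
                for line in ("tak2", "rit1", "rit2")]
        rows.append(("chr1", 40, "tak2"))
        v = pd.DataFrame(rows, columns=["chrom", "pos", "line"])
        out = count_window_polymorphisms(v, 100_000, {"chr1": 99_999})
        assert out[0].intersection == 3

    def test_window_tiling_partitions_chromosome(self):
        out = count_window_polymorphisms(
            pd.DataFrame(columns=["chrom", "pos", "line"]),
            100_000, {"chr1": 777_777})
        widths = sum(w.width for w in out)
        assert widths == 777_778  # coordinates 0..length inclusive


class TestFlagging:
    def test_strict_inequality_at_threshold(self):
        w = _wc({"tak2": 100, "rit1": 101, "rit2": 0})
        flags = flag_significant(w)
        assert flags == {"tak2": False, "rit1": True, "rit2": False}

    def test_megabase_window_threshold(self):
        w = WindowCounts("chr1", 0, 999_999, 1_000_000,
                         {"tak2": 1_001, "rit1": 1_000, "rit2": 999}, 0)
        flags = flag_significant(w)
        assert flags == {"tak2": True, "rit1": False, "rit2": False}

    def test_truncated_terminal_window_scales_threshold(self):
        w = WindowCounts("chr1", 200_000, 249_999, 100_000,
                         {"tak2": 60, "rit1": 50, "rit2": 0}, 0)
        flags = flag_significant(w)
        assert flags["tak2"] is True   # threshold 50 for a 50-kb window
        assert flags["rit1"] is False  # 50 is not > 50


class TestClassification:
    @pytest.mark.parametrize("flags, expected", [
        (dict(tak2=False, rit1=False, rit2=False), Derivation.SHARED),
        (dict(tak2=False, rit1=True, rit2=True), Derivation.SHARED),
        (dict(tak2=True, rit1=True, rit2=True), Derivation.TAK2),
        (dict(tak2=True, rit1=True, rit2=False), Derivation.TAK2),
        (dict(tak2=True, rit1=False, rit2=False), Derivation.TAK1),
    ])
    def test_rule_table(self, flags, expected):
        assert classify_derivation(flags) is expected

    def test_sex_chromosome_excluded(self):
        with pytest.raises(ValueError, match="sex-chromosome"):
            classify_derivation(dict(tak2=True, rit1=True, rit2=True), chrom="chrV")

    def test_call_windows_skips_sex_chromosomes(self):
        windows = [
            _wc({"tak2": 0, "rit1": 0, "rit2": 0}, chrom="chr1"),
            _wc({"tak2": 500, "rit1": 500, "rit2": 500}, chrom="chrU"),
        ]
        calls = call_windows(windows)
        assert len(calls) == 1 and calls[0].chrom == "chr1"


class TestSummaryAndRecovery:
    def test_all_shared(self):
        calls = call_windows([_wc({"tak2": 0, "rit1": 0, "rit2": 0},
                                  start=i * 100_000) for i in range(4)])
        fr = summarize_derivation(calls)
        assert fr == {"TAK1": 0.0, "TAK2": 0.0, "SHARED": 1.0}

    def test_planted_fractions_recovered_exactly(self):
        planted = ([("chr1", Derivation.SHARED)] * 5
                   + [("chr1", Derivation.TAK2)] * 3
                   + [("chr1", Derivation.TAK1)] * 2)
        table, lengths, truth = simulate_variant_table(planted, 100_000, seed=4)
        windows = count_window_polymorphisms(table, 100_000, lengths)
        calls = call_windows(windows)
        assert [c.call for c in calls] == truth
        fr = summarize_derivation(calls)
        assert fr["SHARED"] == pytest.approx(0.5, abs=1e-9)
        assert fr["TAK2"] == pytest.approx(0.3, abs=1e-9)
        assert fr["TAK1"] == pytest.approx(0.2, abs=1e-9)

    def test_fractions_sum_to_one(self):
        planted = [("chr1", Derivation.SHARED), ("chr1", Derivation.TAK1),
                   ("chr2", Derivation.TAK2)]
        table, lengths, _ = simulate_variant_table(planted, 100_000, seed=1)
        calls = call_windows(count_window_polymorphisms(table, 100_000, lengths))
        assert sum(summarize_derivation(calls).values()) == pytest.approx(1.0, abs=1e-9)

    def test_rit_lines_agree_on_planted_ril_genome(self):
        """Lines built from the same derivation track share flag patterns."""
        planted = [("chr1", d) for d in
                   [Derivation.SHARED, Derivation.TAK2, Derivation.TAK1] * 3]
        table, lengths, _ = simulate_variant_table(planted, 100_000, seed=2)
        windows = count_window_polymorphisms(table, 100_000, lengths)
        for w in windows:
            flags = flag_significant(w)
            assert flags["rit1"] == flags["rit2"]

    def test_coverage_gap_detected(self):
        calls = call_windows([
            _wc({"tak2": 0, "rit1": 0, "rit2": 0}, start=0),
            _wc({"tak2": 0, "rit1": 0, "rit2": 0}, start=300_000),
        ])
        with pytest.raises(ValueError, match="gap"):
            summarize_derivation(calls)


class TestIO:
    def test_bed_track_format(self):
        calls = call_windows([_wc({"tak2": 300, "rit1": 300, "rit2": 300})])
        bed = calls_to_bed(calls)
        assert list(bed.columns) == ["chrom", "start", "end", "call"]
        assert bed.iloc[0]["start"] == 0
        assert bed.iloc[0]["end"] == 100_000
        assert bed.iloc[0]["call"] == "TAK2"

    def test_read_tsv_and_vcf(self, tmp_path):
        tsv = tmp_path / "v.tsv"
        tsv.write_text("chrom\tpos\tline\nchr1\t5\ttak2\n")
        df = read_variant_table(tsv)
        assert df.iloc[0]["line"] == "tak2"
        vcf = tmp_path / "rit1.vcf"
        vcf.write_text("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\n"
                       "chr1\t42\t.\tA\tT\t.\t.\t.\n")
        dv = read_variant_table(vcf)
        assert dv.iloc[0]["pos"] == 42 and dv.iloc[0]["line"] == "rit1"
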