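"""Poly(A)-region partitioning, counting, testing and shift calling."""

import numpy as np
import pytest

from apafeedback import apa_shift as sh
from apafeedback.annotation_io import GenomeAccessor, Interval, ReadPlacement, UtrSequence
from apafeedback.apa_discovery import ApaSite


def _sites(gene_id, offsets):
    return [
        ApaSite(f"{gene_id}:s{k}", "c", 0, "+", gene_id, off)
        for k, off in enumerate(offsets, 1)
    ]


def _regions(offsets, gene_id="g", counts=None):
    rs = sh.partition_polya_regions(offsets[-1], _sites(gene_id, offsets))
    if counts:
        for r, (cs, cc) in zip(rs, counts):
            r.count_study, r.count_control = cs, cc
    return rs


class TestPartition:
    def test_three_sites_tile_prefix(self):
        rs = sh.partition_polya_regions(1000, _sites("g", [200, 600, 1000]))
        assert [(r.start, r.end) for r in rs] == [(0, 200), (200, 600), (600, 1000)]
        assert [r.index for r in rs] == [1, 2, 3]

    def test_single_site_at_utr_end(self):
        (r,) = sh.partition_polya_regions(500, _sites("g", [500]))
        assert (r.start, r.end) == (0, 500)

    def test_no_sites_no_regions(self):
        assert sh.partition_polya_regions(500, []) == []

    def test_zfr_like_three_regions(self, zfr):
        rs = sh.partition_polya_regions(zfr.utr, _sites("ZFRL", zfr.site_offsets))
        assert [r.index for r in rs] == [1, 2, 3]
        assert rs[-1].end == 1134

    def test_nonincreasing_offsets_rejected(self):
        with pytest.raises(ValueError):
            sh.partition_polya_regions(1000, _sites("g", [600, 200]))


class TestCounting:
    def test_boundary_and_interior_assignment(self):
        rs = _regions([200, 600, 1000])
        sh.count_reads_by_region(rs, [250, 200], [])
        assert rs[0].count_study == 1  # offset 200: right-closed region 1
        assert rs[1].count_study == 1  # offset 250 -> region 2

    def test_conservation_and_outside_ignored(self):
        rs = _regions([200, 600, 1000])
        offs = [0, 5, 250, 600, 601, 1000, 1001, 2000]
        ns, _ = sh.count_reads_by_region(rs, offs, [])
        inside = [o for o in offs if 0 < o <= 1000]
        assert ns == len(inside)
        assert sum(r.count_study for r in rs) == ns

    def test_zero_reads(self):
        rs = _regions([200, 600])
        sh.count_reads_by_region(rs, [], [])
        assert all(r.count_study == r.count_control == 0 for r in rs)

    def test_read_end_offset_both_strands(self):
        plus = ReadPlacement("r", Interval("c", 100, 150, "+"), 60, True)
        minus = ReadPlacement("r", Interval("c", 100, 150, "-"), 60, True)
        utr_plus = Interval("c", 50, 400, "+")
        utr_minus = Interval("c", 50, 400, "-")
        assert sh.read_end_utr_offset(plus, utr_plus) == 100
        assert sh.read_end_utr_offset(minus, utr_minus) == 300


class TestRegionTests:
    def test_strong_upregulation(self):
        rs = _regions([200, 400], counts=[(30, 10), (10, 40)])
        tests = sh.test_regions(rs, 1, 2, alpha=0.05)
        assert tests[0].direction == sh.DIRECTION_UP
        assert tests[0].p_value < 1e-4

    def test_proportion_at_null_is_not_called(self):
        rs = _regions([200], counts=[(10, 20)])
        (t,) = sh.test_regions(rs, 1, 2, alpha=0.05)
        assert t.direction == sh.DIRECTION_NONE
        assert t.p_value > 0.9

    def test_equal_libraries_match_binomial_example(self):
        rs = _regions([200], counts=[(5, 10)])
        (t,) = sh.test_regions(rs, 7, 7, alpha=0.05)
        assert t.p_value == pytest.approx(0.30175781, abs=1e-6)

    def test_empty_region_p_one_direction_none(self):
        rs = _regions([200], counts=[(0, 0)])
        (t,) = sh.test_regions(rs, 1, 2)
        assert t.p_value == 1.0 and t.direction == sh.DIRECTION_NONE

    def test_bad_library_sizes_rejected(self):
        with pytest.raises(ValueError):
            sh.test_regions([], 0, 10)


def _tests_from(dirs, gene_id="g"):
    rs = _regions([100 * (i + 1) for i in range(len(dirs))], gene_id=gene_id)
    return [
        sh.RegionTest(region=r, p_value=0.01, q_value=0.01, direction=d)
        for r, d in zip(rs, dirs)
    ]


class TestShiftCall:
    def test_proximal_up_distal_down_is_shorter(self):
        call = sh.call_utr_shift(_tests_from(["up", "up", "none", "down"]))
        assert call.call == sh.CALL_SHORTER
        assert call.median_up_index == 1.5 and call.median_down_index == 4

    def test_distal_up_proximal_down_is_longer(self):
        call = sh.call_utr_shift(_tests_from(["down", "down", "none", "up"]))
        assert call.call == sh.CALL_LONGER

    def test_median_tie_goes_to_shorter_and_is_flagged(self):
        # up at {1, 3} (median 2) vs down at {2} (median 2)
        call = sh.call_utr_shift(_tests_from(["up", "down", "up"]))
        assert call.call == sh.CALL_SHORTER and call.tie

    def test_one_direction_only_not_called(self):
        call = sh.call_utr_shift(_tests_from(["up", "up", "none"]))
        assert call.call == sh.CALL_NONE

    def test_adjacent_indices(self):
        call = sh.call_utr_shift(_tests_from(["up", "down"]))
        assert call.call == sh.CALL_SHORTER
        call = sh.call_utr_shift(_tests_from(["down", "up"]))
        assert call.call == sh.CALL_LONGER


class TestDepthFilter:
    @pytest.mark.parametrize("total,kept", [(19, False), (20, True)])
    def test_boundary_inclusive(self, total, kept):
        rs = _regions([100, 200], counts=[(total // 2, total - total // 2 - 5), (5, 0)])
        assert (("g" in sh.filter_genes_for_depth({"g": rs})) is kept)

    def test_zero_threshold_keeps_all(self):
        rs = _regions([100], counts=[(0, 0)])
        assert sh.filter_genes_for_depth({"g": rs}, min_total=0) == {"g"}


class TestClassSummaryAndInvariances:
    def test_class_fractions(self):
        calls = [
            sh.UtrShiftCall("a", sh.CALL_SHORTER),
            sh.UtrShiftCall("b", sh.CALL_SHORTER),
            sh.UtrShiftCall("c", sh.CALL_LONGER),
            sh.UtrShiftCall("d", sh.CALL_NONE),
        ]
        df = sh.summarize_shift_by_class(
            calls, {"a": "HT-host", "b": "HT-host", "c": "NT-host"}
        )
        assert df.loc["HT-host", "n_called"] == 2
        assert df.loc["HT-host", "fraction_shorter"] == 1.0
        assert df.loc["NT-host", "n_longer"] == 1
        assert "d" not in df.index

    def test_all_longer_gives_zero_fraction_shorter(self):
        calls = [sh.UtrShiftCall(g, sh.CALL_LONGER) for g in "abc"]
        df = sh.summarize_shift_by_class(calls, {})
        assert df.loc["other", "fraction_shorter"] == 0.0

    def test_flip_symmetry_on_fixture(self):
        rs = _regions([200, 400, 600], counts=[(60, 40), (20, 60), (15, 70)])
        tests = sh.test_regions(rs, 1, 2)
        call = sh.call_utr_shift(tests)
        flipped = _regions(
            [200, 400, 600], counts=[(40, 60), (60, 20), (70, 15)]
        )
        ftests = sh.test_regions(flipped, 2, 1)
        fcall = sh.call_utr_shift(ftests)
        assert {call.call, fcall.call} == {sh.CALL_SHORTER, sh.CALL_LONGER}

    def test_calls_invariant_under_joint_scaling(self):
        counts = [(60, 40), (20, 60), (15, 70)]
        rs = _regions([200, 400, 600], counts=counts)
        base = sh.call_utr_shift(sh.test_regions(rs, 10, 20))
        scaled = _regions(
            [200, 400, 600], counts=[(2 * a, 2 * b) for a, b in counts]
        )
        double = sh.call_utr_shift(sh.test_regions(scaled, 20, 40))
        assert base.call == double.call


class TestUpstreamExport:
    def test_window_arithmetic_and_strands(self, zfr, tmp_path):
        t = zfr.gene.longest_transcript
        sites = [
            ApaSite(
                f"ZFRL:s{k}",
                t.chrom,
                t.utr3.end - off,
                "-",
                "ZFRL",
                off,
            )
            for k, off in enumerate(zfr.site_offsets, 1)
        ]
        out = tmp_path / "up.fa"
        n = sh.export_upstream_sequences(sites, zfr.genome, out)
        assert n == 3
        records = out.read_text().strip().split("\n")
        seqs = {records[i][1:]: records[i + 1] for i in range(0, len(records), 2)}
        # sense-strand sequence immediately 5' of each cleavage boundary
        for k, off in enumerate(zfr.site_offsets, 1):
            expect = zfr.utr.seq[max(0, off - 40) : off].replace("U", "T")
            assert seqs[f"ZFRL:s{k}"] == expect
        assert len(seqs["ZFRL:s2"]) == 40

    def test_site_near_utr_start_truncated_with_warning(self, zfr, caplog):
        import io

        t = zfr.gene.longest_transcript
        site = ApaSite("ZFRL:s1", t.chrom, t.utr3.end - 30, "-", "ZFRL", 30)
        buf = io.StringIO()
        with caplog.at_level("WARNING"):
            sh.export_upstream_sequences([site], zfr.genome, buf)
        lines = buf.getvalue().strip().split("\n")
        assert len(lines[1]) == 30
        assert "truncated" in caplog.text
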