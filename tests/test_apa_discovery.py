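"""Tail-evidence detection, internal-priming filtering and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apafeedback import apa_discovery as apa
from apafeedback.annotation_io import GenomeAccessor, Interval, ReadPlacement


def _placement(clip, start=100, end=130, strand="+", mapq=60, read_id="r1"):
    return ReadPlacement(
        read_id=read_id,
        aligned=Interval("c", start, end, strand),
        mapq=mapq,
        unique=True,
        clipped_tail_3p=clip,
    )


def _genome(downstream, upstream_len=130):
    """Genome where [130, ...) holds ``downstream`` after a C-run body."""
    return GenomeAccessor({"c": "C" * upstream_len + downstream + "C" * 50})


CLEAN = "CGTCGATCGGATCCGATGCA"  # 20 nt, 3 A's, max run 1


class TestEstTail:
    def test_twelve_a_clip_with_clean_downstream_is_evidence(self):
        e = apa.detect_est_tail(_placement("A" * 12), _genome(CLEAN))
        assert e is not None
        assert e.tail_len == 12
        assert e.cleavage_pos == 130
        assert e.source == apa.SOURCE_EST

    def test_ten_a_clip_is_below_threshold(self):
        # "more than 10" untemplated adenines: 10 is not enough, 11 is
        assert apa.detect_est_tail(_placement("A" * 10), _genome(CLEAN)) is None
        assert apa.detect_est_tail(_placement("A" * 11), _genome(CLEAN)) is not None

    def test_internal_priming_a_run_rejected(self):
        g = _genome("AAAAAA" + "GCGCGCGCGCGCGC")
        assert apa.detect_est_tail(_placement("A" * 12), g) is None

    def test_internal_priming_a_count_rejected(self):
        # 12 A's spread out, max run below the run threshold
        g = _genome("AACAACAACAACAACAACAA")
        assert apa.detect_est_tail(_placement("A" * 12), g) is None

    def test_templated_tail_rejected(self):
        # genome continues with 12 A's at the cleavage point: tail is
        # templated even though the priming window also trips
        g = _genome("A" * 12 + "CGTCGATC")
        assert apa.detect_est_tail(_placement("A" * 12), g) is None

    def test_minus_strand_uses_upstream_window(self):
        # minus-strand read: cleavage boundary at aligned.start, the
        # transcription-downstream window is genomically left, revcomp
        genome = GenomeAccessor({"c": "C" * 80 + "TGCATCGGATCCGATCGACG" + "C" * 100})
        p = _placement("A" * 12, start=100, end=130, strand="-")
        e = apa.detect_est_tail(p, genome)
        assert e is not None and e.cleavage_pos == 100

    def test_non_a_contaminated_clip_counts_terminal_run_only(self):
        e = apa.detect_est_tail(_placement("G" + "A" * 11), _genome(CLEAN))
        assert e is not None and e.tail_len == 11

    def test_no_clip_is_none(self):
        assert apa.detect_est_tail(_placement(""), _genome(CLEAN)) is None


class TestRnaseqTail:
    def test_two_reads_different_lengths_supported(self):
        g = _genome(CLEAN)
        ps = [
            _placement("AA", start=95, end=130, read_id="a"),
            _placement("AAA", start=98, end=130, read_id="b"),
        ]
        ev = apa.detect_rnaseq_tail(ps, g)
        assert ev is not None and len(ev) == 2

    def test_identical_aligned_lengths_not_supported(self):
        g = _genome(CLEAN)
        ps = [
            _placement("AA", start=95, end=130, read_id="a"),
            _placement("AA", start=95, end=130, read_id="b"),
        ]
        assert apa.detect_rnaseq_tail(ps, g) is None

    def test_single_read_not_supported(self):
        assert (
            apa.detect_rnaseq_tail([_placement("AAAA", start=95, end=130)], _genome(CLEAN))
            is None
        )

    def test_mixed_positions_rejected(self):
        with pytest.raises(ValueError):
            apa.detect_rnaseq_tail(
                [_placement("AA", end=130), _placement("AA", end=131)], _genome(CLEAN)
            )


class TestClustering:
    def test_gap_39_merges(self):
        sites = apa.cluster_apa_sites([(100, "EST"), (139, "EST")])
        assert len(sites) == 1

    def test_gap_41_splits(self):
        sites = apa.cluster_apa_sites([(100, "EST"), (141, "EST")])
        assert len(sites) == 2

    def test_single_position_idempotent(self):
        sites = apa.cluster_apa_sites([(100, "EST")])
        assert len(sites) == 1 and sites[0].position == 100

    def test_representative_is_max_support_then_proximal(self):
        ev = [(100, "EST"), (110, "EST"), (110, "EST")]
        (s,) = apa.cluster_apa_sites(ev, strand="+")
        assert s.position == 110
        # tie: both positions once; most proximal wins per strand
        (s,) = apa.cluster_apa_sites([(100, "EST"), (110, "EST")], strand="+")
        assert s.position == 100
        (s,) = apa.cluster_apa_sites([(100, "EST"), (110, "EST")], strand="-")
        assert s.position == 110

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        positions=st.lists(st.integers(0, 2000), min_size=1, max_size=40),
        gap=st.integers(1, 80),
    )
    def test_support_conserved_reps_apart_and_idempotent(self, positions, gap):
        ev = [(p, "EST") for p in positions]
        sites = apa.cluster_apa_sites(ev, max_gap=gap)
        assert sum(s.total_support for s in sites) == len(positions)
        reps = sorted(s.position for s in sites)
        # cluster *extents* are separated by more than the gap
        extents = sorted((min(s.members), max(s.members)) for s in sites)
        for (a0, a1), (b0, b1) in zip(extents, extents[1:]):
            assert b0 - a1 > gap
        reclustered = apa.cluster_apa_sites(
            [(r, "EST") for r in reps], max_gap=gap
        )
        assert sorted(s.position for s in reclustered) == reps


class TestCatalog:
    def test_three_sources_same_position_one_site(self, small_cohort):
        gid = sorted(small_cohort.genes)[0]
        gene = small_cohort.genes[gid]
        pos = small_cohort.truth.site_genomic[gid][0]
        strand = gene.longest_transcript.strand
        chrom = gene.longest_transcript.chrom
        ev = [
            apa.TailEvidence(chrom, pos, strand, 12, src)
            for src in (apa.SOURCE_EST, apa.SOURCE_RNASEQ, apa.SOURCE_EXTERNAL)
        ]
        cat = apa.build_catalog([ev[0]], [ev[1]], None, {gid: gene})
        # feed external via evidence list instead of BED here
        cat2 = apa.build_catalog(ev, [], None, {gid: gene})
        assert len(cat2.sites_for(gid)) == 1
        assert cat2.sites_for(gid)[0].support == {
            apa.SOURCE_EST: 1,
            apa.SOURCE_RNASEQ: 1,
            apa.SOURCE_EXTERNAL: 1,
        }
        assert len(cat.sites_for(gid)) == 1

    def test_site_beyond_longest_transcript_discarded(self, small_cohort):
        gid = sorted(small_cohort.genes)[0]
        gene = small_cohort.genes[gid]
        t = gene.longest_transcript
        outside = t.span.end + 10 if t.strand == "+" else t.span.start - 10
        ev = [apa.TailEvidence(t.chrom, outside, t.strand, 12, apa.SOURCE_EST)]
        cat = apa.build_catalog(ev, [], None, {gid: gene})
        assert cat.site_count(gid) == 0

    def test_external_bed_unknown_chrom_skipped(self, small_cohort, tmp_path, caplog):
        bed = tmp_path / "x.bed"
        bed.write_text("chrUNKNOWN\t100\t101\ts1\t0\t+\n")
        with caplog.at_level("WARNING"):
            cat = apa.build_catalog([], [], bed, small_cohort.genes)
        assert cat.n_genes == 0
        assert "unknown chromosome" in caplog.text

    def test_zfr_like_three_sites_ordered_proximal_to_distal(self, zfr):
        t = zfr.gene.longest_transcript
        ev = [
            apa.TailEvidence(
                t.chrom, t.utr3.end - off, "-", 12, apa.SOURCE_EST
            )
            for off in zfr.site_offsets
            for _ in range(3)
        ]
        cat = apa.build_catalog(ev, [], None, {"ZFRL": zfr.gene})
        sites = cat.sites_for("ZFRL")
        assert [s.utr_offset for s in sites] == [41, 340, 1134]
        assert [s.site_id for s in sites] == ["ZFRL:s1", "ZFRL:s2", "ZFRL:s3"]

    def test_recovery_on_simulated_tail_reads(self, small_cohort):
        from apafeedback.synthetic_data import simulate_tail_reads

        reads = simulate_tail_reads(small_cohort)
        kept = [r for r in reads if r.mapq >= 20]
        ev = [
            e
            for e in (apa.detect_est_tail(p, small_cohort.genome) for p in kept)
            if e is not None
        ]
        cat = apa.build_catalog(ev, [], None, small_cohort.genes)
        truth = {
            (g, p)
            for g, ps in small_cohort.truth.site_genomic.items()
            for p in ps
        }
        found = {(s.gene_id, s.position) for s in cat.all_sites()}
        assert found == truth  # exact positions, full precision and recall
        decoys = {
            (g, p)
            for g, ps in small_cohort.truth.decoy_genomic.items()
            for p in ps
        }
        assert not (found & decoys)
        assert sum(s.total_support for s in cat.all_sites()) == len(ev)
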