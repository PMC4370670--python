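"""miRNA context classification, seed matching, HT/NT calls."""

import numpy as np
import pytest

from apafeedback import mirna_host as mh
from apafeedback.annotation_io import (
    GeneModel,
    Interval,
    MatureArm,
    MirnaRecord,
    TranscriptModel,
    UtrSequence,
)

import oracles


def _gene(gene_id="g1", chrom="c", strand="+"):
    exons = (
        Interval(chrom, 100, 200, strand),
        Interval(chrom, 400, 500, strand),
        Interval(chrom, 800, 900, strand),
    )
    return GeneModel(gene_id, (TranscriptModel(f"{gene_id}.t", exons),))


class TestLocationClassification:
    def test_mirna_in_intron_with_index_and_distance(self):
        gene = _gene()
        m = MirnaRecord("m1", Interval("c", 250, 330, "+"))
        a = mh.classify_mirna_location(m, [gene])
        assert a.category == "intronic"
        assert a.host_gene_id == "g1"
        assert a.intron_index == 1
        assert a.distance_to_upstream_exon == 50  # 250 - 200

    def test_minus_strand_intron_index_counts_from_transcript_5prime(self):
        gene = _gene(strand="-")
        m = MirnaRecord("m1", Interval("c", 250, 330, "-"))
        a = mh.classify_mirna_location(m, [gene])
        # genomically first intron is the last in transcription order
        assert a.intron_index == 2
        assert a.distance_to_upstream_exon == 400 - 330

    def test_intergenic_mirna_has_no_host(self):
        m = MirnaRecord("m1", Interval("c", 1000, 1080, "+"))
        a = mh.classify_mirna_location(m, [_gene()])
        assert a.category == "intergenic"
        assert a.host_gene_id is None

    def test_exon_intron_straddle_is_exonic(self):
        m = MirnaRecord("m1", Interval("c", 150, 260, "+"))
        a = mh.classify_mirna_location(m, [_gene()])
        assert a.category == "exonic"
        assert a.host_gene_id == "g1"

    def test_zfr_like_mirna_sits_in_intron_11(self, zfr):
        a = mh.classify_mirna_location(zfr.mirna, {"ZFRL": zfr.gene})
        assert a.category == "intronic"
        assert a.intron_index == 11
        assert a.distance_to_upstream_exon == 684

    def test_same_strand_host_preferred(self):
        fwd = _gene("fwd", strand="+")
        rev = _gene("rev", strand="-")
        m = MirnaRecord("m1", Interval("c", 250, 330, "+"))
        a = mh.classify_mirna_location(m, [rev, fwd])
        assert a.host_gene_id == "fwd"


def _utr(seq, gene_id="h1"):
    return UtrSequence(gene_id, seq, Interval("c", 0, len(seq)))


class TestSeedMatching:
    MATURE = "UCGGAAUCCUUAAGGCAUUCA"  # revcomp(nt2-8) = GAUUCCG

    def test_7mer_m8_site_found_at_planted_offset(self):
        utr = _utr("C" * 10 + "GAUUCCG" + "C" * 10)
        (m,) = mh.find_seed_matches(utr, self.MATURE)
        assert (m.utr_offset, m.site_type) == (10, "7mer-m8")

    def test_7mer_a1_site(self):
        utr = _utr("C" * 10 + "AUUCCGA" + "C" * 10)
        (m,) = mh.find_seed_matches(utr, self.MATURE)
        assert (m.utr_offset, m.site_type) == (10, "7mer-A1")

    def test_poly_c_utr_has_no_matches(self):
        assert mh.find_seed_matches(_utr("C" * 60), self.MATURE) == []

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError):
            mh.find_seed_matches(_utr("C" * 30), "UCGGAAU")

    def test_zfr_like_match_at_position_1301(self, zfr):
        (m,) = mh.find_seed_matches(zfr.utr, zfr.mature_seq)
        assert m.utr_offset + 1 == 1301
        assert m.site_type == "7mer-m8"

    def test_matches_reverify_from_stored_offset(self, small_cohort):
        from apafeedback.annotation_io import revcomp_rna

        for m in small_cohort.mirnas:
            host = next(
                a.host_gene_id
                for a in [
                    mh.classify_mirna_location(m, small_cohort.genes)
                ]
            )
            utr = small_cohort.utrs[host]
            for arm in m.arms:
                for hit in mh.find_seed_matches(utr, arm.mature_seq):
                    window = utr.seq[hit.utr_offset : hit.utr_offset + 7]
                    if hit.site_type == "7mer-m8":
                        assert window == revcomp_rna(arm.mature_seq[1:8])
                    else:
                        assert window == revcomp_rna(arm.mature_seq[1:7]) + "A"

    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGU"))
        for _ in range(150):
            utr_seq = "".join(rng.choice(bases, rng.integers(50, 400)))
            mature = "".join(rng.choice(bases, 22))
            got = [
                (m.utr_offset, m.site_type)
                for m in mh.find_seed_matches(_utr(utr_seq), mature)
            ]
            assert got == oracles.seed_matches_brute(utr_seq, mature)


class TestHostTargeting:
    def test_cohort_ht_flags_match_planted_truth(self, small_cohort):
        assigns = [
            mh.classify_mirna_location(m, small_cohort.genes)
            for m in small_cohort.mirnas
        ]
        calls = mh.classify_host_targeting(
            assigns, small_cohort.mirnas, small_cohort.utrs
        )
        truth = {
            (a.mirna_gene_id, a.arm_name): a.is_ht for a in small_cohort.truth.arms
        }
        assert len(calls) == len(truth)
        assert sum(c.is_ht for c in calls) == 5
        for c in calls:
            assert truth[(c.mirna_gene_id, c.arm_name)] == c.is_ht

    def test_order_invariance(self, small_cohort):
        assigns = [
            mh.classify_mirna_location(m, small_cohort.genes)
            for m in small_cohort.mirnas
        ]
        calls_fwd = mh.classify_host_targeting(
            assigns, small_cohort.mirnas, small_cohort.utrs
        )
        calls_rev = mh.classify_host_targeting(
            list(reversed(assigns)),
            list(reversed(small_cohort.mirnas)),
            small_cohort.utrs,
        )
        assert calls_fwd == calls_rev

    def test_host_without_utr_called_nt_with_warning(self, caplog):
        gene = _gene()
        m = MirnaRecord(
            "m1",
            Interval("c", 250, 330, "+"),
            (MatureArm("3p", "UCGGAAUCCUUAAGGCAUUCA"),),
        )
        a = mh.classify_mirna_location(m, [gene])
        with caplog.at_level("WARNING"):
            calls = mh.classify_host_targeting([a], [m], {})
        assert calls[0].is_ht is False and calls[0].n_matches == 0
        assert "no annotated 3'UTR" in caplog.text

    def test_multiple_matches_counted(self):
        utr = _utr("GAUUCCG" * 3)
        m = MirnaRecord(
            "m1", Interval("c", 250, 330, "+"), (MatureArm("3p", TestSeedMatching.MATURE),)
        )
        gene = _gene("h1")
        a = mh.classify_mirna_location(m, [gene])
        calls = mh.classify_host_targeting([a], [m], {"h1": utr})
        assert calls[0].is_ht and calls[0].n_matches == 3


class TestCohortSummary:
    def _calls(self, spec):
        return [
            mh.HostTargetingCall(f"m{i}", "3p", host, ht, int(ht))
            for i, (host, ht) in enumerate(spec)
        ]

    def test_degenerate_length_ranges_give_exact_planted_medians(self):
        from apafeedback.synthetic_data import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            rng_seed=4,
            n_genes=12,
            n_intronic_mirnas=12,
            fraction_ht=0.5,
            ht_utr_length_range=(2000, 2000),
            nt_utr_length_range=(1000, 1000),
        )
        c = generate_cohort(cfg)
        assigns = [mh.classify_mirna_location(m, c.genes) for m in c.mirnas]
        calls = mh.classify_host_targeting(assigns, c.mirnas, c.utrs)
        s = mh.cohort_summary(calls, c.utrs)
        assert s.median_utr_len_ht == 2000
        assert s.median_utr_len_nt == 1000
        assert s.utr_len_test.p_value < 0.05

    def test_identical_distributions_are_not_significant(self):
        utrs = {
            f"h{i}": _utr("C" * 500, gene_id=f"h{i}") for i in range(8)
        }
        calls = self._calls([(f"h{i}", i < 4) for i in range(8)])
        s = mh.cohort_summary(calls, utrs)
        assert s.utr_len_test.p_value > 0.9

    def test_single_gene_sets(self):
        utrs = {"a": _utr("C" * 300, "a"), "b": _utr("C" * 700, "b")}
        s = mh.cohort_summary(self._calls([("a", True), ("b", False)]), utrs)
        assert s.median_utr_len_ht == 300 and s.median_utr_len_nt == 700

    def test_gene_hosting_ht_and_nt_arms_counts_as_ht_host(self):
        utrs = {"a": _utr("C" * 300, "a"), "b": _utr("C" * 700, "b")}
        calls = self._calls([("a", True), ("a", False), ("b", False)])
        s = mh.cohort_summary(calls, utrs)
        assert s.n_ht_hosts == 1 and s.n_nt_hosts == 1
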