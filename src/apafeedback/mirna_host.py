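"""miRNA genomic-context classification and host-targeting calls.

A miRNA locus is *intronic* when fully contained in an intron of a
transcript, *exonic* when it overlaps an exon of a transcript that
contains it, and *intergenic* otherwise.  Mature arms of intronic (and
exonic) miRNAs are scanned against the host gene's 3'UTR for canonical
seed matches — a 7-nt site complementary to mature nucleotides 2-8
(7mer-m8), or complementary to nucleotides 2-7 followed by an A on the
UTR (7mer-A1) — and labelled host-targeting (HT, >= 1 match) or
non-host-targeting (NT).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import (
    GeneModel,
    MirnaRecord,
    UtrSequence,
    revcomp_rna,
    rna_normalise,
)
from .stats_core import TestResult, mann_whitney_u

logger = logging.getLogger(__name__)

SITE_7MER_M8 = "7mer-m8"
SITE_7MER_A1 = "7mer-A1"


@dataclass(frozen=True)
class HostAssignment:
    mirna_gene_id: str
    category: str  # intronic | exonic | intergenic
    host_gene_id: str | None = None
    host_transcript_id: str | None = None
    intron_index: int | None = None  # 1-based, transcription order
    distance_to_upstream_exon: int | None = None

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.host_gene_id is None):
            raise ValueError("intergenic assignments must carry no host")
        if self.intron_index is not None and self.category != "intronic":
            raise ValueError("intron_index only valid for intronic assignments")


@dataclass(frozen=True)
class SeedMatch:
    mirna_gene_id: str
    arm_name: str
    gene_id: str
    utr_offset: int  # 0-based start of the 7-nt site within the UTR
    site_type: str  # 7mer-m8 | 7mer-A1


@dataclass(frozen=True)
class HostTargetingCall:
    mirna_gene_id: str
    arm_name: str
    host_gene_id: str | None
    is_ht: bool
    n_matches: int

    def __post_init__(self) -> None:
        if self.is_ht != (self.n_matches >= 1):
            raise ValueError("is_ht must equal (n_matches >= 1)")


def classify_mirna_location(
    mirna: MirnaRecord, genes: Mapping[str, GeneModel] | Iterable[GeneModel]
) -> HostAssignment:
    """Assign genomic context and, when intragenic, the host gene.

    When several genes contain the locus, a same-strand host is
    preferred; among those, the transcript whose containing intron is
    smallest wins; remaining ties break on gene id.  Alternates are
    logged.
    """
    gene_iter = genes.values() if isinstance(genes, Mapping) else genes
    locus = mirna.locus
    intronic = []  # (strand_mismatch, intron_len, gene_id, tid, idx, dist)
    exonic = []  # (strand_mismatch, gene_id, tid)
    for gene in gene_iter:
        for t in gene.transcripts:
            span = t.span
            if span.chrom != locus.chrom:
                continue
            if not (span.start <= locus.start and locus.end <= span.end):
                continue
            mismatch = int(t.strand != locus.strand)
            if any(e.start < locus.end and locus.start < e.end for e in t.exons):
                exonic.append((mismatch, gene.gene_id, t.transcript_id))
                continue
            for k, intron in enumerate(t.introns_transcription_order(), start=1):
                if intron.start <= locus.start and locus.end <= intron.end:
                    if t.strand == "+":
                        dist = locus.start - intron.start
                    else:
                        dist = intron.end - locus.end
                    intronic.append(
                        (
                            mismatch,
                            intron.length,
                            gene.gene_id,
                            t.transcript_id,
                            k,
                            dist,
                        )
                    )
                    break
    if intronic:
        intronic.sort()
        if len({c[2] for c in intronic}) > 1:
            logger.info(
                "miRNA %s contained in multiple genes: %s; keeping %s",
                mirna.mirna_gene_id,
                sorted({c[2] for c in intronic}),
                intronic[0][2],
            )
        _, _, gid, tid, idx, dist = intronic[0]
        return HostAssignment(
            mirna_gene_id=mirna.mirna_gene_id,
            category="intronic",
            host_gene_id=gid,
            host_transcript_id=tid,
            intron_index=idx,
            distance_to_upstream_exon=dist,
        )
    if exonic:
        exonic.sort()
        _, gid, tid = exonic[0]
        return HostAssignment(
            mirna_gene_id=mirna.mirna_gene_id,
            category="exonic",
            host_gene_id=gid,
            host_transcript_id=tid,
        )
    return HostAssignment(mirna_gene_id=mirna.mirna_gene_id, category="intergenic")


def find_seed_matches(
    utr: UtrSequence,
    mature_seq: str,
    *,
    mirna_gene_id: str = "",
    arm_name: str = "",
) -> list[SeedMatch]:
    """All canonical 7-nt seed sites for ``mature_seq`` in the UTR.

    7mer-m8: the UTR 7-mer equals the reverse complement of mature
    nucleotides 2-8 (1-based).  7mer-A1: it equals the reverse
    complement of nucleotides 2-7 followed by an A.  Overlapping sites
    are all reported; a position satisfying both rules is reported once
    as 7mer-m8.
    """
    mature = rna_normalise(mature_seq)
    if len(mature) < 8:
        raise ValueError("mature sequence must be at least 8 nt")
    site_m8 = revcomp_rna(mature[1:8])
    site_a1 = revcomp_rna(mature[1:7]) + "A"
    seq = utr.seq
    out = []
    for i in range(len(seq) - 6):
        window = seq[i : i + 7]
        if window == site_m8:
            out.append(
                SeedMatch(mirna_gene_id, arm_name, utr.gene_id, i, SITE_7MER_M8)
            )
        elif window == site_a1:
            out.append(
                SeedMatch(mirna_gene_id, arm_name, utr.gene_id, i, SITE_7MER_A1)
            )
    return out


def classify_host_targeting(
    assignments: Iterable[HostAssignment],
    mirnas: Iterable[MirnaRecord],
    utrs: Mapping[str, UtrSequence],
) -> list[HostTargetingCall]:
    """One HT/NT call per (miRNA gene, mature arm).

    Intergenic miRNAs are excluded.  An intragenic arm whose host lacks
    an annotated 3'UTR is called NT with zero matches (warned)."""
    amap = {a.mirna_gene_id: a for a in assignments}
    calls: list[HostTargetingCall] = []
    for m in sorted(mirnas, key=lambda r: r.mirna_gene_id):
        a = amap.get(m.mirna_gene_id)
        if a is None or a.category == "intergenic":
            continue
        utr = utrs.get(a.host_gene_id) if a.host_gene_id else None
        for arm in m.arms:
            if utr is None:
                logger.warning(
                    "host %s of %s has no annotated 3'UTR; arm %s called NT",
                    a.host_gene_id,
                    m.mirna_gene_id,
                    arm.name,
                )
                n = 0
            else:
                n = len(
                    find_seed_matches(
                        utr,
                        arm.mature_seq,
                        mirna_gene_id=m.mirna_gene_id,
                        arm_name=arm.name,
                    )
                )
            calls.append(
                HostTargetingCall(
                    mirna_gene_id=m.mirna_gene_id,
                    arm_name=arm.name,
                    host_gene_id=a.host_gene_id,
                    is_ht=n >= 1,
                    n_matches=n,
                )
            )
    return calls


@dataclass(frozen=True)
class CohortSummary:
    """HT-host vs NT-host comparison of UTR lengths and site counts.

    A gene hosting both HT and NT arms belongs to the HT host set.
    """

    n_ht_arms: int
    n_nt_arms: int
    n_ht_hosts: int
    n_nt_hosts: int
    total_seed_matches: int
    median_utr_len_ht: float | None
    median_utr_len_nt: float | None
    utr_len_test: TestResult | None
    median_sites_ht: float | None = None
    median_sites_nt: float | None = None
    site_count_test: TestResult | None = None


def cohort_summary(
    calls: Sequence[HostTargetingCall],
    utrs: Mapping[str, UtrSequence],
    apa_catalog=None,
) -> CohortSummary:
    """Summarise the HT/NT cohorts (UTR-length and APA-site medians with
    Mann-Whitney p-values).  ``apa_catalog`` is an
    :class:`~apafeedback.apa_discovery.ApaSiteCatalog` or None."""
    ht_hosts = {c.host_gene_id for c in calls if c.is_ht and c.host_gene_id}
    all_hosts = {c.host_gene_id for c in calls if c.host_gene_id}
    nt_hosts = all_hosts - ht_hosts

    def lengths(hosts):
        return [utrs[g].length for g in sorted(hosts) if g in utrs]

    ht_len, nt_len = lengths(ht_hosts), lengths(nt_hosts)
    utr_test = mann_whitney_u(ht_len, nt_len) if ht_len and nt_len else None

    med_sites_ht = med_sites_nt = site_test = None
    if apa_catalog is not None:
        ht_sites = [apa_catalog.site_count(g) for g in sorted(ht_hosts)]
        nt_sites = [apa_catalog.site_count(g) for g in sorted(nt_hosts)]
        if ht_sites and nt_sites:
            med_sites_ht = float(statistics.median(ht_sites))
            med_sites_nt = float(statistics.median(nt_sites))
            site_test = mann_whitney_u(ht_sites, nt_sites)

    return CohortSummary(
        n_ht_arms=sum(c.is_ht for c in calls),
        n_nt_arms=sum(not c.is_ht for c in calls),
        n_ht_hosts=len(ht_hosts),
        n_nt_hosts=len(nt_hosts),
        total_seed_matches=sum(c.n_matches for c in calls),
        median_utr_len_ht=float(statistics.median(ht_len)) if ht_len else None,
        median_utr_len_nt=float(statistics.median(nt_len)) if nt_len else None,
        utr_len_test=utr_test,
        median_sites_ht=med_sites_ht,
        median_sites_nt=med_sites_nt,
        site_count_test=site_test,
    )
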