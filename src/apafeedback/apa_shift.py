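"""Differential 3'UTR usage between two RNA-Seq conditions.

Each gene's 3'UTR is partitioned into poly(A) regions — region k spans
(site_{k-1}, site_k] in UTR coordinates, with region 1 anchored at the
UTR start — reads are assigned to the region holding their 3'-most
aligned base, per-region counts are compared with a two-sided binomial
test against the library-size proportion, q-values come from one
genome-wide Benjamini-Hochberg family, and a gene is called *longer*
(prolonged) when the median index of significantly upregulated regions
exceeds the median index of significantly downregulated regions, and
*shorter* otherwise — provided it has at least one of each.  Median
ties go to *shorter* and are flagged.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomeAccessor,
    Interval,
    ReadPlacement,
    UtrSequence,
)
from .apa_discovery import ApaSite
from .stats_core import bh_adjust, binomial_two_sided

logger = logging.getLogger(__name__)

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"

CALL_SHORTER = "shorter"
CALL_LONGER = "longer"
CALL_NONE = "not_called"


@dataclass
class PolyARegion:
    """Poly(A) region k of a gene: UTR offsets in (start, end]."""

    gene_id: str
    index: int  # 1-based, proximal -> distal
    start: int
    end: int
    count_study: int = 0
    count_control: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("region span must satisfy 0 <= start < end")


@dataclass
class RegionTest:
    region: PolyARegion
    p_value: float
    q_value: float
    direction: str


@dataclass(frozen=True)
class UtrShiftCall:
    gene_id: str
    call: str  # shorter | longer | not_called
    median_up_index: float | None = None
    median_down_index: float | None = None
    tie: bool = False


def partition_polya_regions(
    utr: UtrSequence | int, sites: Sequence[ApaSite]
) -> list[PolyARegion]:
    """K regions for K sites: (0, s1], (s1, s2], ..., (s_{K-1}, s_K].

    Genes without sites yield no regions (excluded from the shift
    analysis).  Site offsets must be strictly increasing, positive, and
    within the UTR.
    """
    utr_len = utr if isinstance(utr, int) else utr.length
    if not sites:
        return []
    offsets = [s.utr_offset for s in sites]
    if any(o is None for o in offsets):
        raise ValueError("sites must carry UTR offsets")
    if offsets != sorted(offsets) or len(set(offsets)) != len(offsets):
        raise ValueError("site offsets must be strictly increasing")
    if offsets[0] <= 0 or offsets[-1] > utr_len:
        raise ValueError("site offsets must lie in (0, UTR length]")
    gene_id = sites[0].gene_id
    regions = []
    prev = 0
    for k, off in enumerate(offsets, start=1):
        regions.append(PolyARegion(gene_id=gene_id, index=k, start=prev, end=off))
        prev = off
    return regions


def read_end_utr_offset(placement: ReadPlacement, utr_genomic: Interval) -> int:
    """UTR-coordinate end offset of a read: the boundary after its
    3'-most aligned base in transcription order."""
    if utr_genomic.strand == "+":
        return placement.aligned.end - utr_genomic.start
    return utr_genomic.end - placement.aligned.start


def count_reads_by_region(
    regions: Sequence[PolyARegion],
    study_end_offsets: Iterable[int],
    control_end_offsets: Iterable[int],
) -> tuple[int, int]:
    """Assign read end offsets to regions (right-closed spans); offsets
    outside all regions are ignored.  Returns the number of assigned
    reads per condition; counts accumulate on the regions in place."""
    import bisect

    ends = [r.end for r in regions]
    lo = regions[0].start if regions else 0

    def assign(offsets, attr):
        n = 0
        for o in offsets:
            if o <= lo or (ends and o > ends[-1]):
                continue
            k = bisect.bisect_left(ends, o)
            r = regions[k]
            setattr(r, attr, getattr(r, attr) + 1)
            n += 1
        return n

    return assign(study_end_offsets, "count_study"), assign(
        control_end_offsets, "count_control"
    )


def test_regions(
    regions: Sequence[PolyARegion],
    lib_study: int,
    lib_control: int,
    alpha: float = 0.05,
) -> list[RegionTest]:
    """Binomial test per region against p0 = lib_study / (lib_study +
    lib_control); q-values from one BH family over all regions passed
    (genome-wide by convention)."""
    if lib_study <= 0 or lib_control <= 0:
        raise ValueError("library sizes must be positive")
    p0 = lib_study / (lib_study + lib_control)
    pvals = []
    for r in regions:
        n = r.count_study + r.count_control
        pvals.append(binomial_two_sided(r.count_study, n, p0).p_value if n else 1.0)
    qvals = bh_adjust(pvals)
    out = []
    for r, p, q in zip(regions, pvals, qvals):
        n = r.count_study + r.count_control
        direction = DIRECTION_NONE
        if n > 0 and q < alpha:
            frac = r.count_study / n
            if frac > p0:
                direction = DIRECTION_UP
            elif frac < p0:
                direction = DIRECTION_DOWN
        out.append(RegionTest(region=r, p_value=p, q_value=q, direction=direction))
    return out


def call_utr_shift(tests: Sequence[RegionTest], gene_id: str | None = None) -> UtrShiftCall:
    """Median-index rule for one gene's region tests."""
    if gene_id is None:
        gene_id = tests[0].region.gene_id if tests else ""
    ups = [t.region.index for t in tests if t.direction == DIRECTION_UP]
    downs = [t.region.index for t in tests if t.direction == DIRECTION_DOWN]
    if not ups or not downs:
        return UtrShiftCall(gene_id=gene_id, call=CALL_NONE)
    m_up = float(statistics.median(ups))
    m_down = float(statistics.median(downs))
    if m_up > m_down:
        call = CALL_LONGER
    else:
        call = CALL_SHORTER  # "and shortened otherwise": ties included
    return UtrShiftCall(
        gene_id=gene_id,
        call=call,
        median_up_index=m_up,
        median_down_index=m_down,
        tie=m_up == m_down,
    )


def call_utr_shifts(tests: Sequence[RegionTest]) -> list[UtrShiftCall]:
    """Group region tests by gene and call each gene."""
    by_gene: dict[str, list[RegionTest]] = {}
    for t in tests:
        by_gene.setdefault(t.region.gene_id, []).append(t)
    return [call_utr_shift(by_gene[g], g) for g in sorted(by_gene)]


def filter_genes_for_depth(
    regions_by_gene: Mapping[str, Sequence[PolyARegion]], min_total: int = 20
) -> set[str]:
    """Genes whose summed study+control counts reach ``min_total``."""
    return {
        g
        for g, regions in regions_by_gene.items()
        if sum(r.count_study + r.count_control for r in regions) >= min_total
    }


def summarize_shift_by_class(
    calls: Sequence[UtrShiftCall], class_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-class table of called genes: n_called, n_shorter, n_longer,
    fraction_shorter.  Genes missing from ``class_of`` count as
    'other'."""
    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        if c.call == CALL_NONE:
            continue
        cls = class_of.get(c.gene_id, "other")
        row = rows.setdefault(cls, {"n_called": 0, "n_shorter": 0, "n_longer": 0})
        row["n_called"] += 1
        if c.call == CALL_SHORTER:
            row["n_shorter"] += 1
        else:
            row["n_longer"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=["n_called", "n_shorter", "n_longer"])
    df["fraction_shorter"] = df["n_shorter"] / df["n_called"] if len(df) else []
    df.index.name = "class"
    return df


def export_upstream_sequences(
    sites: Iterable[ApaSite],
    genome: GenomeAccessor,
    path_or_handle,
    window: int = 40,
) -> int:
    """FASTA of the ``window`` nt immediately 5' of each cleavage
    boundary on the sense strand (DNA).  Sites closer than ``window`` nt
    to the UTR start yield truncated records with a warning.  Returns
    the number of records written."""
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "w") if own else path_or_handle
    n = 0
    try:
        for site in sites:
            w = window
            if site.utr_offset is not None and site.utr_offset < window:
                w = site.utr_offset
                logger.warning(
                    "site %s only %d nt from UTR start; truncated record",
                    site.site_id,
                    w,
                )
            if w <= 0:
                continue
            if site.strand == "+":
                seq = genome.fetch(site.chrom, site.position - w, site.position)
            else:
                seq = genome.fetch_transcribed(
                    site.chrom, site.position, site.position + w, "-"
                )
            fh.write(f">{site.site_id}\n{seq}\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n
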