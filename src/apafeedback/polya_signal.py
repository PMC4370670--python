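"""Canonical polyadenylation-signal scanning and positional analysis.

The two canonical hexamers AAUAAA and AUUAAA are scanned over 3'UTR
sequences (overlapping occurrences included).  Relative positions are
(1-based hit position) / UTR length, in (0, 1].  Seed matches are
annotated for APA influence (an upstream poly(A) site exists, so a
shorter isoform would lose the site) and for precedence by a canonical
signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import UtrSequence
from .apa_discovery import ApaSiteCatalog
from .mirna_host import SeedMatch
from .stats_core import TestResult, mann_whitney_u

CANONICAL_MOTIFS = ("AAUAAA", "AUUAAA")
MOTIF_LEN = 6


@dataclass(frozen=True)
class SignalHit:
    gene_id: str
    motif: str
    utr_offset: int  # 0-based start within the UTR
    relative_position: float  # (utr_offset + 1) / UTR length

    def __post_init__(self) -> None:
        if not (0.0 < self.relative_position <= 1.0):
            raise ValueError("relative position outside (0, 1]")


def scan_polya_signals(utr: UtrSequence) -> list[SignalHit]:
    """Every occurrence of each canonical motif, sorted by position."""
    if utr.length == 0:
        raise ValueError("empty UTR")
    hits = []
    for motif in CANONICAL_MOTIFS:
        i = utr.seq.find(motif)
        while i != -1:
            hits.append(
                SignalHit(
                    gene_id=utr.gene_id,
                    motif=motif,
                    utr_offset=i,
                    relative_position=(i + 1) / utr.length,
                )
            )
            i = utr.seq.find(motif, i + 1)
    hits.sort(key=lambda h: (h.utr_offset, h.motif))
    return hits


def relative_positions(hits: Sequence[SignalHit], utr_len: int) -> list[float]:
    """Relative positions (1-based position / UTR length) of hits."""
    if utr_len < 1:
        raise ValueError("UTR length must be >= 1")
    return [(h.utr_offset + 1) / utr_len for h in hits]


@dataclass(frozen=True)
class PositionComparison:
    median_ht: float
    median_nt: float
    test: TestResult


def compare_signal_position_distributions(
    ht_positions: Sequence[float], nt_positions: Sequence[float]
) -> PositionComparison:
    """Medians of relative signal positions per cohort plus a two-sided
    Mann-Whitney-U test."""
    import statistics

    if not ht_positions or not nt_positions:
        raise ValueError("both position collections must be non-empty")
    return PositionComparison(
        median_ht=float(statistics.median(ht_positions)),
        median_nt=float(statistics.median(nt_positions)),
        test=mann_whitney_u(ht_positions, nt_positions),
    )


@dataclass(frozen=True)
class SeedMatchAnnotation:
    match: SeedMatch
    apa_influenced: bool
    preceded_by_canonical: bool


def annotate_seed_match_apa(
    matches: Iterable[SeedMatch],
    catalog: ApaSiteCatalog,
    signals: Iterable[SignalHit],
    *,
    preceded_mode: str = "any_upstream",
    near_site_range: tuple[int, int] = (10, 40),
) -> list[SeedMatchAnnotation]:
    """Per-match flags.

    apa_influenced: some poly(A) site lies strictly between the UTR
    start and the match start (a shorter isoform lacks the site).

    preceded_by_canonical: with ``preceded_mode="any_upstream"`` (the
    default) some canonical motif ends at or before the match start;
    with ``"near_upstream_site"`` additionally a motif must end 10-40 nt
    upstream of a poly(A) site that itself precedes the match.
    """
    if preceded_mode not in ("any_upstream", "near_upstream_site"):
        raise ValueError(f"unknown preceded_mode {preceded_mode!r}")
    sig_by_gene: dict[str, list[SignalHit]] = {}
    for h in signals:
        sig_by_gene.setdefault(h.gene_id, []).append(h)

    out = []
    for m in matches:
        sites = [
            s.utr_offset
            for s in catalog.sites_for(m.gene_id)
            if s.utr_offset is not None
        ]
        influenced = any(0 < s < m.utr_offset for s in sites)
        gene_sigs = sig_by_gene.get(m.gene_id, [])
        if preceded_mode == "any_upstream":
            preceded = any(
                h.utr_offset + MOTIF_LEN <= m.utr_offset for h in gene_sigs
            )
        else:
            lo, hi = near_site_range
            preceded = any(
                h.utr_offset + MOTIF_LEN <= m.utr_offset
                and any(
                    0 < s < m.utr_offset
                    and lo <= s - (h.utr_offset + MOTIF_LEN) <= hi
                    for s in sites
                )
                for h in gene_sigs
            )
        out.append(
            SeedMatchAnnotation(
                match=m, apa_influenced=influenced, preceded_by_canonical=preceded
            )
        )
    return out
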