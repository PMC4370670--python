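"""Poly(A)-site discovery: 3'-tail evidence, internal-priming filtering,
40-nt clustering and the per-gene site catalog.

Evidence sources
----------------
EST-style reads contribute a site when their 3' soft clip ends in a run
of more than 10 untemplated adenines and the genomic window downstream
of the cleavage point is not adenine-rich (internal-priming filter).
RNA-Seq reads support a site when at least two reads carry >= 2
untemplated terminal A's and at least two of them differ in aligned
length.  External site lists arrive as BED6.  All cleavage positions
are inter-base boundaries (see :mod:`apafeedback.annotation_io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_io import (
    AnnotationError,
    GeneModel,
    GenomeAccessor,
    Interval,
    ReadPlacement,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

SOURCE_EST = "EST"
SOURCE_RNASEQ = "RNASEQ"
SOURCE_EXTERNAL = "EXTERNAL"

#: minimal length of the untemplated terminal A-run ("more than 10")
MIN_TAIL_A = 11
#: internal-priming window downstream of the cleavage point (nt)
PRIMING_WINDOW = 20
#: reject when the window holds >= this many A's ...
PRIMING_MAX_A = 12
#: ... or an A-run at least this long
PRIMING_MAX_RUN = 6
#: single-linkage clustering gap
CLUSTER_MAX_GAP = 40


@dataclass(frozen=True)
class TailEvidence:
    """One item of cleavage evidence at an inter-base boundary."""

    chrom: str
    cleavage_pos: int
    strand: str
    tail_len: int
    source: str
    read_id: str = ""
    aligned_length: int = 0

    def __post_init__(self) -> None:
        if self.tail_len < 0 or self.cleavage_pos < 0:
            raise ValueError("negative tail length or cleavage position")


@dataclass
class ApaSite:
    """A clustered cleavage site; ``position`` is the representative
    member (maximal support, ties to the most CDS-proximal member)."""

    site_id: str
    chrom: str
    position: int
    strand: str
    gene_id: str = ""
    utr_offset: int | None = None
    support: dict[str, int] = field(default_factory=dict)
    members: tuple[int, ...] = ()

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class ApaSiteCatalog:
    """Per-gene poly(A) sites, sorted proximal -> distal."""

    sites_by_gene: dict[str, list[ApaSite]] = field(default_factory=dict)

    def sites_for(self, gene_id: str) -> list[ApaSite]:
        return self.sites_by_gene.get(gene_id, [])

    def site_count(self, gene_id: str) -> int:
        return len(self.sites_by_gene.get(gene_id, []))

    def all_sites(self) -> list[ApaSite]:
        return [s for g in sorted(self.sites_by_gene) for s in self.sites_by_gene[g]]

    @property
    def n_genes(self) -> int:
        return len(self.sites_by_gene)


def _terminal_a_run(seq: str) -> int:
    n = 0
    for ch in reversed(seq.upper()):
        if ch != "A":
            break
        n += 1
    return n


def _max_a_run(seq: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == "A" else 0
        best = max(best, cur)
    return best


def _cleavage_boundary(placement: ReadPlacement) -> int:
    return placement.aligned.end if placement.aligned.strand == "+" else placement.aligned.start


def _downstream_sense(
    genome: GenomeAccessor, chrom: str, pos: int, strand: str, n: int
) -> str:
    """``n`` genomic nt downstream of boundary ``pos`` in transcription
    order, on the sense strand (may be shorter near chromosome ends)."""
    if strand == "+":
        return genome.fetch(chrom, pos, pos + n)
    return genome.fetch_transcribed(chrom, pos - n, pos, "-")


def detect_est_tail(
    placement: ReadPlacement,
    genome: GenomeAccessor,
    *,
    min_tail: int = MIN_TAIL_A,
    priming_window: int = PRIMING_WINDOW,
    priming_max_a: int = PRIMING_MAX_A,
    priming_max_run: int = PRIMING_MAX_RUN,
) -> TailEvidence | None:
    """EST tail rule: terminal clip A-run >= ``min_tail``, untemplated,
    and the downstream window passes the internal-priming filter.

    Returns None (not an error) for reads without qualifying clips.
    """
    tail = _terminal_a_run(placement.clipped_tail_3p)
    if tail < min_tail:
        return None
    chrom = placement.aligned.chrom
    strand = placement.aligned.strand
    pos = _cleavage_boundary(placement)
    window = _downstream_sense(genome, chrom, pos, strand, max(priming_window, tail))
    # untemplated requirement: the tail cannot be read off the genome
    if len(window) >= tail and window[:tail] == "A" * tail:
        return None
    prim = window[:priming_window]
    if prim.count("A") >= priming_max_a or _max_a_run(prim) >= priming_max_run:
        return None
    return TailEvidence(
        chrom=chrom,
        cleavage_pos=pos,
        strand=strand,
        tail_len=tail,
        source=SOURCE_EST,
        read_id=placement.read_id,
        aligned_length=placement.aligned_length,
    )


def detect_rnaseq_tail(
    placements: Sequence[ReadPlacement],
    genome: GenomeAccessor,
    *,
    min_tail: int = 2,
) -> list[TailEvidence] | None:
    """RNA-Seq site rule at one candidate cleavage position.

    The position is supported iff >= 2 reads each carry >= ``min_tail``
    untemplated terminal A's and at least two supporting reads differ in
    aligned length.  Returns the supporting evidence, or None.
    """
    if not placements:
        return None
    pos0 = _cleavage_boundary(placements[0])
    supporting = []
    for p in placements:
        if _cleavage_boundary(p) != pos0:
            raise ValueError("placements do not share a cleavage position")
        tail = _terminal_a_run(p.clipped_tail_3p)
        if tail < min_tail:
            continue
        down = _downstream_sense(
            genome, p.aligned.chrom, pos0, p.aligned.strand, min_tail
        )
        if len(down) >= min_tail and down == "A" * len(down):
            continue  # templated
        supporting.append(
            TailEvidence(
                chrom=p.aligned.chrom,
                cleavage_pos=pos0,
                strand=p.aligned.strand,
                tail_len=tail,
                source=SOURCE_RNASEQ,
                read_id=p.read_id,
                aligned_length=p.aligned_length,
            )
        )
    if len(supporting) < 2:
        return None
    if len({e.aligned_length for e in supporting}) < 2:
        return None
    return supporting


def cluster_apa_sites(
    evidence: Iterable[TailEvidence | tuple],
    max_gap: int = CLUSTER_MAX_GAP,
    strand: str = "+",
) -> list[ApaSite]:
    """Single-linkage clustering of cleavage positions.

    Adjacent positions at most ``max_gap`` nt apart join one cluster.
    The representative is the member with maximal total support; ties
    break to the most CDS-proximal member (smallest position on +,
    largest on -).  Accepts TailEvidence or (position, source) pairs.
    """
    items: list[tuple[int, str, str]] = []  # (pos, source, chrom)
    for e in evidence:
        if isinstance(e, TailEvidence):
            items.append((e.cleavage_pos, e.source, e.chrom))
        else:
            pos, source = e[0], e[1]
            items.append((int(pos), str(source), ""))
    if not items:
        return []
    items.sort(key=lambda t: t[0])
    chrom = next((c for _, _, c in items if c), "")

    clusters: list[list[tuple[int, str]]] = [[items[0][:2]]]
    for pos, source, _ in items[1:]:
        if pos - clusters[-1][-1][0] <= max_gap:
            clusters[-1].append((pos, source))
        else:
            clusters.append([(pos, source)])

    out = []
    for members in clusters:
        per_pos: dict[int, int] = {}
        support: dict[str, int] = {}
        for pos, source in members:
            per_pos[pos] = per_pos.get(pos, 0) + 1
            support[source] = support.get(source, 0) + 1
        proximal_sign = 1 if strand == "+" else -1
        rep = min(per_pos, key=lambda p: (-per_pos[p], proximal_sign * p))
        out.append(
            ApaSite(
                site_id="",
                chrom=chrom,
                position=rep,
                strand=strand,
                support=support,
                members=tuple(sorted(per_pos)),
            )
        )
    return out


def load_external_sites(path: str | Path) -> list[TailEvidence]:
    """BED6 poly(A)-site list -> external evidence.

    The cleavage boundary is the feature end on + and the feature start
    on - (single-base features recommended).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AnnotationError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            pos = int(end) if strand == "+" else int(start)
            out.append(
                TailEvidence(
                    chrom=chrom,
                    cleavage_pos=pos,
                    strand=strand,
                    tail_len=0,
                    source=SOURCE_EXTERNAL,
                    read_id=name,
                )
            )
    return out


def _utr_offset_of_boundary(pos: int, t: TranscriptModel) -> int | None:
    if t.utr3 is None:
        return None
    return pos - t.utr3.start if t.strand == "+" else t.utr3.end - pos


def _assign_gene(
    e: TailEvidence, genes: Mapping[str, GeneModel]
) -> GeneModel | None:
    """Map evidence to the gene whose longest transcript contains the
    boundary on the matching strand; UTR-containing genes win ties."""
    best = None
    for gid in sorted(genes):
        t = genes[gid].longest_transcript
        span = t.span
        if span.chrom != e.chrom or t.strand != e.strand:
            continue
        if not (span.start <= e.cleavage_pos <= span.end):
            continue
        off = _utr_offset_of_boundary(e.cleavage_pos, t)
        in_utr = off is not None and 0 <= off <= t.utr3.length
        if best is None or (in_utr and not best[1]):
            best = (genes[gid], in_utr)
    return best[0] if best else None


def build_catalog(
    est_evidence: Iterable[TailEvidence],
    rnaseq_evidence: Iterable[TailEvidence],
    external_bed: str | Path | None,
    genes: Mapping[str, GeneModel],
    *,
    max_gap: int = CLUSTER_MAX_GAP,
) -> ApaSiteCatalog:
    """Union the three evidence sources, cluster jointly per gene, and
    keep sites inside the longest transcript's annotated 3'UTR.

    Evidence outside every longest transcript (or on an unknown
    chromosome) is skipped with a warning, as are clustered sites
    upstream of the UTR start (their UTR offset would be negative).
    """
    evidence = list(est_evidence) + list(rnaseq_evidence)
    if external_bed is not None:
        evidence.extend(load_external_sites(external_bed))

    known_chroms = {
        g.longest_transcript.chrom for g in genes.values()
    }
    per_gene: dict[str, list[TailEvidence]] = {}
    for e in evidence:
        if e.chrom not in known_chroms:
            logger.warning("evidence on unknown chromosome %s skipped", e.chrom)
            continue
        gene = _assign_gene(e, genes)
        if gene is None:
            logger.debug(
                "evidence at %s:%d outside all longest transcripts", e.chrom, e.cleavage_pos
            )
            continue
        per_gene.setdefault(gene.gene_id, []).append(e)

    catalog = ApaSiteCatalog()
    for gid in sorted(per_gene):
        t = genes[gid].longest_transcript
        clusters = cluster_apa_sites(per_gene[gid], max_gap=max_gap, strand=t.strand)
        kept = []
        for site in clusters:
            off = _utr_offset_of_boundary(site.position, t)
            if off is None or off < 0:
                logger.warning(
                    "gene %s: clustered site at %d upstream of 3'UTR; discarded",
                    gid,
                    site.position,
                )
                continue
            site.gene_id = gid
            site.utr_offset = off
            site.chrom = t.chrom
            kept.append(site)
        kept.sort(key=lambda s: s.utr_offset)
        for k, site in enumerate(kept, start=1):
            site.site_id = f"{gid}:s{k}"
        if kept:
            catalog.sites_by_gene[gid] = kept
    return catalog


def write_catalog_bed(catalog: ApaSiteCatalog, path: str | Path) -> None:
    """BED6: chrom, site position, position+1, site_id, total support,
    strand (0-based)."""
    with open(path, "w") as fh:
        for site in catalog.all_sites():
            fh.write(
                f"{site.chrom}\t{site.position}\t{site.position + 1}\t"
                f"{site.site_id}\t{site.total_support}\t{site.strand}\n"
            )
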