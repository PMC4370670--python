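"""Genomic annotation I/O and the in-memory annotation bundle.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open intervals on the genome;
GFF3 input/output converts to/from the format's 1-based inclusive
convention.  Cleavage positions (poly(A) sites) are represented as
inter-base *boundaries*: the boundary after the last templated base in
transcription order is ``aligned.end`` on the plus strand and
``aligned.start`` on the minus strand.  UTR coordinates run in
transcription order starting at 0 at the annotated 3'UTR start.

Sequence alphabets: the genome is DNA (upper-case A/C/G/T/N); extracted
3'UTR sequences and mature miRNA sequences are normalised to RNA (T->U).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pyfaidx
import pysam

logger = logging.getLogger(__name__)

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(RNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_normalise(seq: str) -> str:
    """Upper-case and convert any T to U."""
    return seq.upper().replace("T", "U")


class AnnotationError(ValueError):
    """Malformed or internally inconsistent annotation input."""


class ConsistencyError(AnnotationError):
    """Cross-file references that do not resolve."""


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript structure: exons, CDS end and annotated 3'UTR.

    ``cds_end_genomic`` is the 0-based genomic position of the last CDS
    base in transcription order (the highest CDS coordinate on +, the
    lowest on -).  ``utr3`` is the genomic span of the annotated 3'UTR
    (assumed contiguous, i.e. contained in the terminal exon).
    """

    transcript_id: str
    exons: tuple[Interval, ...]
    cds_end_genomic: int | None = None
    utr3: Interval | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise AnnotationError(
                f"transcript {self.transcript_id}: exons not sorted by start"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Interval:
        return Interval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> tuple[Interval, ...]:
        """Introns in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def introns_transcription_order(self) -> tuple[Interval, ...]:
        ins = self.introns()
        return ins if self.strand == "+" else tuple(reversed(ins))


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts; the longest transcript (maximal genomic
    span, ties broken by lexicographically smallest id) anchors all
    UTR-level analyses."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    longest_transcript_id: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        if not self.longest_transcript_id:
            best = sorted(
                self.transcripts, key=lambda t: (-t.span.length, t.transcript_id)
            )[0]
            object.__setattr__(self, "longest_transcript_id", best.transcript_id)
        elif self.longest_transcript_id not in {
            t.transcript_id for t in self.transcripts
        }:
            raise AnnotationError(
                f"gene {self.gene_id}: unknown longest transcript "
                f"{self.longest_transcript_id}"
            )

    @property
    def longest_transcript(self) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == self.longest_transcript_id:
                return t
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class UtrSequence:
    """3'UTR sequence in mRNA sense orientation (RNA alphabet)."""

    gene_id: str
    seq: str
    genomic: Interval

    def __post_init__(self) -> None:
        if set(self.seq) - set("ACGUN"):
            raise AnnotationError(
                f"UTR of {self.gene_id} contains non-RNA characters"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureArm:
    """One mature arm of a miRNA gene (RNA alphabet)."""

    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        if len(self.mature_seq) < 8:
            raise AnnotationError(
                f"mature arm {self.name}: sequence shorter than 8 nt"
            )
        if set(self.mature_seq) - set("ACGUN"):
            raise AnnotationError(f"mature arm {self.name}: not RNA")

    @property
    def seed_2_8(self) -> str:
        """Nucleotides 2-8 (1-based) of the mature sequence."""
        return self.mature_seq[1:8]


@dataclass(frozen=True)
class MirnaRecord:
    mirna_gene_id: str
    locus: Interval
    arms: tuple[MatureArm, ...] = ()


@dataclass(frozen=True)
class ReadPlacement:
    """A filtered alignment; ``clipped_tail_3p`` holds 3' soft-clipped
    bases in read orientation (DNA)."""

    read_id: str
    aligned: Interval
    mapq: int
    unique: bool
    clipped_tail_3p: str = ""

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise AnnotationError(f"read {self.read_id}: negative MAPQ")

    @property
    def aligned_length(self) -> int:
        return self.aligned.length


class GenomeAccessor:
    """Random access to genome sequence.

    Backed by pyfaidx for FASTA files, or by a plain mapping of
    chromosome name to sequence string (used by the simulator and in
    tests).  Fetches are clamped to chromosome bounds and returned
    upper-case.
    """

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            self._fasta: pyfaidx.Fasta | None = pyfaidx.Fasta(str(source))
            self._dict: dict[str, str] | None = None
        else:
            self._fasta = None
            self._dict = {k: str(v).upper() for k, v in source.items()}

    def chroms(self) -> list[str]:
        if self._dict is not None:
            return sorted(self._dict)
        return sorted(self._fasta.keys())  # type: ignore[union-attr]

    def __contains__(self, chrom: str) -> bool:
        if self._dict is not None:
            return chrom in self._dict
        return chrom in self._fasta  # type: ignore[operator]

    def chrom_length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])  # type: ignore[index]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand DNA over [start, end), clamped to the chromosome."""
        n = self.chrom_length(chrom)
        start, end = max(0, start), min(n, end)
        if start >= end:
            return ""
        if self._dict is not None:
            return self._dict[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()  # type: ignore[index]

    def fetch_transcribed(self, chrom: str, start: int, end: int, strand: str) -> str:
        """Sense-strand DNA (reverse-complemented for minus strand)."""
        seq = self.fetch(chrom, start, end)
        return seq if strand == "+" else revcomp_dna(seq)


@dataclass
class AnnotationBundle:
    genes: dict[str, GeneModel]
    mirnas: list[MirnaRecord]
    genome: GenomeAccessor


# ---------------------------------------------------------------------------
# GFF3 / FASTA / mature-TSV loading
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _open_gff(path: str | Path):
    import gffutils

    try:
        return gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a zoo of exception types
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc


def _feature_interval(f, path) -> Interval:
    try:
        return Interval(f.seqid, f.start - 1, f.end, f.strand)
    except AnnotationError as exc:
        raise AnnotationError(
            f"{path}: bad coordinates on {f.featuretype} line for "
            f"{f.id or f.attributes}: {exc}"
        ) from exc


def load_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Parse a gene-model GFF3 (gene -> mRNA/transcript -> exon/CDS/
    three_prime_UTR) into GeneModel objects keyed by gene id."""
    db = _open_gff(path)
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=_TRANSCRIPT_TYPES, order_by="start"):
            exons = tuple(
                sorted(
                    (
                        _feature_interval(e, path)
                        for e in db.children(t, featuretype="exon")
                    ),
                    key=lambda iv: iv.start,
                )
            )
            cds = [_feature_interval(c, path) for c in db.children(t, featuretype="CDS")]
            cds_end = None
            if cds:
                if t.strand == "+":
                    cds_end = max(c.end for c in cds) - 1
                else:
                    cds_end = min(c.start for c in cds)
            utr_feats = [
                _feature_interval(u, path)
                for u in db.children(t, featuretype="three_prime_UTR")
            ]
            utr3 = None
            if utr_feats:
                if len(utr_feats) > 1:
                    logger.warning(
                        "transcript %s: %d three_prime_UTR segments; using span",
                        t.id,
                        len(utr_feats),
                    )
                utr3 = Interval(
                    utr_feats[0].chrom,
                    min(u.start for u in utr_feats),
                    max(u.end for u in utr_feats),
                    t.strand,
                )
            transcripts.append(
                TranscriptModel(
                    transcript_id=t.id,
                    exons=exons,
                    cds_end_genomic=cds_end,
                    utr3=utr3,
                )
            )
        if not transcripts:
            raise AnnotationError(f"{path}: gene {g.id} has no transcripts")
        genes[g.id] = GeneModel(gene_id=g.id, transcripts=tuple(transcripts))
    if not genes:
        raise AnnotationError(f"{path}: no gene features found")
    return genes


_MIRNA_TYPES = ("miRNA_primary_transcript", "miRNA", "gene")


def load_mirna_records(
    mirna_gff3: str | Path, mature_tsv: str | Path
) -> list[MirnaRecord]:
    """Load miRNA loci (GFF3, miRBase-style) plus mature arm sequences.

    The mature TSV has columns mirna_gene_id, arm_name, mature_seq
    (tab-separated, ``#`` comment lines allowed).  Every locus must have
    at least one arm; arms referencing unknown loci raise
    ConsistencyError.
    """
    db = _open_gff(mirna_gff3)
    loci: dict[str, Interval] = {}
    for ftype in _MIRNA_TYPES:
        for f in db.features_of_type(ftype):
            if f.id not in loci:
                loci[f.id] = _feature_interval(f, mirna_gff3)
    if not loci:
        raise AnnotationError(f"{mirna_gff3}: no miRNA features found")

    arms: dict[str, list[MatureArm]] = {mid: [] for mid in loci}
    with open(mature_tsv) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(
                    f"{mature_tsv}:{lineno}: expected 3 tab-separated columns"
                )
            mid, arm_name, seq = parts[0], parts[1], rna_normalise(parts[2])
            if mid == "mirna_gene_id":  # header row
                continue
            if mid not in arms:
                raise ConsistencyError(
                    f"{mature_tsv}:{lineno}: mature arm references unknown "
                    f"miRNA gene {mid!r}"
                )
            arms[mid].append(MatureArm(arm_name, seq))
    missing = [mid for mid, a in arms.items() if not a]
    if missing:
        raise ConsistencyError(
            f"miRNA genes without mature arms in {mature_tsv}: {missing}"
        )
    return [
        MirnaRecord(mid, loci[mid], tuple(arms[mid])) for mid in sorted(loci)
    ]


def load_annotation_bundle(
    gene_gff3: str | Path,
    mirna_gff3: str | Path,
    mature_tsv: str | Path,
    genome_fasta: str | Path | Mapping[str, str],
) -> AnnotationBundle:
    genes = load_gene_models(gene_gff3)
    mirnas = load_mirna_records(mirna_gff3, mature_tsv)
    genome = GenomeAccessor(genome_fasta)
    return AnnotationBundle(genes=genes, mirnas=mirnas, genome=genome)


def write_gene_models_gff3(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Serialise gene models back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            gene = genes[gid]
            spans = [t.span for t in gene.transcripts]
            chrom = spans[0].chrom
            strand = spans[0].strand
            gstart = min(s.start for s in spans)
            gend = max(s.end for s in spans)
            fh.write(
                f"{chrom}\tapafeedback\tgene\t{gstart + 1}\t{gend}\t.\t{strand}"
                f"\t.\tID={gid}\n"
            )
            for t in gene.transcripts:
                s = t.span
                fh.write(
                    f"{chrom}\tapafeedback\tmRNA\t{s.start + 1}\t{s.end}\t.\t"
                    f"{strand}\t.\tID={t.transcript_id};Parent={gid}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{chrom}\tapafeedback\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{strand}\t.\tParent={t.transcript_id}\n"
                    )
                if t.cds_end_genomic is not None:
                    # Reconstructable CDS span: from transcript start (first
                    # exon boundary) to the recorded CDS end.  Exact CDS
                    # segmentation is not retained; emit a single CDS line
                    # per exon overlapping the CDS span.
                    if strand == "+":
                        cstart, cend = t.exons[0].start, t.cds_end_genomic + 1
                    else:
                        cstart, cend = t.cds_end_genomic, t.exons[-1].end
                    if t.utr3 is not None:
                        if strand == "+":
                            cend = min(cend, t.utr3.start)
                        else:
                            cstart = max(cstart, t.utr3.end)
                    for e in t.exons:
                        lo, hi = max(e.start, cstart), min(e.end, cend)
                        if lo < hi:
                            fh.write(
                                f"{chrom}\tapafeedback\tCDS\t{lo + 1}\t{hi}\t.\t"
                                f"{strand}\t.\tParent={t.transcript_id}\n"
                            )
                if t.utr3 is not None:
                    u = t.utr3
                    fh.write(
                        f"{chrom}\tapafeedback\tthree_prime_UTR\t{u.start + 1}\t"
                        f"{u.end}\t.\t{strand}\t.\tParent={t.transcript_id}\n"
                    )


def extract_utr_sequence(
    gene: GeneModel, genome: GenomeAccessor
) -> UtrSequence | None:
    """3'UTR of the gene's longest transcript in mRNA sense (RNA).

    Returns None when the longest transcript carries no annotated 3'UTR
    (an expected condition, not a parse failure).
    """
    t = gene.longest_transcript
    if t.utr3 is None:
        return None
    dna = genome.fetch(t.utr3.chrom, t.utr3.start, t.utr3.end)
    if len(dna) != t.utr3.length:
        raise AnnotationError(
            f"gene {gene.gene_id}: 3'UTR {t.utr3} extends beyond chromosome"
        )
    if t.strand == "-":
        dna = revcomp_dna(dna)
    return UtrSequence(gene_id=gene.gene_id, seq=dna_to_rna(dna), genomic=t.utr3)


# ---------------------------------------------------------------------------
# Read placements (SAM or simplified TSV)
# ---------------------------------------------------------------------------

TSV_READ_COLUMNS = (
    "read_id",
    "chrom",
    "start",
    "end",
    "strand",
    "mapq",
    "unique",
    "clipped_tail_3p",
)

_TRUE_STRINGS = {"1", "true", "yes", "y"}


def _load_placements_sam(path, min_mapq, require_unique):
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            unique = a.mapping_quality >= min_mapq
            if a.has_tag("NH"):
                unique = unique and a.get_tag("NH") == 1
            if a.mapping_quality < min_mapq or (require_unique and not unique):
                continue
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence or ""
            ct = a.cigartuples or []
            clip = ""
            if strand == "+" and ct and ct[-1][0] == 4:
                clip = seq[len(seq) - ct[-1][1]:]
            elif strand == "-" and ct and ct[0][0] == 4:
                clip = revcomp_dna(seq[: ct[0][1]])
            out.append(
                ReadPlacement(
                    read_id=a.query_name,
                    aligned=Interval(
                        a.reference_name, a.reference_start, a.reference_end, strand
                    ),
                    mapq=a.mapping_quality,
                    unique=unique,
                    clipped_tail_3p=clip.upper(),
                )
            )
    return out


def _load_placements_tsv(path, min_mapq, require_unique):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >=7 tab-separated columns "
                    f"({', '.join(TSV_READ_COLUMNS)})"
                )
            read_id, chrom, start, end, strand, mapq, uniq = parts[:7]
            clip = parts[7] if len(parts) > 7 and parts[7] != "." else ""
            mapq_i = int(mapq)
            unique = uniq.strip().lower() in _TRUE_STRINGS
            if mapq_i < min_mapq or (require_unique and not unique):
                continue
            out.append(
                ReadPlacement(
                    read_id=read_id,
                    aligned=Interval(chrom, int(start), int(end), strand),
                    mapq=mapq_i,
                    unique=unique,
                    clipped_tail_3p=clip.upper(),
                )
            )
    return out


def load_read_placements(
    path: str | Path, min_mapq: int = 20, require_unique: bool = True
) -> list[ReadPlacement]:
    """Load alignments from SAM or the simplified TSV dialect, keeping
    only unique placements with MAPQ >= ``min_mapq`` (boundary
    inclusive) and capturing 3' soft-clipped bases in read orientation."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if path.suffix == ".sam" or first.startswith("@"):
        return _load_placements_sam(path, min_mapq, require_unique)
    if first.count("\t") >= 6 or first.startswith(("#", "read_id")):
        return _load_placements_tsv(path, min_mapq, require_unique)
    raise AnnotationError(f"{path}: unrecognised read-placement format")
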