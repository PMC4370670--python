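"""Ground-truthed synthetic cohorts for every pipeline stage.

The generator emulates the study's inputs at desk scale: host genes
with intronic miRNAs, 3'UTRs with planted seed matches, canonical
poly(A) signals and cleavage sites, 3'-tail read evidence with
internal-priming decoys, and two-condition per-region read counts with
planted shortening/lengthening shifts.

Sequence engineering: UTR backgrounds are scrubbed of accidental
canonical motifs and long A-runs before planting, so planted elements
are (near-)exclusively what downstream scans find; the 20-nt windows
downstream of planted cleavage sites are constrained to pass the
internal-priming filter; decoy positions get a genomic A-run so the
filter must reject them.  Non-host-targeting arms are rejection-sampled
until they have zero seed matches in the final host UTR.

Everything is deterministic given ``rng_seed`` (byte-identical files).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import (
    GeneModel,
    GenomeAccessor,
    Interval,
    MatureArm,
    MirnaRecord,
    ReadPlacement,
    TranscriptModel,
    UtrSequence,
    dna_to_rna,
    revcomp_dna,
    revcomp_rna,
    write_gene_models_gff3,
)
from .apa_discovery import PRIMING_MAX_A, PRIMING_MAX_RUN, PRIMING_WINDOW
from .mirna_host import find_seed_matches

DNA_MOTIFS = ("AATAAA", "ATTAAA")
_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    ``lib_sizes`` is (study, control) and defaults to the 1:2 ratio of
    the silenced versus control sequencing libraries (~50M vs ~100M
    reads).  ``effect_size`` is the fraction of distal read mass moved
    proximally for a planted "shorter" gene (reversed for "longer").
    """

    rng_seed: int = 0
    n_genes: int = 20
    n_intronic_mirnas: int = 10
    arms_per_mirna: int = 1
    fraction_ht: float = 0.5
    utr_length_range: tuple[int, int] = (800, 2500)
    ht_utr_length_range: tuple[int, int] | None = None
    nt_utr_length_range: tuple[int, int] | None = None
    sites_per_utr_range: tuple[int, int] = (2, 4)
    min_site_spacing: int = 100
    signal_placement: str = "distal_biased"  # distal_biased | uniform
    signals_per_utr: int = 3
    n_shorter: int = 0
    n_longer: int = 0
    effect_size: float = 0.3
    depth_per_gene: int = 500
    lib_sizes: tuple[int, int] = (50_000_000, 100_000_000)
    tail_depth_per_site: int = 5
    n_priming_decoys: int = 0
    mature_len: int = 22

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_ht <= 1.0):
            raise ConfigError("fraction_ht must lie in [0, 1]")
        if not (0.0 <= self.effect_size < 1.0):
            raise ConfigError("effect_size must lie in [0, 1)")
        if self.n_intronic_mirnas > self.n_genes:
            raise ConfigError("more intronic miRNAs than genes")
        if self.n_shorter + self.n_longer > self.n_genes:
            raise ConfigError("planted shift labels exceed gene count")
        if self.arms_per_mirna not in (1, 2):
            raise ConfigError("arms_per_mirna must be 1 or 2")
        for lo, hi in filter(
            None,
            [
                self.utr_length_range,
                self.ht_utr_length_range,
                self.nt_utr_length_range,
            ],
        ):
            if lo > hi or lo < 1:
                raise ConfigError("invalid UTR length range")
            k_hi = self.sites_per_utr_range[1]
            if 150 + k_hi * self.min_site_spacing + 60 > lo:
                raise ConfigError(
                    f"UTR length {lo} too short for up to {k_hi} sites "
                    f"spaced {self.min_site_spacing} nt"
                )
        if self.sites_per_utr_range[0] < 1:
            raise ConfigError("need at least one site per UTR")


@dataclass
class ArmTruth:
    mirna_gene_id: str
    arm_name: str
    host_gene_id: str
    is_ht: bool
    match_utr_offset: int | None = None
    apa_influenced: bool | None = None
    preceded_by_canonical: bool | None = None


@dataclass
class GroundTruth:
    arms: list[ArmTruth] = field(default_factory=list)
    site_offsets: dict[str, list[int]] = field(default_factory=dict)
    site_genomic: dict[str, list[int]] = field(default_factory=dict)
    decoy_genomic: dict[str, list[int]] = field(default_factory=dict)
    signal_offsets: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    shift_labels: dict[str, str] = field(default_factory=dict)
    utr_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_regions(self) -> dict[str, int]:
        return {g: len(offs) for g, offs in self.site_offsets.items()}


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genes: dict[str, GeneModel]
    mirnas: list[MirnaRecord]
    genome: GenomeAccessor
    utrs: dict[str, UtrSequence]
    truth: GroundTruth
    chrom_seqs: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _ALPHABET[rng.integers(0, 4, n)].tobytes().decode()


def _max_a_run(s: str) -> int:
    best = cur = 0
    for ch in s:
        cur = cur + 1 if ch == "A" else 0
        best = max(best, cur)
    return best


def _overlaps_any(start: int, end: int, occupied: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in occupied)


def _scrub_region(
    seq: bytearray,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    protected: list[tuple[int, int]],
    *,
    max_a_run: int = 4,
) -> None:
    """Remove canonical motifs and A-runs longer than ``max_a_run`` from
    seq[lo:hi], never touching protected intervals."""

    def is_protected(i: int) -> bool:
        return any(s <= i < e for s, e in protected)

    non_a = b"CGT"
    for _round in range(60):
        changed = False
        s = seq[lo:hi].decode()
        for pat in DNA_MOTIFS:
            idx = s.find(pat)
            while idx != -1:
                for j in range(lo + idx, lo + idx + len(pat)):
                    if not is_protected(j):
                        old = seq[j]
                        choices = [c for c in b"ACGT" if c != old]
                        seq[j] = choices[int(rng.integers(0, len(choices)))]
                        changed = True
                        break
                idx = s.find(pat, idx + 1)
        s = seq[lo:hi].decode()
        run_start = None
        run_len = 0
        for i, ch in enumerate(s):
            if ch == "A":
                run_len += 1
                if run_start is None:
                    run_start = i
                if run_len > max_a_run:
                    for j in range(lo + run_start, lo + i + 1):
                        if not is_protected(j):
                            seq[j] = non_a[int(rng.integers(0, 3))]
                            changed = True
                            break
                    run_len = 0
                    run_start = None
            else:
                run_len = 0
                run_start = None
        if not changed:
            return
    raise ConfigError("sequence scrubbing did not converge")


def _clean_window(rng: np.random.Generator, n: int) -> str:
    """Random window guaranteed to pass the internal-priming filter and
    to contain no canonical motif."""
    for _ in range(200):
        w = _random_dna(rng, n)
        if (
            w.count("A") < min(PRIMING_MAX_A, 10)
            and _max_a_run(w) < min(PRIMING_MAX_RUN, 5)
            and not any(m in w for m in DNA_MOTIFS)
        ):
            return w
    raise ConfigError("could not draw a clean downstream window")


def _pick_free_offset(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    width: int,
    occupied: list[tuple[int, int]],
    margin: int = 0,
) -> int | None:
    if hi <= lo:
        return None
    for _ in range(300):
        o = int(rng.integers(lo, hi))
        if not _overlaps_any(o - margin, o + width + margin, occupied):
            return o
    return None


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------

_FLANK5 = 100
_FLANK3 = 150
_EXON_LEN = 150
_CDS_TAIL = 120
_MIRNA_LEN = 80


@dataclass
class _Draft:
    gene_id: str
    chrom: str
    strand: str
    exons_t: list[tuple[int, int]]
    cds_end_t: int
    utr_start_t: int
    utr_len: int
    n_chrom: int
    seq: bytearray
    mirna_t: tuple[int, int] | None = None


def _layout_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    intron_lens: Sequence[int],
    utr_len: int,
    mirna_intron: int | None = None,
    mirna_distance: int | None = None,
) -> _Draft:
    n_exons = len(intron_lens) + 1
    pos = _FLANK5
    exons_t = []
    for i in range(n_exons):
        elen = _EXON_LEN if i < n_exons - 1 else _CDS_TAIL + utr_len
        exons_t.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += intron_lens[i]
    utr_start_t = exons_t[-1][0] + _CDS_TAIL
    n_chrom = exons_t[-1][1] + _FLANK3
    mirna_t = None
    if mirna_intron is not None:
        istart = exons_t[mirna_intron - 1][1]
        ilen = intron_lens[mirna_intron - 1]
        if mirna_distance is None:
            mirna_distance = int(rng.integers(60, ilen - _MIRNA_LEN - 60))
        if mirna_distance + _MIRNA_LEN > ilen:
            raise ConfigError(f"{gene_id}: miRNA does not fit intron")
        mirna_t = (istart + mirna_distance, istart + mirna_distance + _MIRNA_LEN)
    seq = bytearray(_random_dna(rng, n_chrom).encode())
    return _Draft(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons_t=exons_t,
        cds_end_t=utr_start_t - 1,
        utr_start_t=utr_start_t,
        utr_len=utr_len,
        n_chrom=n_chrom,
        seq=seq,
    ), mirna_t


def _finalize_gene(
    draft: _Draft, mirna_t: tuple[int, int] | None
) -> tuple[GeneModel, str, Interval | None]:
    """Map the transcription-sense draft onto the genome: identity on +,
    reverse complement plus coordinate reflection on -."""
    n = draft.n_chrom
    if draft.strand == "+":
        seq = draft.seq.decode()
        iv = lambda s, e: (s, e)
        base = lambda i: i
    else:
        seq = revcomp_dna(draft.seq.decode())
        iv = lambda s, e: (n - e, n - s)
        base = lambda i: n - 1 - i
    exons = tuple(
        sorted(
            (
                Interval(draft.chrom, *iv(s, e), draft.strand)
                for s, e in draft.exons_t
            ),
            key=lambda e: e.start,
        )
    )
    utr3 = Interval(
        draft.chrom,
        *iv(draft.utr_start_t, draft.utr_start_t + draft.utr_len),
        draft.strand,
    )
    transcript = TranscriptModel(
        transcript_id=f"{draft.gene_id}.t1",
        exons=exons,
        cds_end_genomic=base(draft.cds_end_t),
        utr3=utr3,
    )
    gene = GeneModel(gene_id=draft.gene_id, transcripts=(transcript,))
    locus = (
        Interval(draft.chrom, *iv(*mirna_t), draft.strand) if mirna_t else None
    )
    return gene, seq, locus


def _boundary_genomic(draft: _Draft, offset: int) -> int:
    """Genomic inter-base boundary of a UTR cleavage offset."""
    t = draft.utr_start_t + offset
    return t if draft.strand == "+" else draft.n_chrom - t


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _plant_sites(rng, draft, occupied, k_range, min_spacing) -> list[int]:
    """Plant cleavage sites; ``occupied`` holds UTR-relative intervals."""
    L = draft.utr_len
    k = int(rng.integers(k_range[0], k_range[1] + 1))
    for _ in range(500):
        if k == 1:
            offs = [L]
        else:
            inner = sorted(int(v) for v in rng.integers(150, L - min_spacing + 1, k - 1))
            offs = inner + [L]
        if all(b - a >= min_spacing for a, b in zip(offs, offs[1:])):
            break
    else:
        raise ConfigError(f"{draft.gene_id}: cannot place {k} sites in UTR of {L}")
    u0 = draft.utr_start_t
    for o in offs:
        w = _clean_window(rng, PRIMING_WINDOW)
        draft.seq[u0 + o : u0 + o + PRIMING_WINDOW] = w.encode()
        occupied.append((o, o + PRIMING_WINDOW))
    return offs


def _plant_signals(rng, draft, occupied, cls, mode, n_signals) -> list[tuple[int, str]]:
    L = draft.utr_len
    if mode == "uniform":
        lo, hi = int(0.05 * L), int(0.95 * L)
    elif cls == "ht":
        lo, hi = int(0.10 * L), int(0.95 * L)
    else:  # nt hosts and plain protein-coding genes: distally biased
        lo, hi = int(0.50 * L), int(0.95 * L)
    u0 = draft.utr_start_t
    out = []
    for _ in range(n_signals):
        o = _pick_free_offset(rng, lo, hi, 6, occupied, margin=1)
        if o is None:
            continue
        motif = DNA_MOTIFS[int(rng.integers(0, 2))]
        draft.seq[u0 + o : u0 + o + 6] = motif.encode()
        occupied.append((o, o + 6))
        out.append((o, dna_to_rna(motif)))
    return sorted(out)


def _plant_decoy(rng, draft, occupied) -> int | None:
    """A-rich stretch that must trip the internal-priming filter; the
    decoy cleavage boundary sits at its 5' edge."""
    L = draft.utr_len
    o = _pick_free_offset(rng, 100, L - 60, 16, occupied, margin=45)
    if o is None:
        return None
    u0 = draft.utr_start_t
    decoy = "A" * 6 + _clean_window(rng, 10)
    draft.seq[u0 + o : u0 + o + 16] = decoy.encode()
    occupied.append((o, o + 16))
    return o


def _utr_rna(draft: _Draft) -> str:
    u0 = draft.utr_start_t
    return dna_to_rna(draft.seq[u0 : u0 + draft.utr_len].decode())


def _draw_mature(rng, n: int) -> str:
    """Random mature arm whose seed site is free of canonical motifs and
    long A-runs (so planting it cannot corrupt the scrubbed UTR)."""
    for _ in range(200):
        m = dna_to_rna(_random_dna(rng, n))
        site = revcomp_rna(m[1:8]).replace("U", "T")
        if _max_a_run(site) <= 4 and not any(p in site for p in DNA_MOTIFS):
            return m
    raise ConfigError("could not draw a mature arm")


def _final_motif_cleanup(rng, draft, occupied) -> None:
    """Mutate unprotected bases in any stray canonical-motif occurrence
    created at planting junctions (``occupied`` is UTR-relative)."""
    u0 = draft.utr_start_t
    planted = list(occupied)
    for _round in range(40):
        s = _utr_rna(draft).replace("U", "T")
        stray = None
        for pat in DNA_MOTIFS:
            i = s.find(pat)
            while i != -1:
                if not any(ps <= i and i + 6 <= pe for ps, pe in planted):
                    stray = i
                    break
                i = s.find(pat, i + 1)
            if stray is not None:
                break
        if stray is None:
            return
        for j in range(stray, stray + 6):
            if not any(ps <= j < pe for ps, pe in planted):
                old = draft.seq[u0 + j]
                choices = [c for c in b"CGT" if c != old]
                draft.seq[u0 + j] = choices[int(rng.integers(0, len(choices)))]
                break
    raise ConfigError("motif cleanup did not converge")


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedCohort:
    """Build the cohort; optionally write FASTA/GFF3/TSV plus truth
    tables to ``out_dir``.  Deterministic given ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    arm_names = ("3p",) if config.arms_per_mirna == 1 else ("5p", "3p")
    total_arms = config.n_intronic_mirnas * config.arms_per_mirna
    n_ht = round(config.fraction_ht * total_arms)
    flags = np.array([True] * n_ht + [False] * (total_arms - n_ht))
    flags = flags[rng.permutation(total_arms)]

    labels = (
        ["shorter"] * config.n_shorter
        + ["longer"] * config.n_longer
        + ["none"] * (config.n_genes - config.n_shorter - config.n_longer)
    )
    labels = [labels[i] for i in rng.permutation(config.n_genes)]

    truth = GroundTruth()
    genes: dict[str, GeneModel] = {}
    mirnas: list[MirnaRecord] = []
    chrom_seqs: dict[str, str] = {}
    utrs: dict[str, UtrSequence] = {}

    decoy_gene_idx = (
        rng.integers(0, config.n_genes, config.n_priming_decoys)
        if config.n_priming_decoys
        else np.array([], dtype=int)
    )

    arm_cursor = 0
    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        chrom = f"chr{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        hosted = i < config.n_intronic_mirnas
        gene_arm_flags = []
        if hosted:
            gene_arm_flags = list(flags[arm_cursor : arm_cursor + len(arm_names)])
            arm_cursor += len(arm_names)
        is_ht_host = any(gene_arm_flags)

        if hosted and is_ht_host and config.ht_utr_length_range:
            lr = config.ht_utr_length_range
        elif hosted and not is_ht_host and config.nt_utr_length_range:
            lr = config.nt_utr_length_range
        else:
            lr = config.utr_length_range
        utr_len = int(rng.integers(lr[0], lr[1] + 1))

        intron_len = int(rng.integers(400, 1200)) if hosted else int(
            rng.integers(200, 800)
        )
        draft, mirna_t = _layout_gene(
            rng,
            gid,
            chrom,
            strand,
            intron_lens=[intron_len],
            utr_len=utr_len,
            mirna_intron=1 if hosted else None,
        )

        occupied: list[tuple[int, int]] = []
        u0, L = draft.utr_start_t, draft.utr_len
        _scrub_region(draft.seq, u0, u0 + L + 40, rng, occupied)
        site_offs = _plant_sites(
            rng, draft, occupied, config.sites_per_utr_range, config.min_site_spacing
        )
        cls = "ht" if is_ht_host else "nt"
        signals = _plant_signals(
            rng, draft, occupied, cls, config.signal_placement, config.signals_per_utr
        )
        decoys = []
        for _ in range(int(np.sum(decoy_gene_idx == i))):
            d = _plant_decoy(rng, draft, occupied)
            if d is not None:
                decoys.append(d)

        # mature arms: plant one exact 7mer-m8 site per HT arm
        arms = []
        arm_truths = []
        if hosted:
            for arm_name, is_ht in zip(arm_names, gene_arm_flags):
                if is_ht:
                    mature = _draw_mature(rng, config.mature_len)
                    site_dna = revcomp_rna(mature[1:8]).replace("U", "T")
                    m_off = _pick_free_offset(rng, 20, L - 40, 7, occupied, margin=1)
                    if m_off is None:
                        raise ConfigError(f"{gid}: no room for planted seed site")
                    draft.seq[u0 + m_off : u0 + m_off + 7] = site_dna.encode()
                    occupied.append((m_off, m_off + 7))
                    arm_truths.append(
                        ArmTruth(
                            mirna_gene_id=f"mir{i + 1:04d}",
                            arm_name=arm_name,
                            host_gene_id=gid,
                            is_ht=True,
                            match_utr_offset=m_off,
                            apa_influenced=any(0 < s < m_off for s in site_offs),
                            preceded_by_canonical=any(
                                o + 6 <= m_off for o, _ in signals
                            ),
                        )
                    )
                    arms.append(MatureArm(arm_name, mature))
                else:
                    arms.append(None)  # drawn after the UTR is final
                    arm_truths.append(
                        ArmTruth(
                            mirna_gene_id=f"mir{i + 1:04d}",
                            arm_name=arm_name,
                            host_gene_id=gid,
                            is_ht=False,
                        )
                    )

        _final_motif_cleanup(rng, draft, occupied)

        # NT arms: rejection-sample against the final UTR
        utr_seq_rna = _utr_rna(draft)
        utr_probe = UtrSequence(
            gene_id=gid,
            seq=utr_seq_rna,
            genomic=Interval(chrom, u0, u0 + L, "+"),
        )
        for j, arm in enumerate(arms):
            if arm is None:
                for _ in range(500):
                    mature = _draw_mature(rng, config.mature_len)
                    if not find_seed_matches(utr_probe, mature):
                        arms[j] = MatureArm(arm_names[j], mature)
                        break
                else:
                    raise ConfigError(f"{gid}: NT arm rejection sampling failed")

        gene, chrom_seq, locus = _finalize_gene(draft, mirna_t)
        genes[gid] = gene
        chrom_seqs[chrom] = chrom_seq
        if hosted:
            mirnas.append(
                MirnaRecord(
                    mirna_gene_id=f"mir{i + 1:04d}", locus=locus, arms=tuple(arms)
                )
            )
        truth.arms.extend(arm_truths)
        truth.site_offsets[gid] = site_offs
        truth.site_genomic[gid] = [_boundary_genomic(draft, o) for o in site_offs]
        truth.decoy_genomic[gid] = [_boundary_genomic(draft, d) for d in decoys]
        truth.signal_offsets[gid] = signals
        truth.shift_labels[gid] = labels[i]
        truth.utr_lengths[gid] = L
        utrs[gid] = UtrSequence(
            gene_id=gid,
            seq=utr_seq_rna,
            genomic=gene.longest_transcript.utr3,
        )

    cohort = SimulatedCohort(
        config=config,
        genes=genes,
        mirnas=mirnas,
        genome=GenomeAccessor(chrom_seqs),
        utrs=utrs,
        truth=truth,
        chrom_seqs=chrom_seqs,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.chrom_seqs, out / "genome.fa")
    write_gene_models_gff3(cohort.genes, out / "genes.gff3")
    with open(out / "mirnas.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(cohort.mirnas, key=lambda r: r.mirna_gene_id):
            l = m.locus
            fh.write(
                f"{l.chrom}\tapafeedback\tmiRNA_primary_transcript\t{l.start + 1}"
                f"\t{l.end}\t.\t{l.strand}\t.\tID={m.mirna_gene_id};"
                f"Name={m.mirna_gene_id}\n"
            )
    with open(out / "mature.tsv", "w") as fh:
        fh.write("mirna_gene_id\tarm_name\tmature_seq\n")
        for m in sorted(cohort.mirnas, key=lambda r: r.mirna_gene_id):
            for arm in m.arms:
                fh.write(f"{m.mirna_gene_id}\t{arm.name}\t{arm.mature_seq}\n")
    t = cohort.truth
    with open(out / "truth_arms.tsv", "w") as fh:
        fh.write(
            "mirna_gene_id\tarm_name\thost_gene_id\tis_ht\tmatch_utr_offset"
            "\tapa_influenced\tpreceded_by_canonical\n"
        )
        for a in sorted(t.arms, key=lambda a: (a.mirna_gene_id, a.arm_name)):
            fh.write(
                f"{a.mirna_gene_id}\t{a.arm_name}\t{a.host_gene_id}\t"
                f"{int(a.is_ht)}\t{a.match_utr_offset if a.match_utr_offset is not None else '.'}\t"
                f"{'.' if a.apa_influenced is None else int(a.apa_influenced)}\t"
                f"{'.' if a.preceded_by_canonical is None else int(a.preceded_by_canonical)}\n"
            )
    with open(out / "truth_sites.tsv", "w") as fh:
        fh.write("gene_id\tutr_offset\tgenomic_boundary\n")
        for g in sorted(t.site_offsets):
            for o, p in zip(t.site_offsets[g], t.site_genomic[g]):
                fh.write(f"{g}\t{o}\t{p}\n")
    with open(out / "truth_shifts.tsv", "w") as fh:
        fh.write("gene_id\tlabel\tn_regions\n")
        for g in sorted(t.shift_labels):
            fh.write(f"{g}\t{t.shift_labels[g]}\t{len(t.site_offsets[g])}\n")
    with open(out / "truth_signals.tsv", "w") as fh:
        fh.write("gene_id\tutr_offset\tmotif\n")
        for g in sorted(t.signal_offsets):
            for o, motif in t.signal_offsets[g]:
                fh.write(f"{g}\t{o}\t{motif}\n")


# ---------------------------------------------------------------------------
# tail reads
# ---------------------------------------------------------------------------


def simulate_tail_reads(
    cohort: SimulatedCohort,
    out_tsv: str | Path | None = None,
    out_sam: str | Path | None = None,
) -> list[ReadPlacement]:
    """3'-tail reads at every planted site (``tail_depth_per_site``
    each, varying aligned lengths, >10-A untemplated tails), plus decoy
    reads at A-rich positions, one sub-threshold (10-A) read and one
    low-MAPQ read per gene for filter exercise."""
    config = cohort.config
    rng = np.random.default_rng(config.rng_seed + 1)
    reads: list[ReadPlacement] = []
    n = 0

    def add(gene: GeneModel, boundary: int, tail: str, mapq: int = 60) -> None:
        nonlocal n
        n += 1
        t = gene.longest_transcript
        alen = 25 + int(rng.integers(0, 20))
        if t.strand == "+":
            iv = Interval(t.chrom, boundary - alen, boundary, "+")
        else:
            iv = Interval(t.chrom, boundary, boundary + alen, "-")
        reads.append(
            ReadPlacement(
                read_id=f"r{n:06d}",
                aligned=iv,
                mapq=mapq,
                unique=mapq >= 20,
                clipped_tail_3p=tail,
            )
        )

    for gid in sorted(cohort.genes):
        gene = cohort.genes[gid]
        for boundary in cohort.truth.site_genomic[gid]:
            for _ in range(config.tail_depth_per_site):
                add(gene, boundary, "A" * (11 + int(rng.integers(0, 5))))
        for boundary in cohort.truth.decoy_genomic.get(gid, []):
            for _ in range(config.tail_depth_per_site):
                add(gene, boundary, "A" * 12)
        first = cohort.truth.site_genomic[gid][0]
        add(gene, first, "A" * 10)  # below the >10 threshold
        add(gene, first, "A" * 12, mapq=10)  # fails the MAPQ filter

    if out_tsv is not None:
        with open(out_tsv, "w") as fh:
            fh.write("read_id\tchrom\tstart\tend\tstrand\tmapq\tunique\tclipped_tail_3p\n")
            for r in reads:
                fh.write(
                    f"{r.read_id}\t{r.aligned.chrom}\t{r.aligned.start}\t"
                    f"{r.aligned.end}\t{r.aligned.strand}\t{r.mapq}\t"
                    f"{int(r.unique)}\t{r.clipped_tail_3p or '.'}\n"
                )
    if out_sam is not None:
        genome = cohort.genome
        with open(out_sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for chrom in sorted(cohort.chrom_seqs):
                fh.write(f"@SQ\tSN:{chrom}\tLN:{len(cohort.chrom_seqs[chrom])}\n")
            for r in reads:
                a = r.aligned
                aligned_seq = genome.fetch(a.chrom, a.start, a.end)
                tl = len(r.clipped_tail_3p)
                if a.strand == "+":
                    flag, cigar = 0, f"{a.length}M{tl}S"
                    seq = aligned_seq + r.clipped_tail_3p
                else:
                    flag, cigar = 16, f"{tl}S{a.length}M"
                    seq = revcomp_dna(r.clipped_tail_3p) + aligned_seq
                fh.write(
                    f"{r.read_id}\t{flag}\t{a.chrom}\t{a.start + 1}\t{r.mapq}\t"
                    f"{cigar}\t*\t0\t0\t{seq}\t*\n"
                )
    return reads


# ---------------------------------------------------------------------------
# two-condition region counts
# ---------------------------------------------------------------------------


@dataclass
class RegionCountSim:
    gene_id: str
    label: str
    study: list[int]
    control: list[int]


def _shift_weights(w: np.ndarray, label: str, effect: float) -> np.ndarray:
    """Move ``effect`` of the distal-half mass proximally (shorter) or
    the proximal-half mass distally (longer)."""
    k = len(w)
    if label == "none" or k < 2 or effect <= 0:
        return w.copy()
    idx = np.arange(1, k + 1)
    prox = idx < (k + 1) / 2
    dist = idx > (k + 1) / 2
    out = w.astype(float).copy()
    if label == "shorter":
        src, dst = dist, prox
    elif label == "longer":
        src, dst = prox, dist
    else:
        raise ValueError(f"unknown shift label {label!r}")
    moved = effect * out[src].sum()
    out[src] *= 1 - effect
    out[dst] += moved * (w[dst] / w[dst].sum())
    return out / out.sum()


def make_region_truth(config: SimulationConfig) -> GroundTruth:
    """Minimal region-level truth (site offsets and shift labels only)
    for count-driven experiments; no sequences are generated."""
    rng = np.random.default_rng(config.rng_seed)
    labels = (
        ["shorter"] * config.n_shorter
        + ["longer"] * config.n_longer
        + ["none"] * (config.n_genes - config.n_shorter - config.n_longer)
    )
    labels = [labels[i] for i in rng.permutation(config.n_genes)]
    truth = GroundTruth()
    k_lo, k_hi = config.sites_per_utr_range
    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        k = int(rng.integers(k_lo, k_hi + 1))
        truth.site_offsets[gid] = [(j + 1) * 200 for j in range(k)]
        truth.shift_labels[gid] = labels[i]
        truth.utr_lengths[gid] = k * 200
    return truth


def simulate_region_counts(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, RegionCountSim]:
    """Multinomial per-region read counts for both conditions.

    Control counts follow a distal-heavy baseline (weights proportional
    to the region index); study counts use the baseline re-weighted by
    the gene's planted shift.  Study totals are scaled by the library
    ratio so the binomial null p0 = lib_study/(lib_study+lib_control)
    holds for unshifted genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    lib_s, lib_c = config.lib_sizes
    ratio = lib_s / lib_c
    out: dict[str, RegionCountSim] = {}
    for gid in sorted(truth.site_offsets):
        k = len(truth.site_offsets[gid])
        label = truth.shift_labels.get(gid, "none")
        idx = np.arange(1, k + 1, dtype=float)
        w = idx / idx.sum()
        w_study = _shift_weights(w, label, config.effect_size)
        n_control = config.depth_per_gene
        n_study = max(1, round(config.depth_per_gene * ratio))
        control = rng.multinomial(n_control, w)
        study = rng.multinomial(n_study, w_study)
        out[gid] = RegionCountSim(
            gene_id=gid,
            label=label,
            study=[int(v) for v in study],
            control=[int(v) for v in control],
        )
    return out


def regions_with_simulated_counts(
    truth: GroundTruth, sims: Mapping[str, RegionCountSim]
):
    """Flat PolyARegion list (all genes) carrying the simulated counts."""
    from .apa_shift import PolyARegion

    regions = []
    for gid in sorted(sims):
        sim = sims[gid]
        offsets = truth.site_offsets[gid]
        prev = 0
        for k, off in enumerate(offsets, start=1):
            regions.append(
                PolyARegion(
                    gene_id=gid,
                    index=k,
                    start=prev,
                    end=off,
                    count_study=sim.study[k - 1],
                    count_control=sim.control[k - 1],
                )
            )
            prev = off
    return regions


# ---------------------------------------------------------------------------
# signal-position experiment
# ---------------------------------------------------------------------------


def simulate_signal_utrs(
    n_utrs: int,
    cls: str,
    rng: np.random.Generator,
    *,
    utr_length_range: tuple[int, int] = (800, 2500),
    signals_per_utr: int = 3,
    placement: str = "distal_biased",
) -> list[UtrSequence]:
    """UTR sequences with planted canonical signals only (no sites or
    seeds), for positional-distribution experiments.  ``cls`` is 'ht'
    (evenly spread signals) or 'nt' (distally concentrated)."""
    out = []
    for i in range(n_utrs):
        L = int(rng.integers(utr_length_range[0], utr_length_range[1] + 1))
        seq = bytearray(_random_dna(rng, L).encode())
        occupied: list[tuple[int, int]] = []
        _scrub_region(seq, 0, L, rng, occupied)
        if placement == "uniform":
            lo, hi = int(0.05 * L), int(0.95 * L)
        elif cls == "ht":
            lo, hi = int(0.10 * L), int(0.95 * L)
        else:
            lo, hi = int(0.50 * L), int(0.95 * L)
        for _ in range(signals_per_utr):
            o = _pick_free_offset(rng, lo, hi, 6, occupied, margin=1)
            if o is None:
                continue
            seq[o : o + 6] = DNA_MOTIFS[int(rng.integers(0, 2))].encode()
            occupied.append((o, o + 6))
        out.append(
            UtrSequence(
                gene_id=f"{cls}{i + 1:05d}",
                seq=dna_to_rna(seq.decode()),
                genomic=Interval(f"u_{cls}{i + 1}", 0, L, "+"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# the ZFR-like synthetic fixture
# ---------------------------------------------------------------------------


@dataclass
class ZfrLikeFixture:
    gene: GeneModel
    mirna: MirnaRecord
    genome: GenomeAccessor
    utr: UtrSequence
    site_offsets: list[int]
    signal_positions_1based: list[tuple[int, str]]
    match_offset: int  # 0-based UTR start of the planted seed site
    mature_seq: str


def synthetic_zfr_like() -> ZfrLikeFixture:
    """Synthetic stand-in for the ZFR/mir-579 geometry.

    Entirely synthetic sequence (deterministic), reproducing the
    published architecture: a minus-strand gene of total span 90,389 bp
    with 20 exons, a miRNA of length 80 in intron 11 (intron length
    4,722 bp, 684 bp from the upstream exon), a 1,409-nt 3'UTR with
    three cleavage sites at UTR offsets 41/340/1134, canonical signals
    at 1-based positions 135 (AAUAAA), 314 (AUUAAA) and 738 (AAUAAA),
    and a single 7mer-m8 seed site at 1-based position 1301.
    """
    rng = np.random.default_rng(579)
    utr_len = 1409
    intron_lens = [4516] * 18
    intron_lens.insert(10, 4722)  # intron 11 in transcription order
    draft, mirna_t = _layout_gene(
        rng,
        "ZFRL",
        "chr5s",
        "-",
        intron_lens=intron_lens,
        utr_len=utr_len,
        mirna_intron=11,
        mirna_distance=684,
    )
    span = draft.exons_t[-1][1] - draft.exons_t[0][0]
    assert span == 90389, span

    occupied: list[tuple[int, int]] = []
    u0 = draft.utr_start_t
    _scrub_region(draft.seq, u0, u0 + utr_len + 40, rng, occupied)

    site_offsets = [41, 340, 1134]
    for o in site_offsets:
        w = _clean_window(rng, PRIMING_WINDOW)
        draft.seq[u0 + o : u0 + o + PRIMING_WINDOW] = w.encode()
        occupied.append((o, o + PRIMING_WINDOW))
    signals = [(135, "AAUAAA"), (314, "AUUAAA"), (738, "AAUAAA")]
    for pos1, motif in signals:
        o = pos1 - 1
        draft.seq[u0 + o : u0 + o + 6] = motif.replace("U", "T").encode()
        occupied.append((o, o + 6))
    mature = "UCGGAAUCCUUAAGGCAUUCA"
    site_dna = revcomp_rna(mature[1:8]).replace("U", "T")
    match_offset = 1300  # 1-based position 1301
    draft.seq[u0 + match_offset : u0 + match_offset + 7] = site_dna.encode()
    occupied.append((match_offset, match_offset + 7))
    _final_motif_cleanup(rng, draft, occupied)

    gene, chrom_seq, locus = _finalize_gene(draft, mirna_t)
    genome = GenomeAccessor({"chr5s": chrom_seq})
    from .annotation_io import extract_utr_sequence

    utr = extract_utr_sequence(gene, genome)
    assert utr is not None and utr.length == utr_len
    mirna = MirnaRecord(
        mirna_gene_id="mir-Z",
        locus=locus,
        arms=(MatureArm("3p", mature),),
    )
    return ZfrLikeFixture(
        gene=gene,
        mirna=mirna,
        genome=genome,
        utr=utr,
        site_offsets=site_offsets,
        signal_positions_1based=signals,
        match_offset=match_offset,
        mature_seq=mature,
    )
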