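"""End-to-end orchestration: load -> classify -> detect APA -> scan
signals -> shift-call -> enrich, with per-stage logging and report
tables.

A *bundle* is a directory holding ``genome.fa``, ``genes.gff3``,
``mirnas.gff3`` and ``mature.tsv`` (the simulator's output layout), or
a ``manifest.yaml`` mapping those four keys to paths elsewhere.

All report tables are TSV with ``#``-prefixed provenance headers
echoing every threshold, so any number in the report traces back to a
stage output and a configuration value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import apa_discovery, apa_shift, enrichment, mirna_host, polya_signal
from .annotation_io import (
    AnnotationBundle,
    AnnotationError,
    extract_utr_sequence,
    load_annotation_bundle,
    load_read_placements,
)
from .apa_discovery import ApaSiteCatalog, build_catalog, write_catalog_bed
from .apa_shift import PolyARegion

logger = logging.getLogger(__name__)

BUNDLE_FILES = {
    "genes": "genes.gff3",
    "mirnas": "mirnas.gff3",
    "mature": "mature.tsv",
    "genome": "genome.fa",
}


@dataclass
class PipelineConfig:
    bundle: str
    out_dir: str
    est_reads: str | None = None
    rnaseq_reads: str | None = None
    external_bed: str | None = None
    region_counts: str | None = None
    study_reads: str | None = None
    control_reads: str | None = None
    lib_study: int = 50_000_000
    lib_control: int = 100_000_000
    apa_genes: str | None = None
    alpha: float = 0.05
    min_mapq: int = 20
    min_total_depth: int = 20
    cluster_gap: int = 40
    min_tail: int = 11
    priming_max_a: int = 12
    priming_max_run: int = 6
    bh_family: str = "per_table"
    preceded_mode: str = "any_upstream"
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        missing = {"bundle", "out_dir"} - set(raw)
        if missing:
            raise ValueError(f"pipeline config missing keys: {sorted(missing)}")
        return cls(**raw)


def resolve_bundle(bundle_dir: str | Path) -> dict[str, Path]:
    """Map bundle component names to file paths."""
    d = Path(bundle_dir)
    manifest = d / "manifest.yaml"
    if manifest.exists():
        with open(manifest) as fh:
            raw = yaml.safe_load(fh)
        paths = {k: Path(raw[k]) for k in BUNDLE_FILES}
    else:
        paths = {k: d / v for k, v in BUNDLE_FILES.items()}
    for k, p in paths.items():
        if not p.exists():
            raise AnnotationError(f"bundle component {k!r} missing: {p}")
    return paths


def load_bundle(bundle_dir: str | Path) -> AnnotationBundle:
    paths = resolve_bundle(bundle_dir)
    return load_annotation_bundle(
        paths["genes"], paths["mirnas"], paths["mature"], paths["genome"]
    )


def _provenance(config: PipelineConfig) -> list[str]:
    return [
        f"# {f.name}={getattr(config, f.name)}"
        for f in dataclasses.fields(PipelineConfig)
    ]


def _write_table(path: Path, header: str, rows, provenance: list[str]) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(line + "\n")
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _load_region_counts(path: str | Path) -> list[PolyARegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "gene_id\t")):
                continue
            g, idx, start, end, cs, cc = line.rstrip("\n").split("\t")
            regions.append(
                PolyARegion(
                    gene_id=g,
                    index=int(idx),
                    start=int(start),
                    end=int(end),
                    count_study=int(cs),
                    count_control=int(cc),
                )
            )
    return regions


@dataclass
class PipelineResult:
    bundle: AnnotationBundle
    utrs: dict
    assignments: list
    calls: list
    catalog: ApaSiteCatalog
    cohort: mirna_host.CohortSummary | None
    shift_calls: list
    class_summary: Any
    enrichment_results: list


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every configured stage; any stage failure aborts with the
    stage name attached."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    stage = "load"
    try:
        bundle = load_bundle(config.bundle)
        utrs = {}
        for gid in sorted(bundle.genes):
            u = extract_utr_sequence(bundle.genes[gid], bundle.genome)
            if u is not None:
                utrs[gid] = u
        logger.info("stage load: %d genes, %d miRNAs, %d UTRs",
                    len(bundle.genes), len(bundle.mirnas), len(utrs))

        stage = "classify-mirnas"
        assignments = [
            mirna_host.classify_mirna_location(m, bundle.genes)
            for m in bundle.mirnas
        ]
        calls = mirna_host.classify_host_targeting(assignments, bundle.mirnas, utrs)
        _write_table(
            out / "mirna_calls.tsv",
            "mirna_gene_id\tarm_name\tcategory\thost_gene_id\tintron_index\tis_ht\tn_matches",
            [
                (
                    c.mirna_gene_id,
                    c.arm_name,
                    next(
                        a.category
                        for a in assignments
                        if a.mirna_gene_id == c.mirna_gene_id
                    ),
                    c.host_gene_id,
                    next(
                        a.intron_index
                        for a in assignments
                        if a.mirna_gene_id == c.mirna_gene_id
                    ),
                    int(c.is_ht),
                    c.n_matches,
                )
                for c in calls
            ],
            prov,
        )
        logger.info("stage classify-mirnas: %d arm calls", len(calls))

        stage = "detect-apa"
        est_ev: list = []
        rnaseq_ev: list = []
        if config.est_reads:
            placements = load_read_placements(
                config.est_reads, min_mapq=config.min_mapq
            )
            for p in placements:
                e = apa_discovery.detect_est_tail(
                    p,
                    bundle.genome,
                    min_tail=config.min_tail,
                    priming_max_a=config.priming_max_a,
                    priming_max_run=config.priming_max_run,
                )
                if e is not None:
                    est_ev.append(e)
        if config.rnaseq_reads:
            placements = load_read_placements(
                config.rnaseq_reads, min_mapq=config.min_mapq
            )
            by_pos: dict = {}
            for p in placements:
                key = (
                    p.aligned.chrom,
                    p.aligned.strand,
                    apa_discovery._cleavage_boundary(p),
                )
                by_pos.setdefault(key, []).append(p)
            for key in sorted(by_pos):
                ev = apa_discovery.detect_rnaseq_tail(by_pos[key], bundle.genome)
                if ev:
                    rnaseq_ev.extend(ev)
        catalog = build_catalog(
            est_ev,
            rnaseq_ev,
            config.external_bed,
            bundle.genes,
            max_gap=config.cluster_gap,
        )
        write_catalog_bed(catalog, out / "apa_sites.bed")
        logger.info(
            "stage detect-apa: %d EST + %d RNA-Seq evidence -> %d sites in %d genes",
            len(est_ev),
            len(rnaseq_ev),
            len(catalog.all_sites()),
            catalog.n_genes,
        )

        stage = "cohort-summary"
        cohort = mirna_host.cohort_summary(calls, utrs, catalog) if calls else None
        if cohort is not None:
            _write_table(
                out / "cohort_summary.tsv",
                "metric\tht\tnt\tp_value",
                [
                    ("n_arms", cohort.n_ht_arms, cohort.n_nt_arms, ""),
                    ("n_host_genes", cohort.n_ht_hosts, cohort.n_nt_hosts, ""),
                    ("total_seed_matches", cohort.total_seed_matches, "", ""),
                    (
                        "median_utr_length",
                        cohort.median_utr_len_ht,
                        cohort.median_utr_len_nt,
                        cohort.utr_len_test.p_value if cohort.utr_len_test else "",
                    ),
                    (
                        "median_apa_sites",
                        cohort.median_sites_ht,
                        cohort.median_sites_nt,
                        cohort.site_count_test.p_value
                        if cohort.site_count_test
                        else "",
                    ),
                ],
                prov,
            )

        stage = "scan-signals"
        all_hits = []
        for gid in sorted(utrs):
            all_hits.extend(polya_signal.scan_polya_signals(utrs[gid]))
        _write_table(
            out / "signal_hits.tsv",
            "gene_id\tmotif\tposition_1based\trelative_position",
            [
                (h.gene_id, h.motif, h.utr_offset + 1, f"{h.relative_position:.6f}")
                for h in all_hits
            ],
            prov,
        )
        matches = []
        utr_by_host = utrs
        for m in bundle.mirnas:
            a = next(
                x for x in assignments if x.mirna_gene_id == m.mirna_gene_id
            )
            if a.host_gene_id and a.host_gene_id in utr_by_host:
                for arm in m.arms:
                    matches.extend(
                        mirna_host.find_seed_matches(
                            utr_by_host[a.host_gene_id],
                            arm.mature_seq,
                            mirna_gene_id=m.mirna_gene_id,
                            arm_name=arm.name,
                        )
                    )
        flags = polya_signal.annotate_seed_match_apa(
            matches, catalog, all_hits, preceded_mode=config.preceded_mode
        )
        _write_table(
            out / "match_flags.tsv",
            "mirna_gene_id\tarm_name\tgene_id\tutr_offset\tsite_type\tapa_influenced\tpreceded_by_canonical",
            [
                (
                    f.match.mirna_gene_id,
                    f.match.arm_name,
                    f.match.gene_id,
                    f.match.utr_offset,
                    f.match.site_type,
                    int(f.apa_influenced),
                    int(f.preceded_by_canonical),
                )
                for f in flags
            ],
            prov,
        )
        logger.info(
            "stage scan-signals: %d hits, %d seed matches", len(all_hits), len(matches)
        )

        stage = "shift-call"
        shift_calls = []
        class_summary = None
        regions: list[PolyARegion] = []
        if config.region_counts:
            regions = _load_region_counts(config.region_counts)
        elif config.study_reads and config.control_reads:
            study = load_read_placements(config.study_reads, min_mapq=config.min_mapq)
            control = load_read_placements(
                config.control_reads, min_mapq=config.min_mapq
            )
            for gid in sorted(catalog.sites_by_gene):
                gene = bundle.genes[gid]
                utr = gene.longest_transcript.utr3
                if utr is None or gid not in utrs:
                    continue
                rs = apa_shift.partition_polya_regions(
                    utrs[gid], catalog.sites_for(gid)
                )
                if not rs:
                    continue
                s_off = [
                    apa_shift.read_end_utr_offset(p, utr)
                    for p in study
                    if p.aligned.chrom == utr.chrom and p.aligned.strand == utr.strand
                ]
                c_off = [
                    apa_shift.read_end_utr_offset(p, utr)
                    for p in control
                    if p.aligned.chrom == utr.chrom and p.aligned.strand == utr.strand
                ]
                apa_shift.count_reads_by_region(rs, s_off, c_off)
                regions.extend(rs)
        if regions:
            by_gene: dict[str, list[PolyARegion]] = {}
            for r in regions:
                by_gene.setdefault(r.gene_id, []).append(r)
            kept = apa_shift.filter_genes_for_depth(
                by_gene, min_total=config.min_total_depth
            )
            tested = [r for r in regions if r.gene_id in kept]
            tests = apa_shift.test_regions(
                tested, config.lib_study, config.lib_control, alpha=config.alpha
            )
            shift_calls = apa_shift.call_utr_shifts(tests)
            ht_hosts = {c.host_gene_id for c in calls if c.is_ht}
            nt_hosts = {c.host_gene_id for c in calls if c.host_gene_id} - ht_hosts
            class_of = {g: "HT-host" for g in ht_hosts if g}
            class_of.update({g: "NT-host" for g in nt_hosts if g})
            class_summary = apa_shift.summarize_shift_by_class(shift_calls, class_of)
            _write_table(
                out / "shift_calls.tsv",
                "gene_id\tcall\tmedian_up_index\tmedian_down_index\ttie",
                [
                    (c.gene_id, c.call, c.median_up_index, c.median_down_index, int(c.tie))
                    for c in shift_calls
                ],
                prov,
            )
            with open(out / "shift_class_summary.tsv", "w") as fh:
                for line in prov:
                    fh.write(line + "\n")
                class_summary.to_csv(fh, sep="\t")
            logger.info(
                "stage shift-call: %d regions, %d genes called",
                len(tested),
                sum(c.call != apa_shift.CALL_NONE for c in shift_calls),
            )

        stage = "enrich"
        enrich_results = []
        if config.apa_genes:
            with open(config.apa_genes) as fh:
                apa_gene_ids = [l.strip() for l in fh if l.strip()]
            apa_utrs = {g: utrs[g] for g in apa_gene_ids if g in utrs}
            arm_seq = {}
            for m in bundle.mirnas:
                for arm in m.arms:
                    arm_seq[(m.mirna_gene_id, arm.name)] = arm.mature_seq
            ht_cohort = [
                arm_seq[(c.mirna_gene_id, c.arm_name)] for c in calls if c.is_ht
            ]
            nt_cohort = [
                arm_seq[(c.mirna_gene_id, c.arm_name)] for c in calls if not c.is_ht
            ]
            if apa_utrs and ht_cohort and nt_cohort:
                tables = enrichment.enrichment_tables(
                    apa_utrs, ht_cohort, nt_cohort, bh_family=config.bh_family
                )
                enrich_results = tables["ht_vs_nt"]
                _write_table(
                    out / "enrichment_ht_vs_nt.tsv",
                    "apa_gene_id\tn_targeting_ht\tn_ht\tn_targeting_nt\tn_nt\todds_ratio\tp_value\tq_value",
                    [
                        (
                            r.apa_gene_id,
                            r.n_targeting_a,
                            r.n_a,
                            r.n_targeting_b,
                            r.n_b,
                            f"{r.odds_ratio:.6g}",
                            f"{r.p_value:.6g}",
                            f"{r.q_value:.6g}",
                        )
                        for r in enrich_results
                    ],
                    prov,
                )
                logger.info("stage enrich: %d genes tested", len(enrich_results))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        bundle=bundle,
        utrs=utrs,
        assignments=assignments,
        calls=calls,
        catalog=catalog,
        cohort=cohort,
        shift_calls=shift_calls,
        class_summary=class_summary,
        enrichment_results=enrich_results,
    )
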