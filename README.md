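# apafeedback

Tools for studying how **alternative polyadenylation (APA) gates the
negative feedback of intronic miRNAs on their host genes**.

Roughly half of human miRNA genes are intronic: they are co-transcribed
with a protein-coding host, and when the mature miRNA has a
seed-complementary site in the host's 3'UTR, the host transcribes its
own repressor.  Because many 3'UTRs carry several
cleavage/polyadenylation sites, the cell can switch between UTR
isoforms that contain or lack the miRNA site — turning the feedback
loop on or off.  `apafeedback` implements the full in-silico side of
this analysis for bulk RNA-Seq/EST data:

- **HT/NT classification** — label each mature arm of an intronic miRNA
  *host-targeting* (≥ 1 canonical seed match in the host 3'UTR) or
  *non-host-targeting*.  Seed sites are the two 7-nt classes: the UTR
  7-mer equal to the reverse complement of mature nucleotides 2–8
  (**7mer-m8**), or of nucleotides 2–7 followed by an A (**7mer-A1**).
- **Poly(A)-site discovery** — 3'-tail evidence from EST-style reads
  (> 10 untemplated terminal A's, internal-priming filtered) and
  RNA-Seq reads (≥ 2 reads with ≥ 2 untemplated A's and distinct
  aligned lengths), merged with external BED site lists and clustered
  with a 40-nt single-linkage gap within the longest transcript.
- **Poly(A)-signal analysis** — scan for the canonical hexamers
  AAUAAA/AUUAAA, compare relative-position distributions between
  cohorts, and flag seed matches that an upstream site can excise
  (APA-influenced) or that a canonical signal precedes.
- **Differential 3'UTR usage** — partition each UTR into poly(A)
  regions, test per-region read-count changes between two conditions
  with an exact binomial test against the library-size proportion
  (genome-wide Benjamini–Hochberg), and call each gene **shorter** or
  **longer** by comparing the median indices of significantly up- vs
  downregulated regions.
- **Machinery enrichment** — Fisher's exact test per
  polyadenylation-machinery gene for preferential targeting by HT
  arms, with BH adjustment.
- **Ground-truthed simulation** — generators for genomes, host genes
  with planted miRNAs/seed sites/signals/cleavage sites, tail reads
  with internal-priming decoys, and two-condition region counts with
  planted shortening/lengthening shifts.

## Worked example

```python
from apafeedback.synthetic_data import (
    SimulationConfig, generate_cohort, simulate_tail_reads,
)
from apafeedback import mirna_host
from apafeedback.apa_discovery import detect_est_tail, build_catalog

cfg = SimulationConfig(rng_seed=17, n_genes=20, n_intronic_mirnas=10,
                       fraction_ht=0.5, n_priming_decoys=10,
                       ht_utr_length_range=(1800, 2600),
                       nt_utr_length_range=(900, 1500))
cohort = generate_cohort(cfg)

assignments = [mirna_host.classify_mirna_location(m, cohort.genes)
               for m in cohort.mirnas]
calls = mirna_host.classify_host_targeting(assignments, cohort.mirnas,
                                           cohort.utrs)
print(f"{sum(c.is_ht for c in calls)} HT / "
      f"{sum(not c.is_ht for c in calls)} NT arms")

reads = simulate_tail_reads(cohort)
evidence = [e for p in reads if p.mapq >= 20
            if (e := detect_est_tail(p, cohort.genome)) is not None]
catalog = build_catalog(evidence, [], None, cohort.genes)
print(f"{len(catalog.all_sites())} poly(A) sites in {catalog.n_genes} genes "
      f"from {len(evidence)} accepted tail reads")

summary = mirna_host.cohort_summary(calls, cohort.utrs, catalog)
print(f"median UTR length HT {summary.median_utr_len_ht:.0f} vs "
      f"NT {summary.median_utr_len_nt:.0f} "
      f"(MWU p = {summary.utr_len_test.p_value:.4f})")
```

prints

```
5 HT / 5 NT arms
61 poly(A) sites in 20 genes from 305 accepted tail reads
median UTR length HT 1894 vs NT 1042 (MWU p = 0.0079)
```

Ten miRNA arms were planted, exactly five with a seed match in their
host UTR — all ten are classified correctly.  Every planted cleavage
site is recovered at its exact position from the simulated tail reads
(decoy reads at A-rich genomic positions are rejected by the
internal-priming filter), and the planted UTR-length contrast between
HT and NT hosts is detected by the Mann–Whitney test.

## Command line

```bash
apafeedback simulate --config sim.yaml --out simdir/
apafeedback load --genes genes.gff3 --mirnas mirnas.gff3 \
                 --mature mature.tsv --genome genome.fa --out bundle/
apafeedback classify-mirnas --bundle simdir/ --out calls.tsv
apafeedback detect-apa --bundle simdir/ --est simdir/tail_reads.sam --out apa.bed
apafeedback run --config pipeline.yaml
```

`run` executes load → classify → detect-apa → scan-signals →
shift-call → enrich and writes the report tables (cohort summary,
per-arm calls, site BED, signal positions, per-match flags, shift
calls with per-class summary, enrichment table), each with a
provenance header echoing every threshold.

### File formats

- Gene models: GFF3 with `gene` → `mRNA`/`transcript` →
  `exon`/`CDS`/`three_prime_UTR`; miRNA loci: GFF3
  (`miRNA_primary_transcript`, miRBase-style).
- Mature arms: TSV `mirna_gene_id  arm_name  mature_seq`.
- Read placements: SAM (soft clips parsed for 3' tails), or the
  simplified TSV dialect
  `read_id  chrom  start  end  strand  mapq  unique  clipped_tail_3p`
  (0-based half-open, clip in read orientation, `.` for no clip).
- Poly(A) sites: BED6 `chrom  pos  pos+1  site_id  support  strand`
  (0-based inter-base cleavage boundary).
- Region counts: TSV `gene_id  index  start  end  count_study
  count_control` (UTR coordinates).

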