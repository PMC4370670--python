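# Methods

`apafeedback` implements an in-silico analysis of how alternative
polyadenylation (APA) can gate the negative feedback that an intronic
miRNA exerts on its own host gene.  This note documents the models,
rules and numerical choices the package makes, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The biological question and the analysis model

About half of human miRNA genes sit inside protein-coding host genes,
mostly in introns, and are co-transcribed with them.  When the mature
miRNA has a seed-complementary site in the host's 3'UTR, transcription
of the host produces its own repressor — a negative feedback loop.
Many 3'UTRs carry several cleavage/polyadenylation sites, so the cell
can transcribe UTR isoforms that either contain or lack the miRNA
binding site.  The analysis asks, genome-scale: do hosts of
*host-targeting* (HT) miRNAs look different, in UTR length, poly(A)-site
count and poly(A)-signal placement, from hosts of *non-host-targeting*
(NT) miRNAs, and does perturbing the 3'-processing machinery (CPSF2
silencing) shift poly(A)-site usage differently in HT hosts?

The pipeline decomposes into:

1. **Context classification.** A miRNA locus is *intronic* when fully
   contained in an intron of a transcript, *exonic* when it overlaps an
   exon of a transcript that contains it, *intergenic* otherwise.
   When several genes contain a locus, a same-strand host is preferred,
   then the smallest containing intron, then the lexicographically
   smallest gene id (deterministic; alternates are logged).
2. **Seed matching.** A 7-nt UTR site is a *7mer-m8* when it equals the
   reverse complement of mature nucleotides 2–8 (1-based), and a
   *7mer-A1* when it equals the reverse complement of nucleotides 2–7
   followed by an adenine on the UTR.  Overlapping sites are all
   reported; a site satisfying both definitions is reported once as
   7mer-m8.  An arm with at least one site in its host's 3'UTR is HT,
   otherwise NT; calls are made per mature arm, and "miRNA" counts in
   cohort tables count arms.
3. **Poly(A)-site discovery.** EST-style evidence requires a terminal
   soft-clip run of **more than 10** untemplated adenines (i.e. ≥ 11),
   with an internal-priming filter on the 20 genomic nt downstream of
   the cleavage point (reject if ≥ 12 adenines or any A-run ≥ 6 — the
   window parameters follow common PolyA-Seq practice and are
   configurable).  RNA-Seq evidence requires ≥ 2 reads with ≥ 2
   untemplated terminal A's, at least two of which differ in aligned
   length (a base-space generalisation of a colorspace two-zeros rule;
   colorspace itself is not implemented).  External site lists are
   consumed as BED6.  All sources are clustered jointly per gene by
   single linkage with a 40-nt gap; the cluster representative is the
   member with maximal support, ties to the most CDS-proximal member.
   Only sites within the longest annotated transcript are kept, and —
   a further restriction this package applies — only sites at or
   downstream of the annotated 3'UTR start, so every catalogued site
   has a non-negative UTR offset.
4. **Poly(A)-signal analysis.** The two canonical hexamers AAUAAA and
   AUUAAA are scanned over each UTR; a hit's relative position is
   (1-based position)/(UTR length) ∈ (0, 1].  Human-facing tables
   print 1-based positions; BED output is 0-based.  A seed match is
   *potentially APA-influenced* when some poly(A) site lies strictly
   between the UTR start and the match start (a shorter isoform loses
   the site), and *preceded by a canonical signal* when some hexamer
   ends at or before the match start.  A stricter reading — the signal
   must also sit 10–40 nt upstream of a poly(A) site that precedes the
   match — is available behind `preceded_mode="near_upstream_site"`.
5. **Differential 3'UTR usage.** With K catalogued sites, the UTR
   prefix is tiled by K poly(A) regions, region k spanning
   (site_{k−1}, site_k] with region 1 anchored at the UTR start.  A read
   belongs to the region containing the boundary after its 3'-most
   aligned base (right-closed spans).  Each region's study count x out
   of n = x + control is tested two-sided against
   p0 = lib_study/(lib_study + lib_control); q-values come from a
   single genome-wide Benjamini–Hochberg family at α = 0.05.  A gene
   with at least one significantly up- and one significantly
   downregulated region is called **longer** when the median index of
   the up regions exceeds the median index of the down regions and
   **shorter** otherwise; exact median ties therefore fall to
   "shorter" and are flagged (`tie=True`).  Medians of even sets are
   midpoint means and may be fractional.  Genes are pre-filtered for
   depth (default ≥ 20 study+control reads summed over regions;
   configurable — no published value exists for this threshold).
6. **Machinery enrichment.** For each gene of the 3'-processing
   machinery, the number of HT arms versus NT (or intergenic) arms with
   ≥ 1 seed match in its UTR forms a 2×2 table tested with Fisher's
   exact test.  The default BH family is the 11 HT-vs-NT tests, with a
   `joint` option pooling both columns into one 22-test family; only
   family-robust properties (which gene is most significant, whether
   its q clears 0.05) are asserted, since the original correction
   family is ambiguous.  The HT-vs-intergenic comparison is only run
   when an intergenic cohort is supplied: the packaged fixture does not
   invent the unpublished intergenic denominator.

## Statistics

- **Mann–Whitney U** (two-sided, statistic = U for the first sample):
  for n1+n2 ≤ 14 the permutation null is enumerated over all
  C(n1+n2, n1) labelings (tie-safe; p = P(|U − n1n2/2| ≥ |U_obs −
  n1n2/2|)).  For larger tie-free samples up to 60 total the exact
  distribution is used; beyond that, the normal approximation with
  midrank tie correction and continuity correction.  The exact
  extension past the enumeration boundary keeps moderate-sample
  p-values within Monte-Carlo error of the exact permutation law.
- **Binomial** and **Fisher** two-sided p-values use the
  minimum-likelihood ("small-p") convention, the dominant convention
  in standard statistical software.  Degenerate inputs (n = 0,
  all-zero tables) return p = 1.
- **Benjamini–Hochberg** is the standard step-up adjustment; outputs
  preserve input order, dominate the input p-values and are capped at
  1.  Each caller documents its own family (regions: genome-wide;
  enrichment: per table by default).

Delegations: the binomial test, Fisher test and BH adjustment are
computed via scipy/statsmodels; the small-sample Mann–Whitney
enumeration is implemented here.  The test suite checks all four
against independent enumeration oracles (exact rational arithmetic for
Fisher) on exhaustive small-instance sweeps.

## Coordinate and sequence conventions

Internal coordinates are 0-based half-open; GFF3 I/O converts to/from
1-based inclusive.  Cleavage positions are inter-base boundaries: the
boundary after the last templated base is `aligned.end` on the plus
strand and `aligned.start` on the minus strand, making UTR offsets
non-negative on both strands.  The "longest annotated transcript" is
the transcript of maximal genomic span (not summed exon length), ties
to the lexicographically smallest id.  UTR and mature sequences are
RNA (T→U on load); the genome stays DNA.  3' soft-clips are stored in
read orientation (reverse-complemented for minus-strand alignments).

## The synthetic-data generator

The generator emulates the study's inputs at desk scale with full
ground truth:

- **Genes and miRNAs.** Each gene occupies its own chromosome (two
  exons for cohort genes; the ZFR-like fixture uses twenty), with an
  intronic miRNA in the first `n_intronic_mirnas` genes.  Strands
  alternate.  The HT arm count is exactly
  `round(fraction_ht · n_arms)`.
- **UTR engineering.** Backgrounds are scrubbed of accidental
  canonical hexamers and A-runs ≥ 5 before planting, so scans recover
  (essentially only) planted elements.  Each planted cleavage site
  gets a downstream 20-nt window constrained to pass the
  internal-priming filter; sites are ≥ 100 nt apart with the most
  distal site at the UTR end.  Internal-priming decoys are A-run
  stretches whose reads must be rejected.  HT arms get one exact
  planted 7mer-m8 site; NT arms are rejection-sampled until they have
  zero matches in the final UTR (no post-hoc masking).
- **Signal placement.** In `distal_biased` mode, HT-host signals are
  uniform over [0.10, 0.95] of the UTR (median relative position
  ≈ 0.52) and NT-host signals uniform over [0.50, 0.95] (median
  ≈ 0.72), chosen once as a qualitative analog of the published
  contrast between evenly spread and distally accumulated signals.
- **Tail reads.** Each planted site receives `tail_depth_per_site`
  reads (default 5) with 11–15 untemplated A's and varying aligned
  lengths, plus per gene one 10-A read (below the >10 threshold) and
  one MAPQ-10 read (below the ≥ 20 filter) to exercise the filters.
  Reads are emitted in SAM and in a documented TSV dialect.
- **Region counts.** Control counts are multinomial over regions with
  distal-heavy weights (∝ region index); study counts re-weight by the
  planted shift, moving `effect_size` of the distal-half mass
  proximally ("shorter") or the reverse ("longer"), with totals scaled
  by the 1:2 study:control library ratio mirroring the ~50M/~100M read
  libraries of the silencing experiment.  Counts are multinomial
  without overdispersion, matching the binomial test's assumptions for
  single libraries per condition.

What the simulator does **not** emulate: realistic genome composition
or repeat structure, sequencing errors beyond untemplated tails,
alignment ambiguity, overdispersed biological replicates, non-canonical
poly(A) signals, or 3'UTR splicing.  Passing recovery tests therefore
demonstrate correctness of the detection/calling logic under the
stated evidence model, not robustness to noisy real libraries.

### The ZFR-like fixture

`synthetic_data.synthetic_zfr_like()` builds a fully synthetic
minus-strand gene reproducing the published ZFR/mir-579 geometry: total
span 90,389 bp, 20 exons, miRNA (80 nt) in intron 11 (length 4,722 bp,
684 bp from the upstream exon), a 1,409-nt 3'UTR with cleavage sites at
UTR offsets 41/340/1134 (back-computed from the printed chromosome-5
coordinates under the minus-strand reading), canonical signals at
1-based 135/314/738 and a single 7mer-m8 seed site at position 1301 —
downstream of all three sites, so only the longest isoform carries it.
The sequence and the mature miRNA are synthetic; only the geometry is
real.

## Problem sizes used in the checks

The packaged recovery experiments run at desk scale: 20–40 genes for
classification and site-detection recovery (~90–120 planted sites, 30
decoys), 200 genes (40 shorter / 40 longer / 120 null, effect size
0.3, 500 reads/gene, 1:2 libraries) for the shift caller, and ≥ 10,000
signal hits per cohort for the positional contrast.  These sizes give
stable metrics in seconds.

The genome-wide cohort numbers of the original analysis (203 HT / 601
NT arms, 168/351 host genes, 583 seed matches, UTR-length medians
2553/1198 nt, site-count medians 5/3, 435/124 APA-influenced matches,
473/583 signal-preceded matches, 6313 genes with 36 HT / 191 NT hosts
after silencing) depend on the full public inputs — RefSeq Release 49
gene models, miRBase v18, dbEST alignments, the PolyA-Seq atlas and
the deposited silencing RNA-Seq libraries — and are **not reproduced at
desk scale**.  The pipeline accepts those full-scale files through the
same loaders; the packaged checks rest on the count fixtures, the
enumeration oracles and the simulator-recovery experiments above.

## Known limitations

- Contiguous (single-exon) 3'UTRs are assumed; multi-segment UTR
  annotations are collapsed to their span with a warning.
- The internal-priming window parameters stand in for unpublished
  upstream-protocol details and are exposed as configuration.
- EST chimera/paralog control is reduced to the unique-mapping flag;
  mapping itself is out of scope.
- One library per condition: no dispersion estimation; the binomial
  test treats counts as fixed-proportion draws.
- The "shorter-on-tie" rule makes the caller asymmetric on exact
  median ties; ties are flagged so downstream consumers can drop them.
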