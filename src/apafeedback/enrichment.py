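"""Enrichment of 3'-processing-machinery genes among miRNA cohorts.

For each gene of the polyadenylation machinery, counts how many mature
arms of cohort A (host-targeting intronic miRNAs) versus cohort B
(non-host-targeting, or intergenic) carry at least one seed match in
the gene's 3'UTR, tests the 2x2 table with Fisher's exact test, and
adjusts within the declared Benjamini-Hochberg family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation_io import UtrSequence
from .mirna_host import find_seed_matches
from .stats_core import bh_adjust, fisher_exact_two_sided

BH_PER_TABLE = "per_table"
BH_JOINT = "joint"


@dataclass(frozen=True)
class EnrichmentResult:
    apa_gene_id: str
    n_targeting_a: int
    n_a: int
    n_targeting_b: int
    n_b: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.n_targeting_a > self.n_a or self.n_targeting_b > self.n_b:
            raise ValueError("targeting counts exceed cohort size")

    @property
    def fraction_a(self) -> float:
        return self.n_targeting_a / self.n_a if self.n_a else math.nan

    @property
    def fraction_b(self) -> float:
        return self.n_targeting_b / self.n_b if self.n_b else math.nan


def count_targeting_arms(
    apa_gene_utr: UtrSequence, mature_seqs: Sequence[str]
) -> int:
    """Number of arms with >= 1 canonical seed match in the UTR (an arm
    matching several times counts once)."""
    return sum(
        1 for seq in mature_seqs if find_seed_matches(apa_gene_utr, seq)
    )


def _fisher_row(gene_id, ta, na, tb, nb) -> tuple[float, float]:
    a, b = ta, na - ta
    c, d = tb, nb - tb
    res = fisher_exact_two_sided(a, b, c, d)
    return res.statistic, res.p_value


def enrichment_from_counts(
    rows: Sequence[tuple[str, int, int, int, int]],
) -> list[EnrichmentResult]:
    """Fisher tests from precomputed counts.

    ``rows``: (gene_id, n_targeting_a, n_a, n_targeting_b, n_b); the BH
    family is exactly the rows given.
    """
    prelim = []
    for gene_id, ta, na, tb, nb in rows:
        odds, p = _fisher_row(gene_id, ta, na, tb, nb)
        prelim.append((gene_id, ta, na, tb, nb, odds, p))
    qvals = bh_adjust([r[6] for r in prelim])
    return [
        EnrichmentResult(g, ta, na, tb, nb, odds, p, q)
        for (g, ta, na, tb, nb, odds, p), q in zip(prelim, qvals)
    ]


def enrichment_table(
    apa_gene_utrs: Mapping[str, UtrSequence],
    cohort_a: Sequence[str],
    cohort_b: Sequence[str],
) -> list[EnrichmentResult]:
    """One Fisher test per APA-machinery gene, cohort A vs cohort B.

    Cohorts are mature-arm RNA sequences.  An empty cohort makes every
    gene untestable (raises ValueError)."""
    if not cohort_a or not cohort_b:
        raise ValueError("cohorts must be non-empty")
    rows = []
    for gid in sorted(apa_gene_utrs):
        utr = apa_gene_utrs[gid]
        ta = count_targeting_arms(utr, cohort_a)
        tb = count_targeting_arms(utr, cohort_b)
        rows.append((gid, ta, len(cohort_a), tb, len(cohort_b)))
    return enrichment_from_counts(rows)


def enrichment_tables(
    apa_gene_utrs: Mapping[str, UtrSequence],
    ht_cohort: Sequence[str],
    nt_cohort: Sequence[str],
    intergenic_cohort: Sequence[str] | None = None,
    bh_family: str = BH_PER_TABLE,
) -> dict[str, list[EnrichmentResult]]:
    """HT-vs-NT and (optionally) HT-vs-intergenic enrichment tables.

    ``bh_family='per_table'`` adjusts each table's tests among
    themselves; ``'joint'`` adjusts both tables as one family.
    """
    if bh_family not in (BH_PER_TABLE, BH_JOINT):
        raise ValueError(f"unknown BH family {bh_family!r}")
    tables: dict[str, list[EnrichmentResult]] = {
        "ht_vs_nt": enrichment_table(apa_gene_utrs, ht_cohort, nt_cohort)
    }
    if intergenic_cohort:
        tables["ht_vs_intergenic"] = enrichment_table(
            apa_gene_utrs, ht_cohort, intergenic_cohort
        )
    if bh_family == BH_JOINT and len(tables) > 1:
        names = sorted(tables)
        ps = [r.p_value for n in names for r in tables[n]]
        qs = bh_adjust(ps)
        i = 0
        for n in names:
            new = []
            for r in tables[n]:
                new.append(
                    EnrichmentResult(
                        r.apa_gene_id,
                        r.n_targeting_a,
                        r.n_a,
                        r.n_targeting_b,
                        r.n_b,
                        r.odds_ratio,
                        r.p_value,
                        qs[i],
                    )
                )
                i += 1
            tables[n] = new
    return tables
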