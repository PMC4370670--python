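"""Packaged desk-scale fixtures.

Two small TSV tables ship with the package: per-gene seed-match counts
of the 11 polyadenylation-machinery genes against the HT (n=203) and NT
(n=601) intronic-miRNA arm cohorts, and the per-(host gene, miRNA arm)
3'UTR shortening/lengthening calls observed after CPSF2 silencing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("apafeedback").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_table1_counts() -> pd.DataFrame:
    """Columns: gene, ht_targeting, ht_total, nt_targeting, nt_total.

    Note the printed percentages in the source table round some
    fractions (e.g. 158/601 = 26.3% reported as 27%); the raw counts are
    kept here.
    """
    return _read("table1_counts.tsv")


def load_table2_calls() -> pd.DataFrame:
    """Columns: host_gene, mirna, is_ht (yes/no), utr_change
    (shorter/longer); one row per (host gene, mature arm)."""
    return _read("table2_calls.tsv")


def table1_fisher_rows() -> list[tuple[str, int, int, int, int]]:
    """Rows in the shape enrichment_from_counts expects."""
    df = load_table1_counts()
    return [
        (r.gene, int(r.ht_targeting), int(r.ht_total), int(r.nt_targeting), int(r.nt_total))
        for r in df.itertuples()
    ]
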