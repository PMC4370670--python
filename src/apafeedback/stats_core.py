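"""Small-sample statistics used throughout the pipeline.

Exactly four procedures: two-sided Mann-Whitney-U, two-sided binomial
test, two-sided Fisher's exact test, and Benjamini-Hochberg adjustment.
Two-sided p-values for the binomial and Fisher tests use the
minimum-likelihood ("small-p") convention.  The Mann-Whitney test is
exact by permutation enumeration for small samples (tie-safe), exact by
the distribution recurrence for moderate tie-free samples, and a normal
approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: total sample size up to which the tie-safe permutation enumeration runs
EXACT_MWU_ENUMERATION_LIMIT = 14
#: total sample size up to which the tie-free exact distribution is used
EXACT_MWU_DISTRIBUTION_LIMIT = 60


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for sample x: number of (x, y) pairs with x > y, ties half."""
    u = 0.0
    for xv in x:
        for yv in y:
            if xv > yv:
                u += 1.0
            elif xv == yv:
                u += 0.5
    return u


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = EXACT_MWU_ENUMERATION_LIMIT,
) -> TestResult:
    """Two-sided Mann-Whitney-U test; statistic is U for ``x``.

    For n1+n2 <= ``exact_limit`` the permutation null is enumerated over
    all C(n1+n2, n1) group labelings of the observed values and the
    two-sided p is P(|U - n1*n2/2| >= |U_obs - n1*n2/2|).
    """
    xs = [float(v) for v in x]
    ys = [float(v) for v in y]
    if not xs or not ys:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(xs), len(ys)
    u_obs = _u_statistic(xs, ys)

    if n1 + n2 <= exact_limit:
        combined = xs + ys
        idx = tuple(range(n1 + n2))
        centre = n1 * n2 / 2.0
        d_obs = abs(u_obs - centre)
        hits = total = 0
        for comb in combinations(idx, n1):
            sel = set(comb)
            gx = [combined[i] for i in comb]
            gy = [combined[i] for i in idx if i not in sel]
            if abs(_u_statistic(gx, gy) - centre) >= d_obs - 1e-12:
                hits += 1
            total += 1
        return TestResult(u_obs, hits / total, "exact")

    has_ties = len(set(xs + ys)) < n1 + n2
    if not has_ties and n1 + n2 <= EXACT_MWU_DISTRIBUTION_LIMIT:
        res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        xs, ys, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(
        float(res.statistic), min(1.0, float(res.pvalue)), "normal_approx"
    )


def binomial_two_sided(x: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-sided exact binomial test (minimum-likelihood method).

    p = sum of P(k | n, p0) over all k whose point probability does not
    exceed that of the observed count.  A vacuous test (n == 0) returns
    p = 1.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if not (0 <= x <= n):
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if n == 0:
        return TestResult(0.0, 1.0, "exact")
    p = stats.binomtest(int(x), int(n), p0, alternative="two-sided").pvalue
    return TestResult(float(x), min(1.0, float(p)), "exact")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.  Degenerate margins give p = 1.  The statistic is the
    sample odds ratio (inf when b*c == 0 and a*d > 0, nan for 0/0).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("Fisher table counts must be non-negative")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(odds), min(1.0, float(p)), "exact")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Output order matches input order; values are capped at 1 and are
    pointwise >= the input p-values.
    """
    ps = [float(p) for p in p_values]
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    if not ps:
        return []
    q = multipletests(ps, method="fdr_bh")[1]
    return [float(v) for v in q]
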