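"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives the expected value from first principles
(enumeration, exact rational arithmetic, or position-by-position
comparison) without calling the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

_RNA_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def mwu_two_sided_enumeration(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group labelings,
    using rank sums (midranks for ties) rather than pairwise counts."""
    combined = list(x) + list(y)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    # midranks
    order = sorted(range(n), key=lambda i: combined[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1

    def u_of(idx_set):
        r1 = sum(ranks[i] for i in idx_set)
        return r1 - n1 * (n1 + 1) / 2

    centre = n1 * n2 / 2
    d_obs = abs(u_of(range(n1)) - centre)
    hits = total = 0
    for comb in combinations(range(n), n1):
        if abs(u_of(comb) - centre) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def binomial_two_sided_enumeration(x: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial p by summing the pmf over
    all outcomes no more probable than the observed one (standard 1e-7
    relative slack for floating-point pmf ties)."""
    if n == 0:
        return 1.0
    pmf = [math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)]
    cut = pmf[x] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf if p <= cut))


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration
    over all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= p_obs)))


def bh_step_up(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up
    recursion on sorted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = q
        prev = q
    return adj


def seed_matches_brute(utr_seq: str, mature_seq: str):
    """(offset, site_type) for every canonical 7-nt seed site, by
    explicit base-by-base complementarity at each UTR position."""
    out = []
    m = mature_seq.upper().replace("T", "U")
    for i in range(len(utr_seq) - 6):
        window = utr_seq[i : i + 7]
        # 7mer-m8: window pairs antiparallel with mature nt 2..8
        if all(
            _RNA_COMP.get(m[1 + k]) == window[6 - k] for k in range(7)
        ):
            out.append((i, "7mer-m8"))
            continue
        # 7mer-A1: window[:6] pairs with mature nt 2..7, window[6] == A
        if window[6] == "A" and all(
            _RNA_COMP.get(m[1 + k]) == window[5 - k] for k in range(6)
        ):
            out.append((i, "7mer-A1"))
    return out
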