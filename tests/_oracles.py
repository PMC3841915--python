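"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's code paths (and scipy's pmfs for the
likelihood oracle): plain recursion and math.log/lgamma only.
"""

from __future__ import annotations

import math
from functools import lru_cache

MATCH, MISMATCH, GAP = 1, -1, -2


def enumerate_alignment(a: str, b: str) -> tuple[int, int, int]:
    """Best (score, matches, length) over ALL global alignments of a and b.

    Exhaustive recursion (no DP recurrence shared with the implementation);
    ties resolved by the lexicographic key (score, matches, -length).
    Feasible for sequences up to ~8 bases.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[int, int, int]:
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        best = None
        if i < len(a) and j < len(b):
            s, m, L = rec(i + 1, j + 1)
            hit = a[i] == b[j]
            cand = (s + (MATCH if hit else MISMATCH), m + int(hit), L + 1)
            best = cand
        if i < len(a):
            s, m, L = rec(i + 1, j)
            cand = (s + GAP, m, L + 1)
            if best is None or _key(cand) > _key(best):
                best = cand
        if j < len(b):
            s, m, L = rec(i, j + 1)
            cand = (s + GAP, m, L + 1)
            if best is None or _key(cand) > _key(best):
                best = cand
        return best

    def _key(t):
        return (t[0], t[1], -t[2])

    return rec(0, 0)


def oracle_identity(a: str, b: str) -> float:
    _, matches, length = enumerate_alignment(a, b)
    return matches / length


# ---- naive reimplementation of the network likelihoods and AICs -------------


def naive_binary_ll(L: int, S_i: int, verbatim_sign: bool = False) -> float:
    p = L / S_i
    out = 0.0
    if L > 0:
        out += L * math.log(p)
    if S_i - L > 0:
        term = (S_i - L) * math.log(1.0 - p)
        out += -term if verbatim_sign else term
    return out


def naive_poisson_logpmf(a: int, lam: float) -> float:
    if lam == 0.0:
        return 0.0 if a == 0 else float("-inf")
    return a * math.log(lam) - lam - math.lgamma(a + 1)


def naive_binomial_logpmf(a: int, n: int, p: float) -> float:
    if p == 1.0 or n == 0:
        return 0.0  # degenerate at a == n (a == 0)
    comb = math.lgamma(n + 1) - math.lgamma(a + 1) - math.lgamma(n - a + 1)
    return comb + a * math.log(p) + (n - a) * math.log(1.0 - p)


def naive_network_scores(
    member_rows: list[list[list[int]]], model: str = "poisson",
    verbatim_sign: bool = False,
) -> dict[str, float]:
    """Direct summation of the binary and abundance log-likelihoods and AICs.

    ``member_rows[i]`` is OTU i's list of member per-plot abundance rows.
    """
    k = len(member_rows)
    r = len(member_rows[0][0])
    S = sum(len(m) for m in member_rows)
    ll_bin = 0.0
    ll_ab = 0.0
    for rows in member_rows:
        S_i = len(rows)
        for q in range(r):
            col = [row[q] for row in rows]
            L = sum(1 for v in col if v > 0)
            a_dot = sum(col)
            ll_bin += naive_binary_ll(L, S_i, verbatim_sign)
            if model == "poisson":
                lam = a_dot / S_i
                ll_ab += sum(naive_poisson_logpmf(v, lam) for v in col)
            elif model == "binomial":
                ll_ab += sum(naive_binomial_logpmf(v, a_dot, 1.0 / S_i) for v in col)
            else:
                raise ValueError(model)
    return {
        "ll_binary": ll_bin,
        "ll_abund": ll_ab,
        "aic_binary": 2 * k * r + 2 * S - 2 * ll_bin,
        "aic_weighted": 4 * k * r + 2 * S - 2 * (ll_bin + ll_ab),
    }
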