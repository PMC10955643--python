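"""Independent oracle implementations used only by the tests.

Each oracle recomputes a quantity through a route deliberately different from
the package implementation: exact rational arithmetic over explicitly
enumerated 2x2 tables for the allelic test, literal enumerate-and-retest for
the subset burden, the Mann-Whitney rank statistic for ROC-AUC, and a
hand-written step-up for Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.stats import mannwhitneyu


def table_probability(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact conditional probability of a 2x2 table given its margins."""
    n = a + b + c + d
    num = (
        math.factorial(a + b) * math.factorial(c + d)
        * math.factorial(a + c) * math.factorial(b + d)
    )
    den = (
        math.factorial(n) * math.factorial(a) * math.factorial(b)
        * math.factorial(c) * math.factorial(d)
    )
    return Fraction(num, den)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Point-probability two-sided exact p by explicit table enumeration."""
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    p_obs = table_probability(a, b, c, d)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = table_probability(k, r1 - k, m - k, r2 - (m - k))
        if pk <= p_obs:
            total += pk
    return float(total)


def fisher_pvalues_for_margins(r1: int, r2: int, m: int) -> list[float]:
    """Two-sided p for every table with margins (r1, r2, m), indexed by k - lo.

    The pmf vector is built once by the exact recurrence
    pmf(k+1) = pmf(k) * (r1-k)(m-k) / ((k+1)(r2-m+k+1)) in rational
    arithmetic, then each observed k sums the probabilities <= its own.
    """
    lo, hi = max(0, m - r2), min(r1, m)
    pmf = [Fraction(0)] * (hi - lo + 1)
    pmf[0] = table_probability(lo, r1 - lo, m - lo, r2 - (m - lo))
    for k in range(lo, hi):
        pmf[k - lo + 1] = (
            pmf[k - lo] * (r1 - k) * (m - k)
        ) / ((k + 1) * (r2 - m + k + 1))
    order = sorted(range(len(pmf)), key=pmf.__getitem__)
    prefix = []
    acc = Fraction(0)
    for i in order:
        acc += pmf[i]
        prefix.append(acc)
    rank_of = {i: r for r, i in enumerate(order)}
    out = [0.0] * len(pmf)
    for i in range(len(pmf)):
        # sum of pmf values <= pmf[i]: walk forward over ties
        r = rank_of[i]
        while r + 1 < len(order) and pmf[order[r + 1]] == pmf[i]:
            r += 1
        out[i] = float(prefix[r])
    return out


def chi2_4_sf(x: float) -> float:
    """Closed-form survival function of chi-square with 4 df."""
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def brute_force_burden(rows: list[dict]) -> dict:
    """Literal enumerate-and-retest subset burden for one gene.

    ``rows``: one dict per significant variant with keys variant_id,
    case_alt, case_ref, ctrl_alt, ctrl_ref, direction. Returns the four
    meta-p-values and the best directional subsets.
    """
    rows = sorted(rows, key=lambda r: r["variant_id"])

    def search(subset_rows):
        best = None
        count = 0
        for size in range(1, len(subset_rows) + 1):
            for combo in combinations(subset_rows, size):
                count += 1
                a = sum(r["case_alt"] for r in combo)
                b = sum(r["case_ref"] for r in combo)
                c = sum(r["ctrl_alt"] for r in combo)
                d = sum(r["ctrl_ref"] for r in combo)
                p = fisher_two_sided(a, b, c, d)
                key = (p, tuple(r["variant_id"] for r in combo))
                if best is None or key < best:
                    best = key
        return best[0], best[1], count

    p_all, _, n_all = search(rows)
    meta_p = min(1.0, p_all * n_all)

    directional = {}
    for direction in ("case", "control"):
        sub = [r for r in rows if r["direction"] == direction]
        if not sub:
            directional[direction] = (1.0, ())
            continue
        p, subset, n = search(sub)
        directional[direction] = (min(1.0, p * n), subset)

    p_case, best_case = directional["case"]
    p_ctrl, best_ctrl = directional["control"]
    pc = max(p_case, np.finfo(float).tiny)
    pt = max(p_ctrl, np.finfo(float).tiny)
    x = -2.0 * (math.log(pc) + math.log(pt))
    return {
        "meta_p": meta_p,
        "subset_case_meta_p": p_case,
        "subset_control_meta_p": p_ctrl,
        "subset_meta_p": chi2_4_sf(x),
        "best_case_subset": list(best_case),
        "best_control_subset": list(best_ctrl),
    }


def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC as the normalised Mann-Whitney U statistic."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (len(pos) * len(neg))


def bh_step_up(pvalues) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def hypergeom_tail(k: int, m_total: int, n_set: int, n_drawn: int) -> float:
    """P[X >= k] for X ~ Hypergeom(m_total, n_set, n_drawn), by direct sum."""
    total = Fraction(0)
    den = math.comb(m_total, n_drawn)
    for j in range(k, min(n_set, n_drawn) + 1):
        total += Fraction(
            math.comb(n_set, j) * math.comb(m_total - n_set, n_drawn - j), den
        )
    return float(total)
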