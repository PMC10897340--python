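"""Independent brute-force oracles used to verify the package's statistics.

Everything here is deliberately written in plain loops, independent of the
implementations under test.
"""

from __future__ import annotations

import math
from itertools import combinations

from scipy.stats import chi2 as _chi2
from scipy.stats import t as _t


def brute_logrank(time, event, group):
    """Two-group log-rank by direct hypergeometric summation over event
    times. ``group`` holds 0/1 labels. Returns (chi2, p)."""
    rows = list(zip(time, event, group))
    o = e = v = 0.0
    for et in sorted({t for t, ev, _ in rows if ev == 1}):
        at_risk = [r for r in rows if r[0] >= et]
        n = len(at_risk)
        n1 = sum(1 for r in at_risk if r[2] == 1)
        d = sum(1 for r in rows if r[0] == et and r[1] == 1)
        d1 = sum(1 for r in rows if r[0] == et and r[1] == 1 and r[2] == 1)
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0
    stat = (o - e) ** 2 / v
    return stat, float(_chi2.sf(stat, 1))


def brute_logit_combine(p_values):
    """Mudholkar–George combination evaluated directly from its formula."""
    k = len(p_values)
    g = -sum(math.log(p / (1 - p)) for p in p_values)
    nu = 5 * k + 4
    c = math.sqrt(k * math.pi**2 * (5 * k + 2) / (3 * nu))
    return float(_t.sf(g / c, df=nu))


def brute_fisher_2xc(table):
    """Two-sided (probability-mass rule) Fisher p for a 2 x c table by
    explicit enumeration with exact rational binomials."""
    from math import comb

    row1 = list(table[0])
    cols = [a + b for a, b in zip(table[0], table[1])]
    r1 = sum(row1)
    n = sum(cols)
    denom = comb(n, r1)

    def tables(j, remaining):
        if j == len(cols) - 1:
            if 0 <= remaining <= cols[j]:
                yield (remaining,)
            return
        for a in range(0, min(cols[j], remaining) + 1):
            for rest in tables(j + 1, remaining - a):
                yield (a,) + rest

    def prob(row):
        num = 1
        for c, a in zip(cols, row):
            num *= comb(c, a)
        return num / denom

    p_obs = prob(row1)
    return sum(p for row in tables(0, r1) if (p := prob(row)) <= p_obs * (1 + 1e-9))


def brute_mccv(values, times, events, grid, splits, min_group_size):
    """Single-endpoint Monte-Carlo cutpoint search by plain loops, using
    lifelines' log-rank as the p-value engine and the directly-evaluated
    logit combination. Returns (chosen threshold, combined p by threshold).
    """
    from lifelines.statistics import logrank_test as ll_logrank

    def p_at(idx, tau):
        high = [i for i in idx if values[i] > tau]
        low = [i for i in idx if values[i] <= tau]
        if not high or not low:
            return 1.0
        if sum(events[i] for i in idx) == 0:
            return 1.0
        res = ll_logrank(
            [times[i] for i in high], [times[i] for i in low],
            [events[i] for i in high], [events[i] for i in low],
        )
        if not math.isfinite(res.test_statistic):
            return 1.0
        return float(res.p_value)

    n = len(values)
    test_ps: dict[float, list[float]] = {}
    for train in splits:
        train = list(train)
        test = [i for i in range(n) if i not in set(train)]
        train_p = [p_at(train, tau) for tau in grid]
        j = min(range(len(grid)), key=lambda jj: (train_p[jj], jj))
        tau = grid[j]
        sizes = [
            sum(1 for i in train if values[i] > tau),
            sum(1 for i in train if values[i] <= tau),
            sum(1 for i in test if values[i] > tau),
            sum(1 for i in test if values[i] <= tau),
        ]
        if min(sizes) < min_group_size:
            continue
        test_ps.setdefault(tau, []).append(p_at(test, tau))
    combined = {tau: brute_logit_combine(ps) for tau, ps in test_ps.items()}
    chosen = min(combined, key=lambda t: (combined[t], t))
    return chosen, combined


def all_half_splits(n):
    """Every subset of size n//2 of range(n)."""
    return [list(c) for c in combinations(range(n), n // 2)]
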