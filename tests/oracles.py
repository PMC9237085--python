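"""Independent brute-force oracles used to check the package's numerics.

Every function here is written as a plain, loop-based transcription of the
defining formula, deliberately sharing no code with the implementation
under test.
"""
from __future__ import annotations

import math


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def average_ranks(x) -> list[float]:
    """1-based average ranks; the largest value gets rank len(x)."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    return pearson_oracle(average_ranks(x), average_ranks(y))


def mean_score_oracle(values_by_gene) -> float:
    vals = [v for v in values_by_gene if v == v]  # drop NaN
    return sum(vals) / len(vals)


def ssgsea_oracle(x, member, alpha) -> float:
    """Unnormalized single-sample enrichment score.

    ``x``: one sample's expression over all genes; ``member``: bool per
    gene. Ranks are average ranks (largest expression -> largest rank);
    positions walk from the top rank down, ties broken stably by gene index.
    """
    n = len(x)
    ranks = average_ranks(x)
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    denom_in = sum(ranks[i] ** alpha for i in range(n) if member[i])
    n_out = n - sum(member)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in order:
        if member[i]:
            cum_in += ranks[i] ** alpha
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es


def bh_oracle(p) -> list[float]:
    """Step-up BH: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = float("inf")
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p[i] * m / (pos + 1))
        q[i] = min(running_min, 1.0)
    return q


def km_oracle(times, events):
    """Product-limit estimator; returns (event_times, survival) with the
    curve value just after each distinct event time."""
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    s = 1.0
    out_t, out_s = [], []
    for t in distinct:
        n_at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return out_t, out_s


def logrank_oracle(times, events, in_a):
    """(chi2, O_A, E_A, V) by direct accumulation over event times."""
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    o_a = e_a = v = 0.0
    for t in distinct:
        at_risk = [i for i, ti in enumerate(times) if ti >= t]
        n = len(at_risk)
        n_a = sum(1 for i in at_risk if in_a[i])
        d = sum(
            1 for i, (ti, ei) in enumerate(zip(times, events))
            if ti == t and ei == 1
        )
        d_a = sum(
            1 for i, (ti, ei) in enumerate(zip(times, events))
            if ti == t and ei == 1 and in_a[i]
        )
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2 = (o_a - e_a) ** 2 / v if v > 0 else float("nan")
    return chi2, o_a, e_a, v


def cox_breslow_loglik(beta, times, events, x) -> float:
    """Breslow log partial likelihood for a single covariate."""
    ll = 0.0
    for i, (ti, ei) in enumerate(zip(times, events)):
        if not ei:
            continue
        risk = sum(
            math.exp(beta * x[j]) for j, tj in enumerate(times) if tj >= ti
        )
        ll += beta * x[i] - math.log(risk)
    return ll


def cox_breslow_score(beta, times, events, x) -> float:
    """Derivative of the Breslow log partial likelihood at ``beta``."""
    sc = 0.0
    for i, (ti, ei) in enumerate(zip(times, events)):
        if not ei:
            continue
        num = sum(
            x[j] * math.exp(beta * x[j]) for j, tj in enumerate(times) if tj >= ti
        )
        den = sum(
            math.exp(beta * x[j]) for j, tj in enumerate(times) if tj >= ti
        )
        sc += x[i] - num / den
    return sc


def cox_grid_argmax(times, events, x, lo=-3.0, hi=3.0, step=0.001) -> float:
    """Grid-search maximizer of the Breslow partial likelihood."""
    best_b, best_ll = lo, -float("inf")
    b = lo
    while b <= hi:
        ll = cox_breslow_loglik(b, times, events, x)
        if ll > best_ll:
            best_ll, best_b = ll, b
        b += step
    return best_b
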