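"""Independent brute-force oracles used to freeze expected values.

Every function here recomputes a quantity by direct enumeration or a
closed form, independently of the package's implementation paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def fisher_p_enumeration(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher p by exact rational enumeration of the support.

    Sums hypergeometric table probabilities that do not exceed the
    observed table's probability by more than a 1e-7 relative slack.
    """
    r1, c1 = n11 + n10, n11 + n01
    n = n11 + n10 + n01 + n00
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k),
                    math.comb(n, c1))
        for k in range(lo, hi + 1)
    }
    obs = probs[n11]
    cutoff = obs + obs * Fraction(1, 10_000_000)
    return float(sum(p for p in probs.values() if p <= cutoff))


def cmle_or_enumeration(n11: int, n10: int, n01: int, n00: int) -> float:
    """Conditional-MLE odds ratio by direct support enumeration.

    Independent route: exact integer binomial coefficients from
    math.comb, the noncentral-hypergeometric conditional mean evaluated
    in log space over the full support, and plain bisection on log psi.
    """
    r1, c1 = n11 + n10, n11 + n01
    n = n11 + n10 + n01 + n00
    r2 = n - r1
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if lo == hi:
        return math.nan
    if n11 == lo:
        return 0.0
    if n11 == hi:
        return math.inf

    log_coef = {
        k: math.log(math.comb(r1, k)) + math.log(math.comb(r2, c1 - k))
        for k in range(lo, hi + 1)
    }

    def mean_minus_obs(logpsi: float) -> float:
        terms = {k: log_coef[k] + k * logpsi for k in log_coef}
        m = max(terms.values())
        num = sum(k * math.exp(t - m) for k, t in terms.items())
        den = sum(math.exp(t - m) for t in terms.values())
        return num / den - n11

    a, b = -700.0, 700.0  # the conditional mean is monotone in psi
    assert mean_minus_obs(a) < 0 < mean_minus_obs(b)
    for _ in range(200):
        mid = 0.5 * (a + b)
        if mean_minus_obs(mid) < 0:
            a = mid
        else:
            b = mid
    return math.exp(0.5 * (a + b))


def bh_stepup(p: list[float]) -> list[float]:
    """Hand-rolled Benjamini–Hochberg step-up."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_min_partition(graph, score_fn):
    """Minimum-description-length partition by exhaustive search."""
    nodes = sorted(graph.nodes)
    best = None
    best_L = math.inf
    for blocks in all_partitions(nodes):
        partition = {u: i for i, block in enumerate(blocks) for u in block}
        L = score_fn(graph, partition)
        if L < best_L - 1e-12:
            best_L, best = L, partition
    return best, best_L


def pooled_t_test(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample t test from the textbook formula."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p
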