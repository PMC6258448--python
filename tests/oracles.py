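"""Independent reference implementations used only to check the package.

Deliberately naive: exact rational arithmetic, pure-Python loops and
quadratic scans, kept free of the code paths they validate.
"""

from __future__ import annotations

import math
from fractions import Fraction


def exact_binomial_tail(k: int, n: int, p: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p), exact rational tail sum."""
    q = 1 - p
    return sum((math.comb(n, j) * p**j * q ** (n - j) for j in range(k, n + 1)), Fraction(0))


def exact_binomial_tail_grid(n: int, p: Fraction) -> list[Fraction]:
    """[P(X >= k) for k in 0..n] via one exact suffix sum."""
    q = 1 - p
    pmf = [math.comb(n, j) * p**j * q ** (n - j) for j in range(n + 1)]
    tails = [Fraction(0)] * (n + 1)
    acc = Fraction(0)
    for j in range(n, -1, -1):
        acc += pmf[j]
        tails[j] = acc
    return tails


def bh_stepup(p_values) -> list[float]:
    """Benjamini-Hochberg step-up q-values, pure-Python loop version."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        raw = p_values[order[rank - 1]] * m / rank
        running = min(running, raw)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank_minus_1, idx in enumerate(order):
        out[idx] = q_sorted[rank_minus_1]
    return out


def brute_force_intersect(snvs, regions):
    """O(n*m) scan assigning each SNV to the regions containing it.

    Returns (per-region mutation counts, per-region sample sets, outside
    count). Regions may be given in any order; an SNV inside two regions is
    counted in both (callers use disjoint catalogues, so this doubles as an
    overlap detector when totals fail to reconcile).
    """
    counts = [0] * len(regions)
    samples = [set() for _ in regions]
    outside = 0
    for v in snvs:
        hit = False
        for i, r in enumerate(regions):
            if v.chrom == r.chrom and r.start0 <= v.pos0 < r.end0:
                counts[i] += 1
                samples[i].add(v.sample_id)
                hit = True
        if not hit:
            outside += 1
    return counts, samples, outside
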