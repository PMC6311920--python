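"""Independent oracles used by the test suite.

Deliberately naive implementations (pure-Python loops, textbook series)
kept separate from the package code paths they validate.
"""

from __future__ import annotations

import math


def naive_mi(x, labels) -> float:
    """Triple-loop plug-in MI: min-max normalisation, Gaussian marginal
    kernel, 0/1 label kernel, and the root-distance joint kernel, summed
    term by term in pure Python."""
    n = len(x)
    lo, hi = min(x), max(x)
    if hi == lo:
        xs = [0.0] * n
    else:
        xs = [(v - lo) / (hi - lo) for v in x]
    d = [[0.0 if labels[i] == labels[j] else 1.0 for j in range(n)] for i in range(n)]
    c1 = math.sqrt(2.0 * math.pi) * n
    c2 = 2.0 * math.pi * n
    total = 0.0
    for i in range(n):
        fx = sum(math.exp(-((xs[i] - xs[j]) ** 2) / 2.0) for j in range(n)) / c1
        fy = sum(math.exp(-d[i][j] / 2.0) for j in range(n)) / c1
        fxy = (
            sum(
                math.exp(-math.sqrt((xs[i] - xs[k]) ** 2 + d[k][i]) / 2.0)
                for k in range(n)
            )
            / c2
        )
        total += math.log(fxy / (fx * fy))
    return total / n


def _gamma_p(a: float, x: float) -> float:
    """Regularized lower incomplete gamma P(a, x) by series / continued
    fraction (textbook forms, independent of scipy.special)."""
    if x < 0 or a <= 0:
        raise ValueError("bad arguments")
    if x == 0:
        return 0.0
    lg = math.lgamma(a)
    if x < a + 1.0:
        # series expansion
        term = 1.0 / a
        total = term
        ap = a
        for _ in range(10000):
            ap += 1.0
            term *= x / ap
            total += term
            if abs(term) < abs(total) * 1e-16:
                break
        return total * math.exp(-x + a * math.log(x) - lg)
    # continued fraction for Q(a, x), modified Lentz
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 10000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    q = math.exp(-x + a * math.log(x) - lg) * h
    return 1.0 - q


def chi2_cdf(x: float, df: float) -> float:
    return _gamma_p(df / 2.0, x / 2.0)


def chi2_quantile(p: float, df: float) -> float:
    """Inverse chi-square CDF by bisection on :func:`chi2_cdf`."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    lo, hi = 0.0, df + 20.0 * math.sqrt(2.0 * df) + 100.0
    while chi2_cdf(hi, df) < p:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if chi2_cdf(mid, df) < p:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)
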