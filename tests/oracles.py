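"""Independent brute-force oracles used to validate the package's statistics.

Each oracle recomputes a quantity by direct enumeration or closed form,
sharing no code path with the implementation it checks.  Binomial and
hypergeometric enumerations are carried out in exact integer arithmetic, so
tie decisions (which outcomes count as "at most as likely") are exact; only
the final division is floating point (correctly rounded in Python).
"""

from bisect import bisect_right
from itertools import accumulate
from math import comb, exp, factorial


def binom_twosided_enum(k: int, n: int, a: int, b: int) -> float:
    """Exact two-sided binomial p-value at rho = a/(a+b) by full enumeration.

    pmf numerators are C(n,i)·a^i·b^(n-i) over the common denominator
    (a+b)^n; the qualifying set {i : pmf(i) <= pmf(k)} is decided by exact
    integer comparison.
    """
    num = [comb(n, i) * a**i * b ** (n - i) for i in range(n + 1)]
    pk = num[k]
    return sum(x for x in num if x <= pk) / (a + b) ** n


def binom_twosided_enum_all(n: int, a: int, b: int) -> list[float]:
    """:func:`binom_twosided_enum` for every k in 0..n, via sorted prefix sums."""
    num = [comb(n, i) * a**i * b ** (n - i) for i in range(n + 1)]
    snum = sorted(num)
    prefix = list(accumulate(snum))
    denom = (a + b) ** n
    return [prefix[bisect_right(snum, num[k]) - 1] / denom for k in range(n + 1)]


def chi2_sf_even_df(x: float, df: int) -> float:
    """Closed-form chi-square survival function for even df:
    exp(-x/2) · Σ_{j<df/2} (x/2)^j / j!"""
    assert df % 2 == 0 and df >= 2
    half = x / 2.0
    return exp(-half) * sum(half**j / factorial(j) for j in range(df // 2))


def bh_stepup(pvalues) -> list[float]:
    """Hand-rolled Benjamini–Hochberg step-up adjusted values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def fisher_2x2_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration with exact
    integer tie decisions (minimum-likelihood two-siding)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    pk = weights[a]
    return sum(w for w in weights.values() if w <= pk) / comb(n, c1)


def clopper_pearson_contains(k: int, n: int, p0: float, alpha: float) -> bool:
    """Whether p0 lies inside the exact level-(1-alpha) CI for k/n, decided
    directly from binomial tail masses (the CI inversion criterion)."""
    upper_tail = sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))
    lower_tail = sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(0, k + 1))
    return upper_tail > alpha / 2 and lower_tail > alpha / 2
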