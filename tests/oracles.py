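"""Independent brute-force oracles used only by the test suite."""

import math

import numpy as np


def sample_entropy_bruteforce(x, m: int, r: float) -> float:
    """Naive O(N^2) double-loop template-counting sample entropy.

    Counts Chebyshev matches of m- and (m+1)-length templates over the first
    N - m template starts (self-matches excluded), independent of the
    vectorized implementation it checks.
    """
    x = list(map(float, x))
    n = len(x)
    n_t = n - m
    a = b = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return -math.log(2.0 / (n_t * (n_t - 1)))
    return -math.log(a / b)


def bh_stepup(p):
    """Hand application of the Benjamini-Hochberg step-up formula."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def chi2_quantile_numeric(df: int, alpha: float) -> float:
    """Upper-alpha chi-square quantile by numerical integration + bisection."""
    from scipy.integrate import quad

    def pdf(t):
        return t ** (df / 2 - 1) * math.exp(-t / 2) / (2 ** (df / 2) * math.gamma(df / 2))

    def cdf(q):
        return quad(pdf, 0.0, q, limit=200)[0]

    lo, hi = 0.0, 10.0 * df + 50.0
    target = 1.0 - alpha
    for _ in range(80):
        mid = (lo + hi) / 2
        if cdf(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
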