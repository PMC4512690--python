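"""Independent brute-force oracles for the time-domain feature bank.

Deliberately written in plain Python, directly off the printed formulas,
with no shared code or vectorization from the package under test.
"""

import math


def mav(x):
    return sum(abs(v) for v in x) / len(x)


def _w1(i, n):
    return 1.0 if 0.25 * n <= i <= 0.75 * n else 0.5


def _w2(i, n):
    if 0.25 * n <= i <= 0.75 * n:
        return 1.0
    if i < 0.25 * n:
        return 4.0 * i / n
    return 4.0 * (n - i) / n


def wmav(x, window_id):
    n = len(x)
    w = _w1 if window_id == 1 else _w2
    return sum(w(i, n) * abs(v) for i, v in enumerate(x, start=1)) / n


def harmonic_mean(x):
    if any(v == 0 for v in x):
        return 0.0
    # exactly rounded sum: the reciprocals of signed samples can cancel
    # almost completely, so naive summation order changes the result
    s = math.fsum(1.0 / v for v in x)
    if s == 0:
        return 0.0
    return len(x) / s


def variance(x):
    mu = sum(x) / len(x)
    return sum((v - mu) ** 2 for v in x) / len(x)


def rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def skewness(x, tol=1e-12):
    mu = sum(x) / len(x)
    sigma = math.sqrt(variance(x))
    if sigma < tol:
        return 0.0
    return sum((v - mu) ** 3 for v in x) / len(x) / sigma**3


def kurtosis(x, tol=1e-12):
    mu = sum(x) / len(x)
    sigma = math.sqrt(variance(x))
    if sigma < tol:
        return 0.0
    return sum((v - mu) ** 4 for v in x) / len(x) / sigma**4


def cumulative_length(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def zero_crossings(x):
    return sum(
        1
        for i in range(len(x) - 1)
        if (x[i] > 0 and x[i + 1] < 0) or (x[i] < 0 and x[i + 1] > 0)
    )


def willison_amplitude(x, eps):
    return sum(1 for i in range(len(x) - 1) if abs(x[i + 1] - x[i]) > eps)


def slope_sign_changes(x):
    return sum(
        1
        for i in range(1, len(x) - 1)
        if (x[i] > x[i - 1] and x[i] > x[i + 1]) or (x[i] < x[i - 1] and x[i] < x[i + 1])
    )


def simple_squared_integral(x):
    return sum(v * v for v in x)


def pearson(a, b, tol=1e-12):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    sa = math.sqrt(sum((v - ma) ** 2 for v in a) / n)
    sb = math.sqrt(sum((v - mb) ** 2 for v in b) / n)
    if sa < tol or sb < tol:
        return 0.0
    cov = sum((p - ma) * (q - mb) for p, q in zip(a, b)) / n
    return cov / (sa * sb)


def cfs_merit(indices, relevance, abs_corr):
    """Direct CFS merit from a relevance vector and an |r| matrix."""
    k = len(indices)
    rcf = sum(relevance[i] for i in indices) / k
    if k == 1:
        return rcf
    rff = sum(
        abs_corr[i][j] for i in indices for j in indices if i != j
    ) / (k * (k - 1))
    return k * rcf / math.sqrt(k + k * (k - 1) * rff)
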