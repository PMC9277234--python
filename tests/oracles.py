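"""Independently coded brute-force oracles for neutrality statistics.

pi from explicit pairwise Hamming distances; S and singleton counts from
per-site allele tallies; Tajima and Fu & Li constants written out term by
term. Used as the dual implementation that the package's vectorized
statistics must reproduce.
"""

import numpy as np


def brute_pi(geno):
    n = geno.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(geno[i] != geno[j]))
    return total / (n * (n - 1) / 2)


def brute_counts(geno):
    n = geno.shape[0]
    s = 0
    singles = 0
    for col in geno.T:
        ones = int(col.sum())
        if 0 < ones < n:
            s += 1
            if ones == 1 or ones == n - 1:
                singles += 1
    return s, singles


def brute_tajima_d(geno):
    n = geno.shape[0]
    s, _ = brute_counts(geno)
    if s == 0:
        return np.nan
    if n == 2:
        return 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (brute_pi(geno) - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def brute_fu_li(geno):
    n = geno.shape[0]
    s, eta_s = brute_counts(geno)
    if s == 0 or n < 3:
        return np.nan, np.nan
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    a1 = a + 1.0 / n
    c = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = c + (n - 2) / (n - 1) ** 2 + 2.0 / (n - 1) * (1.5 - (2 * a1 - 3) / (n - 2) - 1.0 / n)
    vd = ((n / (n - 1)) ** 2 * b + a**2 * d - 2 * n * a * (a + 1) / (n - 1) ** 2) / (a**2 + b)
    ud = n / (n - 1) * (a - n / (n - 1)) - vd
    dstar = (n / (n - 1) * s - a * eta_s) / np.sqrt(ud * s + vd * s * s)
    vf = (
        (2 * n**3 + 110.0 * n**2 - 255 * n + 153) / (9.0 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8.0 * b / n
    ) / (a**2 + b)
    uf = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a1) / (3.0 * n * (n - 1))) / a - vf
    fstar = (brute_pi(geno) - (n - 1.0) / n * eta_s) / np.sqrt(uf * s + vf * s * s)
    return dstar, fstar


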