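"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (direct DFT sums, full enumeration of
rank assignments) that never share code with the package paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def direct_dft_power_onesided(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum by the O(N^2) DFT definition.

    Scaled so the one-sided power sums to mean(x^2), matching the package's
    Parseval convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n // 2 + 1)
    ns = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, ns) / n)  # explicit DFT matrix
    coeffs = basis @ x
    power = np.abs(coeffs) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = k * fs / n
    return freqs, power


def direct_dft_bin_power(x: np.ndarray, fs: float, k: int) -> float:
    """One-sided power of a single DFT bin by the direct sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    coeff = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
    p = abs(coeff) ** 2 / n**2
    if k not in (0, n // 2 if n % 2 == 0 else -1):
        p *= 2.0
    return float(p)


def oracle_spectral_features(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> tuple[float, float, float]:
    """(f_peak, f_mean, f_median) from the O(N^2) DFT, plain-loop style."""
    freqs, power = direct_dft_power_onesided(x, fs)
    lo, hi = band
    eps = (fs / x.size) * 1e-9
    keep = [(f, p) for f, p in zip(freqs, power) if lo - eps <= f <= hi + eps]
    fs_kept = [f for f, _ in keep]
    ps_kept = [p for _, p in keep]
    total = sum(ps_kept)
    # peak: lowest-frequency argmax
    best_i = 0
    for i in range(1, len(ps_kept)):
        if ps_kept[i] > ps_kept[best_i]:
            best_i = i
    f_peak = fs_kept[best_i]
    f_mean = sum(f * p for f, p in keep) / total
    cum = 0.0
    f_median = fs_kept[-1]
    for f, p in keep:
        cum += p
        if cum >= total / 2.0 - total * 1e-12:
            f_median = f
            break
    return f_peak, f_mean, f_median


def exact_ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of rank assignments.

    Requires tie-free pooled data. p = 2 * min tail of the W distribution,
    capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1
    w_obs = ranks[: a.size].sum()
    n = pooled.size
    n_total = comb(n, a.size)
    all_w = [sum(c) for c in combinations(range(1, n + 1), a.size)]
    lo = sum(1 for w in all_w if w <= w_obs) / n_total
    hi = sum(1 for w in all_w if w >= w_obs) / n_total
    return min(1.0, 2.0 * min(lo, hi))
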