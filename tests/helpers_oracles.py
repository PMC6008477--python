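"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops / naive DFTs, deliberately avoiding
the vectorized code paths of the package, so the two routes stay independent.
"""

from __future__ import annotations

import math

import numpy as np


def naive_short_term_ac(u: np.ndarray, fs: float, prefix_s: float = 1.5) -> np.ndarray:
    """Double-loop R(i) = sum_j u15[j] * u[j+i], truncated at the end of u."""
    n = len(u)
    n15 = int(round(prefix_s * fs))
    r = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n15):
            if j + i < n:
                acc += u[j] * u[j + i]
        r[i] = acc
    return r


def naive_apen(x: np.ndarray, m: int, r: float) -> float:
    """Pincus approximate entropy, plain loops, self-matches included."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        k = n - mm + 1
        total = 0.0
        for i in range(k):
            count = 0
            for j in range(k):
                dist = max(abs(x[i + t] - x[j + t]) for t in range(mm))
                if dist <= r:
                    count += 1
            total += math.log(count / k)
        return total / k

    return phi(m) - phi(m + 1)


def naive_dft_power(x: np.ndarray) -> np.ndarray:
    """|DFT|^2 for bins 0..N//2 via an explicit DFT matrix."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = np.arange(n // 2 + 1)
    w = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    return np.abs(w @ x) ** 2


def naive_spectral_entropy(
    x: np.ndarray, fs: float, band=(1.0, 11.0), floor_frac=1.0 / 6.0
) -> float:
    """Direct DFT periodogram + noise-floor filtering + Shannon entropy."""
    power = naive_dft_power(x)
    n = len(x)
    freqs = np.arange(n // 2 + 1) * fs / n
    p = [pw for f, pw in zip(freqs, power) if band[0] <= f <= band[1]]
    if not p or max(p) <= 0:
        return 0.0
    cutoff = floor_frac * max(p)
    survivors = [pw for pw in p if pw >= cutoff]
    total = sum(survivors)
    return -sum((pw / total) * math.log(pw / total) for pw in survivors)


def naive_brickwall(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Band-pass via an explicit DFT matrix: zero bins outside [lo, hi]."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = np.arange(n)
    w = np.exp(-2j * np.pi * np.outer(k, k) / n)
    spectrum = w @ x
    freqs = np.minimum(k, n - k) * fs / n  # |f| of each bin
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    return np.real(np.conj(w.T) @ spectrum / n)


def naive_turning_point_ratio(x: np.ndarray) -> float:
    """Loop count of strict interior extrema over N - 2."""
    x = list(map(float, x))
    n = len(x)
    count = 0
    for i in range(1, n - 1):
        if (x[i] - x[i - 1]) * (x[i + 1] - x[i]) < 0:
            count += 1
    return count / (n - 2)


def naive_triangular_kernel(length: int) -> np.ndarray:
    """Symmetric triangular window (odd length), peak 1, matching scipy."""
    assert length % 2 == 1
    centre = (length - 1) / 2
    return np.array([1.0 - abs(i - centre) / ((length + 1) / 2) for i in range(length)])


def naive_convolve_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-length zero-padded convolution by explicit loops."""
    n, m = len(x), len(kernel)
    full = np.zeros(n + m - 1)
    for i in range(n):
        for j in range(m):
            full[i + j] += x[i] * kernel[j]
    start = (m - 1) // 2
    return full[start : start + n]


def naive_energy_feature(
    x: np.ndarray, fs: float, band, smoothed: bool, smooth_len: int
) -> float:
    """Explicit filter -> (rectify + smooth) -> square -> mean."""
    y = naive_brickwall(x, fs, band[0], band[1])
    if smoothed:
        kernel = naive_triangular_kernel(smooth_len)
        kernel = kernel / kernel.sum()
        y = naive_convolve_same(np.abs(y), kernel)
    return float(sum(v * v for v in y) / len(y))


def naive_lbp_code(v: np.ndarray, i: int, spacing: int) -> int:
    """Loop evaluation of the 8-neighbour pattern code."""
    code = 0
    for r in range(4):
        if v[i + (r - 4) * spacing] - v[i] >= 0:
            code += 2**r
        if v[i + (r + 1) * spacing] - v[i] >= 0:
            code += 2 ** (r + 4)
    return code


def naive_uniform_bins() -> dict[int, int]:
    """Map code -> bin, uniform codes (<= 2 circular transitions) ascending."""
    def transitions(code: int) -> int:
        bits = [(code >> b) & 1 for b in range(8)]
        return sum(bits[b] != bits[(b + 1) % 8] for b in range(8))

    uniform = [c for c in range(256) if transitions(c) <= 2]
    table = {c: 58 for c in range(256)}
    for idx, c in enumerate(uniform):
        table[c] = idx
    return table


def naive_cumtrapz(v: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral, unit spacing, zero initial value."""
    out = np.zeros(len(v))
    for i in range(1, len(v)):
        out[i] = out[i - 1] + (v[i - 1] + v[i]) / 2.0
    return out


def naive_lbp_histogram(
    v: np.ndarray, spacing: int, integrated: bool
) -> np.ndarray:
    """Per-index loop histogram over all fully-interior positions."""
    v = np.asarray(v, dtype=float)
    if integrated:
        v = naive_cumtrapz(v)
    table = naive_uniform_bins()
    bins = np.zeros(59, dtype=int)
    for i in range(4 * spacing, len(v) - 4 * spacing):
        bins[table[naive_lbp_code(v, i, spacing)]] += 1
    return bins
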