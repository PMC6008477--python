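"""Morphology features: sub-band energies and 1-D uniform local binary patterns.

Energy block: eleven values per axis segment.  Each scheme band-passes the
segment with a brick-wall filter; flagged schemes are additionally rectified
and smoothed with a triangular kernel; the feature is the mean of the squared
result.

LBP block: four 59-bin histograms per axis segment.  At every position the
8-bit code compares the four neighbours before and four after the centre
(at multiples of the spacing) against the centre value:

    code = sum_{r=0..3} s(v[i + (r-4)*d] - v[i]) * 2^r
         + sum_{r=0..3} s(v[i + (r+1)*d] - v[i]) * 2^(r+4),

with ``s(x) = 1`` for ``x >= 0`` else 0.  Codes with at most two circular
0<->1 transitions ("uniform", 58 of the 256) get individual histogram bins;
all others share one aggregate bin.  The four variants are spacing 3 and 21
on the raw signal and on its cumulative trapezoidal integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import windows

from .config import PipelineConfig
from .preprocess import AxisSegment, bandpass_brickwall

__all__ = [
    "N_LBP_BINS",
    "N_NEIGHBOURS",
    "LBPHistogram",
    "energy_features",
    "lbp_code",
    "uniform_map",
    "lbp_histogram",
    "morphology_block",
]

N_NEIGHBOURS = 8  # P: 4 samples before + 4 after the centre
N_LBP_BINS = 59  # 58 uniform codes + 1 aggregate non-uniform bin


def _circular_transitions(code: int) -> int:
    bits = [(code >> b) & 1 for b in range(N_NEIGHBOURS)]
    return sum(bits[b] != bits[(b + 1) % N_NEIGHBOURS] for b in range(N_NEIGHBOURS))


def _build_uniform_table() -> np.ndarray:
    """Map each 8-bit code to a bin in 0..58 (58 = aggregate non-uniform)."""
    table = np.full(256, N_LBP_BINS - 1, dtype=np.intp)
    uniform = [c for c in range(256) if _circular_transitions(c) <= 2]
    for bin_idx, code in enumerate(uniform):
        table[code] = bin_idx
    assert len(uniform) == N_LBP_BINS - 1
    return table


_UNIFORM_TABLE = _build_uniform_table()


def uniform_map(code: int) -> int:
    """Histogram bin (0-based, 0..58) of an 8-bit pattern code."""
    if not 0 <= code <= 255:
        raise ValueError("code must lie in [0, 255]")
    return int(_UNIFORM_TABLE[code])


@dataclass
class LBPHistogram:
    """A 59-bin uniform-pattern histogram (raw counts)."""

    bins: np.ndarray
    spacing: int
    integrated: bool

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        if self.bins.shape != (N_LBP_BINS,):
            raise ValueError(f"expected {N_LBP_BINS} bins")

    @property
    def n_positions(self) -> int:
        return int(self.bins.sum())


def _step(x: np.ndarray) -> np.ndarray:
    """Threshold s(x): 1 for x >= 0, 0 otherwise."""
    return (x >= 0).astype(np.uint8)


def lbp_code(v: np.ndarray, i: int, spacing: int = 1) -> int:
    """8-bit pattern code at index ``i`` of vector ``v``.

    Bits 0-3 compare the four preceding neighbours (farthest first), bits 4-7
    the four following neighbours (nearest first), each at multiples of
    ``spacing`` samples from the centre.
    """
    v = np.asarray(v, dtype=float)
    half = N_NEIGHBOURS // 2
    if i - half * spacing < 0 or i + half * spacing >= v.size:
        raise IndexError("neighbourhood extends outside the vector")
    code = 0
    for r in range(half):
        if v[i + (r - half) * spacing] - v[i] >= 0:
            code |= 1 << r
        if v[i + (r + 1) * spacing] - v[i] >= 0:
            code |= 1 << (r + half)
    return code


def _lbp_codes_vectorized(v: np.ndarray, spacing: int) -> np.ndarray:
    half = N_NEIGHBOURS // 2
    n = v.size
    lo, hi = half * spacing, n - half * spacing
    if hi <= lo:
        return np.empty(0, dtype=np.intp)
    centre = v[lo:hi]
    codes = np.zeros(hi - lo, dtype=np.intp)
    for r in range(half):
        before = v[lo + (r - half) * spacing : hi + (r - half) * spacing]
        after = v[lo + (r + 1) * spacing : hi + (r + 1) * spacing]
        codes |= _step(before - centre).astype(np.intp) << r
        codes |= _step(after - centre).astype(np.intp) << (r + half)
    return codes


def lbp_histogram(
    v: np.ndarray, spacing: int, integrated: bool = False
) -> LBPHistogram:
    """59-bin uniform-pattern histogram of a signal vector.

    Every index whose full 8-neighbourhood exists contributes one count, so
    the bin total equals ``len(v) - 8 * spacing``.  With ``integrated`` the
    signal is first replaced by its cumulative trapezoidal integral (unit
    sample spacing, zero initial value).
    """
    v = np.asarray(v, dtype=float)
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    if integrated:
        v = cumulative_trapezoid(v, dx=1.0, initial=0.0)
    codes = _lbp_codes_vectorized(v, spacing)
    if codes.size == 0:
        warnings.warn("no evaluable position; all-zero histogram")
        bins = np.zeros(N_LBP_BINS, dtype=np.int64)
    else:
        bins = np.bincount(_UNIFORM_TABLE[codes], minlength=N_LBP_BINS)
    return LBPHistogram(bins=bins, spacing=spacing, integrated=integrated)


def _triangular_smooth(x: np.ndarray, length: int) -> np.ndarray:
    kernel = windows.triang(length)
    kernel /= kernel.sum()
    return np.convolve(x, kernel, mode="same")


def energy_features(
    seg: AxisSegment, config: Optional[PipelineConfig] = None
) -> np.ndarray:
    """Eleven sub-band energies of one axis segment.

    Scheme ``m``: band-pass per ``config.energy_bands[m]``; if ``m`` is in
    ``config.energy_smoothed`` the filtered signal is rectified and smoothed
    with a triangular kernel first; the feature is the mean of the square.
    """
    config = config or PipelineConfig()
    x = seg.samples
    out = np.empty(len(config.energy_bands))
    smoothed = set(config.energy_smoothed)
    for m, band in enumerate(config.energy_bands):
        y = bandpass_brickwall(x, seg.fs, band[0], band[1])
        if m in smoothed:
            y = _triangular_smooth(np.abs(y), config.energy_smooth_len)
        out[m] = np.mean(y * y)
    return out


def morphology_block(
    seg: AxisSegment, config: Optional[PipelineConfig] = None
) -> list[LBPHistogram]:
    """The four LBP histograms of one axis segment, in deterministic order.

    Order: (raw, spacing_1), (raw, spacing_2), (integrated, spacing_1),
    (integrated, spacing_2).
    """
    config = config or PipelineConfig()
    out = []
    for integrated in (False, True):
        for spacing in config.lbp_spacings:
            out.append(lbp_histogram(seg.samples, spacing, integrated))
    return out
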